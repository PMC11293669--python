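"""Synthetic cohorts and oracle regression problems.

Two generators live here:

``generate_cohort``
    Emits a multi-subject feature table with the statistical structure the
    downstream analysis assumes: per-subject feature vectors whose means
    shift with the pain level, subject-level random effects, latent subject
    clusters that differ in *how* their features respond to pain, and
    heteroscedastic observation noise.  It stands in for a licensed
    physiological-signal cohort (87 subjects, 22 electrodermal-activity
    features, continuous pain label on a 0-4 scale).

``generate_known_quantile_regression``
    A one-dimensional regression problem whose conditional noise
    distribution is fully known, so the true central prediction interval at
    any confidence level is available in closed form.  Used to validate
    coverage of trained interval models against an oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_known_quantile_regression",
    "clean_table",
    "feature_columns",
    "read_feature_table",
    "write_feature_table",
]

N_LEVELS = 5  # pain levels are fixed at {0, 1, 2, 3, 4}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe the reference cohort used throughout the test
    suite: 87 subjects x 5 pain levels x 20 observations each (8700 rows
    before cleaning), 22 features, 4 latent subject clusters.

    Parameters
    ----------
    n_subjects : int
        Number of subjects in the cohort.
    obs_per_subject_level : int
        Repeated observations per subject at each pain level.
    n_features : int
        Number of feature columns (22 mirrors the canonical time-series
        characteristics extracted from an EDA waveform).
    n_latent_clusters : int
        Number of latent subject clusters.  Clusters differ both in their
        baseline feature means and in the direction/magnitude of the
        per-level feature response, so they are genuine subpopulations.
    effect_size : float
        Scale of the per-pain-level mean shift (feature units per level).
    subject_sd : float
        Standard deviation of the per-subject random effect.
    cluster_sd : float
        Standard deviation of cluster baseline means.
    noise_sd_base : float
        Observation noise standard deviation at pain level 0.
    heteroscedasticity : float
        Fractional noise growth per pain level: the level-``l`` noise sd is
        ``noise_sd_base * (1 + heteroscedasticity * l)``.
    subject_noise_sd : float
        Log-normal sigma of a per-subject noise multiplier, modelling how
        readable each subject's signal is (electrodermal responders vs
        non-responders).  0 gives every subject the same noise scale.
    noise_df : float
        Degrees of freedom of the Student-t feature and response noise,
        standardized to unit variance.  Physiological signals carry
        occasional large artifacts (motion, electrode contact) and
        occasional non-responses, so the default is heavy tailed; ``inf``
        recovers Gaussian noise.  Must exceed 2 so the configured noise sd
        is well defined.
    response_noise_sd : float
        Standard deviation of the trial-level stimulus-response jitter:
        the *effective* response level driving the features deviates from
        the nominal stimulus label by a Student-t (``noise_df``) draw of
        this scale, modelling habituation/sensitisation between trials.
        This is irreducible label uncertainty: no feature reveals it.
    missing_rate : float
        Probability that a row has a missing feature cell injected
        (one uniformly chosen cell per affected row); cleaning drops such
        rows.
    label_jitter : float
        Optional uniform jitter half-width added to the integer pain level
        to produce a strictly continuous label (default off); jittered
        labels are clipped to [0, 4].
    seed : int
        Seed for the single generator all randomness flows from.
    """

    n_subjects: int = 87
    obs_per_subject_level: int = 20
    n_features: int = 22
    n_latent_clusters: int = 4
    effect_size: float = 0.1
    subject_sd: float = 0.3
    cluster_sd: float = 1.0
    noise_sd_base: float = 0.3
    heteroscedasticity: float = 0.1
    subject_noise_sd: float = 0.6
    noise_df: float = 3.0
    response_noise_sd: float = 0.5
    missing_rate: float = 0.01
    label_jitter: float = 0.5
    seed: int = 0

    n_levels: int = N_LEVELS  # fixed; kept as a field for introspection

    def __post_init__(self) -> None:
        if self.n_levels != N_LEVELS:
            raise ValueError(f"n_levels is fixed at {N_LEVELS}")
        for name in ("n_subjects", "obs_per_subject_level", "n_features",
                     "n_latent_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_latent_clusters > self.n_subjects:
            raise ValueError("n_latent_clusters cannot exceed n_subjects")
        if self.noise_sd_base <= 0:
            raise ValueError("noise_sd_base must be > 0")
        for name in ("subject_sd", "cluster_sd", "heteroscedasticity",
                     "subject_noise_sd", "response_noise_sd", "label_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not self.noise_df > 2:
            raise ValueError("noise_df must exceed 2")

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def feature_columns(n_features: int = 22) -> list[str]:
    """Column names for the feature block: ``f01 .. f22`` by default."""
    width = max(2, len(str(n_features)))
    return [f"f{j + 1:0{width}d}" for j in range(n_features)]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort feature table.

    Each feature value decomposes as

        cluster baseline + subject random effect
        + effect_size * cluster loading * effective_level + noise,

    with noise sd ``noise_sd_base * (1 + heteroscedasticity * level)``
    times the subject's log-normal readability multiplier.
    Cluster loadings are drawn once per (cluster, feature), so clusters
    respond to pain in different directions — the heterogeneity that makes
    cluster-specific models genuinely different from a pooled one.

    Returns a DataFrame with columns ``subject_id``, ``pain_label``,
    ``cluster_truth`` and the feature block; rows selected for missingness
    carry a single NaN cell and are removed by :func:`clean_table`.
    Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sub, n_feat, n_clu = cfg.n_subjects, cfg.n_features, cfg.n_latent_clusters

    cluster_means = rng.normal(0.0, cfg.cluster_sd, size=(n_clu, n_feat))
    cluster_loadings = rng.normal(0.0, 1.0, size=(n_clu, n_feat))
    # balanced assignment, shuffled, so planted clusters are near-equal size
    subject_cluster = rng.permutation(np.arange(n_sub) % n_clu)
    subject_effects = rng.normal(0.0, cfg.subject_sd, size=(n_sub, n_feat))
    subject_noise_scale = np.exp(
        rng.normal(0.0, cfg.subject_noise_sd, size=n_sub))

    n_rows = n_sub * N_LEVELS * cfg.obs_per_subject_level
    subject_idx = np.repeat(np.arange(n_sub), N_LEVELS * cfg.obs_per_subject_level)
    level = np.tile(np.repeat(np.arange(N_LEVELS), cfg.obs_per_subject_level), n_sub)

    clu = subject_cluster[subject_idx]

    def _t_noise(size):
        if np.isfinite(cfg.noise_df):
            unit = np.sqrt((cfg.noise_df - 2.0) / cfg.noise_df)
            return rng.standard_t(cfg.noise_df, size=size) * unit
        return rng.normal(size=size)

    # trial-level effective response: the stimulus the physiology actually
    # expresses, jittered around the nominal level with heavy tails
    effective = level + cfg.response_noise_sd * _t_noise(n_rows)
    mean = (cluster_means[clu]
            + subject_effects[subject_idx]
            + cfg.effect_size * cluster_loadings[clu] * effective[:, None])
    noise_sd = (cfg.noise_sd_base * (1.0 + cfg.heteroscedasticity * level)
                * subject_noise_scale[subject_idx])
    X = mean + _t_noise((n_rows, n_feat)) * noise_sd[:, None]

    label = level.astype(float)
    if cfg.label_jitter > 0:
        label = np.clip(
            label + rng.uniform(-cfg.label_jitter, cfg.label_jitter, n_rows),
            0.0, 4.0)

    if cfg.missing_rate > 0:
        hit = rng.random(n_rows) < cfg.missing_rate
        cols = rng.integers(0, n_feat, size=n_rows)
        X[hit, cols[hit]] = np.nan

    df = pd.DataFrame(X, columns=feature_columns(n_feat))
    df.insert(0, "subject_id", pd.Categorical([f"S{i + 1:03d}" for i in subject_idx]))
    df.insert(1, "pain_label", label)
    df.insert(2, "cluster_truth", pd.Categorical(clu))
    return df


def clean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows containing any missing value; reset the row index."""
    return table.dropna(axis=0, how="any").reset_index(drop=True)


def generate_known_quantile_regression(
    n: int,
    noise: str = "gaussian",
    seed: int = 0,
    sigma: float = 1.0,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """One-dimensional regression with known conditional quantiles.

    ``y = f(x) + eps`` with ``f(x) = 2 + 1.2 sin(2 pi x)`` on x ~ U(0, 1).
    The noise is centred Gaussian with sd ``sigma`` (``noise="gaussian"``)
    or ``sigma * (0.5 + x)`` (``noise="heteroscedastic"``).  The returned
    frame carries the true central ``1 - alpha`` interval per row in
    ``oracle_lower`` / ``oracle_upper``, so empirical coverage of the
    oracle converges to ``1 - alpha``.

    Raises ``ValueError`` for ``n < 10`` or an unknown noise model.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n)
    f = 2.0 + 1.2 * np.sin(2.0 * np.pi * x)
    if noise == "gaussian":
        sd = np.full(n, float(sigma))
    elif noise == "heteroscedastic":
        sd = sigma * (0.5 + x)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    y = f + rng.normal(size=n) * sd
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return pd.DataFrame({
        "x": x,
        "y": y,
        "f_true": f,
        "oracle_lower": f - z * sd,
        "oracle_upper": f + z * sd,
    })


# -- CSV round-trips ------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = pd.Categorical(df["subject_id"])
    if "cluster_truth" in df.columns:
        df["cluster_truth"] = pd.Categorical(df["cluster_truth"])
    return df
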