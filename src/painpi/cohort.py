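"""Model-building regimes over a multi-subject cohort.

Three regimes are supported: a *generalized* model trained on the whole
cohort, *personalized* models trained per subject, and a *hybrid* regime
that first groups subjects by k-means on their 110-dimensional summary
vectors (22 feature means x 5 pain levels) and trains one model per
cluster.  New subjects are routed to the nearest centroid.

The k-means here is a plain Lloyd loop with Euclidean distance, random
centroid initialisation, seeded restarts, and an explicit empty-cluster
rule (re-seed at the point farthest from its assigned centroid).  It is
written out rather than delegated so the per-iteration inertia trace, the
lowest-index tie-break and the empty-cluster behaviour are part of the
contract; the test suite cross-checks its solutions against an
independent library implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .losses import LossSParams
from .network import IntervalNet, predict_intervals
from .metrics import IntervalBatch
from .preprocessing import MinMaxScaler, build_subject_vectors
from .train import GDParams, train_soft_gd

__all__ = ["ClusterModel", "CohortModelSet", "kmeans_subjects",
           "assign_subject", "pairwise_distance_stats",
           "build_cohort_models"]

log = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """Fitted k-means over subject vectors."""

    k: int
    centroids: np.ndarray                  # (k, d)
    assignments: dict[str, int]            # subject_id -> cluster index
    inertia: float
    inertia_trace: list[float] = field(default_factory=list)

    def labels_for(self, subject_ids) -> np.ndarray:
        return np.array([self.assignments[str(s)] for s in subject_ids])


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300):
    """One Lloyd run: returns (centroids, labels, inertia, trace)."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        inertia = float(d2[np.arange(n), new_labels].sum())
        trace.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = X[members].mean(axis=0)
            else:
                farthest = int(d2[np.arange(n), labels].argmax())
                log.debug("empty cluster %d re-seeded at point %d", c, farthest)
                centroids[c] = X[farthest]
                labels[farthest] = c
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return centroids, labels, inertia, trace


def kmeans_subjects(vectors: pd.DataFrame, k: int, seed: int,
                    n_restarts: int = 10) -> ClusterModel:
    """Cluster subject vectors with Lloyd's algorithm, keeping the best of
    ``n_restarts`` seeded random initialisations (lowest inertia)."""
    X = vectors.to_numpy(dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        centroids, labels, inertia, trace = _lloyd(X, k, rng)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia, trace)
    centroids, labels, inertia, trace = best
    assignments = {str(s): int(c) for s, c in zip(vectors.index, labels)}
    return ClusterModel(k=k, centroids=centroids, assignments=assignments,
                        inertia=inertia, inertia_trace=trace)


def assign_subject(vector: np.ndarray, cm: ClusterModel) -> int:
    """Nearest-centroid cluster for one subject vector (ties -> lowest)."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.shape[0] != cm.centroids.shape[1]:
        raise ValueError(
            f"vector has {v.shape[0]} entries, centroids expect "
            f"{cm.centroids.shape[1]}")
    d2 = ((cm.centroids - v) ** 2).sum(axis=1)
    return int(d2.argmin())


def pairwise_distance_stats(vectors: pd.DataFrame,
                            assignments: dict[str, int]) -> pd.DataFrame:
    """Within-cluster pairwise Euclidean distance summaries.

    One row per cluster: pair count, mean, quartiles and the number of
    outlier pairs by the 1.5 x IQR rule.  Singleton clusters yield an
    all-NaN summary with a warning.
    """
    labels = vectors.index.map(lambda s: assignments[str(s)]).to_numpy()
    rows = []
    for c in sorted(set(assignments.values())):
        sub = vectors.to_numpy(dtype=float)[labels == c]
        if sub.shape[0] < 2:
            warnings.warn(f"cluster {c} has fewer than 2 subjects; "
                          "no pairwise distances", stacklevel=2)
            rows.append({"cluster": c, "n_subjects": sub.shape[0],
                         "n_pairs": 0, "mean": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "n_outliers": 0})
            continue
        d = pdist(sub)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        outliers = int(((d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr)).sum())
        rows.append({"cluster": c, "n_subjects": int(sub.shape[0]),
                     "n_pairs": int(d.size), "mean": float(d.mean()),
                     "q1": float(q1), "median": float(med), "q3": float(q3),
                     "n_outliers": outliers})
    return pd.DataFrame(rows)


@dataclass
class CohortModelSet:
    """Trained interval models plus the regime they were built under."""

    regime: str                      # generalized | personalized | hybrid
    models: dict                     # key -> IntervalNet
    scaler: MinMaxScaler
    feature_cols: list[str]
    cluster_model: ClusterModel | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("generalized", "personalized", "hybrid"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "hybrid" and self.cluster_model is None:
            raise ValueError("hybrid regime requires a cluster model")

    def model_for_row(self, subject_id: str):
        if self.regime == "generalized":
            return self.models["all"]
        if self.regime == "personalized":
            return self.models.get(str(subject_id))
        cluster = self.cluster_model.assignments[str(subject_id)]
        return self.models[cluster]

    def predict(self, table: pd.DataFrame):
        """Interval bounds for every row of a feature table."""
        Xn = self.scaler.transform(table[self.feature_cols]).to_numpy()
        y = table["pain_label"].to_numpy(dtype=float)
        lower = np.full(len(table), np.nan)
        upper = np.full(len(table), np.nan)
        for sid in table["subject_id"].astype(str).unique():
            model = self.model_for_row(sid)
            if model is None:
                continue
            mask = (table["subject_id"].astype(str) == sid).to_numpy()
            batch = predict_intervals(model, Xn[mask], y[mask])
            lower[mask] = batch.lower
            upper[mask] = batch.upper
        keep = ~np.isnan(lower)
        return IntervalBatch(lower[keep], upper[keep], y[keep])


def build_cohort_models(
    table: pd.DataFrame,
    regime: str,
    loss_params: LossSParams | None = None,
    gd_params: GDParams | None = None,
    k: int = 4,
    hidden_layers=(32, 32),
    min_rows_personalized: int = 25,
    seed: int = 0,
) -> CohortModelSet:
    """Train soft-loss interval models under one of the three regimes.

    generalized
        One model on all rows.
    personalized
        One model per subject on that subject's rows; subjects with fewer
        than ``min_rows_personalized`` rows are skipped with a warning.
    hybrid
        k-means on the subject summary vectors (normalized features),
        then one model per cluster on its members' rows.

    Features are min-max normalized with a scaler fitted on ``table``;
    cross-validated evaluation of regimes lives in
    :func:`painpi.evaluation.evaluate_method`.
    """
    loss_params = loss_params or LossSParams()
    gd_params = gd_params or GDParams(seed=seed)
    feat = [c for c in table.columns
            if c not in ("subject_id", "pain_label", "cluster_truth")]
    scaler = MinMaxScaler().fit(table[feat])
    norm = table.copy()
    norm[feat] = scaler.transform(table[feat])
    X = norm[feat].to_numpy(dtype=float)
    y = norm["pain_label"].to_numpy(dtype=float)
    subjects = norm["subject_id"].astype(str)

    def fit(Xs, ys, sub_seed):
        net = IntervalNet(Xs.shape[1], hidden_layers, seed=sub_seed)
        gd = GDParams(learning_rate=gd_params.learning_rate,
                      decay=gd_params.decay, epochs=gd_params.epochs,
                      batch_size=gd_params.batch_size, seed=sub_seed,
                      grad_tol=gd_params.grad_tol)
        net, _ = train_soft_gd(net, Xs, ys, loss_params, gd)
        return net

    if regime == "generalized":
        return CohortModelSet("generalized", {"all": fit(X, y, seed)},
                              scaler, feat)
    if regime == "personalized":
        models = {}
        for i, sid in enumerate(sorted(subjects.unique())):
            mask = (subjects == sid).to_numpy()
            if mask.sum() < min_rows_personalized:
                warnings.warn(
                    f"subject {sid} has {int(mask.sum())} rows "
                    f"(< {min_rows_personalized}); skipped", stacklevel=2)
                continue
            models[sid] = fit(X[mask], y[mask], seed + 1 + i)
        return CohortModelSet("personalized", models, scaler, feat)
    if regime == "hybrid":
        vectors = build_subject_vectors(norm, feat)
        cm = kmeans_subjects(vectors, k=k, seed=seed)
        models = {}
        for c in range(cm.k):
            members = {s for s, lab in cm.assignments.items() if lab == c}
            mask = subjects.isin(members).to_numpy()
            # k = 1 must reduce exactly to the generalized regime
            sub_seed = seed if cm.k == 1 else seed + 1000 + c
            models[c] = fit(X[mask], y[mask], sub_seed)
        return CohortModelSet("hybrid", models, scaler, feat, cluster_model=cm)
    raise ValueError(f"unknown regime {regime!r}")
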