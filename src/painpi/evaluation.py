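"""Hyperparameter search, cross-validated comparison, and reporting.

``evaluate_method`` runs stratified K-fold cross-validation of one
interval method (soft-loss GD, LUBE GA, or bootstrap) under one
model-building regime (generalized, personalized, hybrid), at each
requested nominal confidence level.  To target a nominal level the
confidence hyperparameter mu is set to that level and the achieved
(empirical) coverage is always reported alongside it.

``hyperparameter_search`` is a seeded random search over the printed
tuning ranges; its trace doubles as the data for width-versus-coverage
scatter diagnostics.

``report`` writes the result tables (summary, per-level mean bounds,
per-cluster blocks) as CSV plus a full-precision JSON and a grouped bar
chart of widths by nominal level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapParams, bootstrap_pi
from .cohort import kmeans_subjects
from .losses import LossLParams, LossSParams
from .metrics import IntervalBatch, PIQuality
from .metrics import mpiw as mpiw_of
from .metrics import picp as picp_of
from .network import IntervalNet, predict_intervals
from .preprocessing import MinMaxScaler, build_subject_vectors, tenfold_splits
from .train import GAParams, GDParams, train_lube_ga, train_soft_gd

__all__ = ["SearchSpace", "hyperparameter_search", "evaluate_method",
           "aggregate_rows", "report", "width_at_coverage",
           "compare_methods_on_cohort", "softening_factor_sweep",
           "binned_softening_gain"]

METHODS = ("loss_s", "loss_l", "bootstrap")
REGIMES = ("generalized", "personalized", "hybrid")
NOMINALS = (0.50, 0.75, 0.85, 0.95)


@dataclass(frozen=True)
class SearchSpace:
    """Tuning ranges for the network, the GA/LUBE loss, and the GD/soft loss.

    The defaults are the published search spaces: 1-4 hidden layers of
    10-150 neurons with relu/tanh/linear activations; GA with 10-20
    solutions, 5-10 mating parents, 10-20% mutated genes, LUBE eta in
    [25, 100] and mu in [0.5, 0.95]; GD with learning rate [0.001, 0.1],
    decay [1e-6, 1e-4], soft-loss lambda [5, 30], eta [35, 240],
    mu [0.5, 0.95] and softening factor s [10, 220].
    """

    n_hidden_layers: tuple = (1, 4)
    n_neurons: tuple = (10, 150)
    activations: tuple = ("relu", "tanh", "linear")
    ga_n_solutions: tuple = (10, 20)
    ga_n_parents: tuple = (5, 10)
    ga_mutation_percent: tuple = (10, 20)
    loss_l_eta: tuple = (25, 100)
    mu: tuple = (0.5, 0.95)
    gd_learning_rate: tuple = (0.001, 0.1)
    gd_decay: tuple = (1e-6, 1e-4)
    loss_s_lam: tuple = (5, 30)
    loss_s_eta: tuple = (35, 240)
    loss_s_s: tuple = (10, 220)

    def sample_architecture(self, rng: np.random.Generator) -> dict:
        n_layers = int(rng.integers(self.n_hidden_layers[0],
                                    self.n_hidden_layers[1] + 1))
        return {
            "hidden_layers": tuple(int(rng.integers(self.n_neurons[0],
                                                    self.n_neurons[1] + 1))
                                   for _ in range(n_layers)),
            "activation": str(rng.choice(self.activations)),
        }

    def sample_config(self, method: str, rng: np.random.Generator,
                      mu: float | None = None) -> dict:
        """Draw one configuration for ``method`` uniformly from the space.

        ``mu`` pins the confidence level (the usual case when targeting a
        nominal coverage); left ``None`` it is sampled from its range.
        """
        cfg = self.sample_architecture(rng)
        cfg["mu"] = float(rng.uniform(*self.mu)) if mu is None else float(mu)
        if method == "loss_s":
            cfg.update(
                learning_rate=float(np.exp(rng.uniform(
                    np.log(self.gd_learning_rate[0]),
                    np.log(self.gd_learning_rate[1])))),
                decay=float(np.exp(rng.uniform(np.log(self.gd_decay[0]),
                                               np.log(self.gd_decay[1])))),
                lam=float(rng.uniform(*self.loss_s_lam)),
                eta=float(rng.uniform(*self.loss_s_eta)),
                s=float(rng.uniform(*self.loss_s_s)),
            )
        elif method == "loss_l":
            cfg.update(
                n_solutions=int(rng.integers(self.ga_n_solutions[0],
                                             self.ga_n_solutions[1] + 1)),
                n_parents_mating=int(rng.integers(self.ga_n_parents[0],
                                                  self.ga_n_parents[1] + 1)),
                mutation_percent_genes=float(rng.uniform(
                    *self.ga_mutation_percent)),
                eta=float(rng.uniform(*self.loss_l_eta)),
            )
        else:
            raise ValueError(f"no search space for method {method!r}")
        return cfg


def hyperparameter_search(space: SearchSpace, budget: int, objective,
                          seed: int = 0, method: str = "loss_s",
                          mu: float | None = None):
    """Seeded random search; returns (best config, trace frame).

    ``objective(config)`` must return a mapping with at least ``"loss"``
    (lower is better); any extra keys (e.g. picp/mpiw) are carried into
    the trace for scatter diagnostics.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    best_cfg, best_loss = None, np.inf
    for trial in range(budget):
        cfg = space.sample_config(method, rng, mu=mu)
        result = dict(objective(cfg))
        loss = float(result["loss"])
        records.append({"trial": trial, **{k: v for k, v in cfg.items()},
                        **result})
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    return best_cfg, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# cross-validated method evaluation


def _fit_predict(method: str, X_tr, y_tr, X_te, y_te, nominal: float,
                 seed: int, cfg: dict) -> IntervalBatch:
    """Train one model of ``method`` at confidence ``nominal``; predict."""
    hidden = cfg.get("hidden_layers", (32, 32))
    activation = cfg.get("activation", "relu")
    if method == "loss_s":
        net = IntervalNet(X_tr.shape[1], hidden, activation, seed=seed)
        lp = LossSParams(lam=cfg.get("lam", 10.0), eta=cfg.get("eta", 50.0),
                         alpha=1.0 - nominal, s=cfg.get("s", 60.0))
        gd = GDParams(learning_rate=cfg.get("learning_rate", 0.01),
                      decay=cfg.get("decay", 1e-3),
                      epochs=cfg.get("epochs", 800),
                      batch_size=cfg.get("batch_size", 128), seed=seed,
                      pretrain_epochs=cfg.get("pretrain_epochs", 150))
        net, _ = train_soft_gd(net, X_tr, y_tr, lp, gd)
        return predict_intervals(net, X_te, y_te)
    if method == "loss_l":
        net = IntervalNet(X_tr.shape[1], hidden, activation, seed=seed)
        lp = LossLParams(eta=cfg.get("eta", 50.0), mu=nominal,
                         target_range=cfg.get("target_range", 4.0))
        ga = GAParams(n_solutions=cfg.get("n_solutions", 16),
                      n_parents_mating=cfg.get("n_parents_mating", 6),
                      mutation_percent_genes=cfg.get(
                          "mutation_percent_genes", 15.0),
                      n_generations=cfg.get("n_generations", 120), seed=seed)
        net, _ = train_lube_ga(net, X_tr, y_tr, lp, ga)
        return predict_intervals(net, X_te, y_te)
    if method == "bootstrap":
        bp = BootstrapParams(B=cfg.get("B", 20), nominal=nominal,
                             hidden_layers=hidden, activation=activation,
                             epochs=cfg.get("epochs", 100),
                             batch_size=cfg.get("batch_size", 128),
                             learning_rate=cfg.get("learning_rate", 0.01),
                             seed=seed)
        return bootstrap_pi(X_tr, y_tr, X_te, bp).as_batch(y_te)
    raise ValueError(f"unknown method {method!r}")


def _level_bound_rows(batch: IntervalBatch, base: dict) -> list[dict]:
    levels = np.clip(np.round(batch.target), 0, 4).astype(int)
    rows = []
    for lvl in np.unique(levels):
        m = levels == lvl
        rows.append({**base, "level": int(lvl),
                     "mean_lower": float(batch.lower[m].mean()),
                     "mean_upper": float(batch.upper[m].mean()),
                     "n_obs": int(m.sum())})
    return rows


def _cv_one_group(method, sub: pd.DataFrame, feat, nominal, seed, cfg,
                  n_folds, base: dict, target_range, max_folds=None):
    """K-fold CV within one row group (whole cohort / subject / cluster)."""
    rows, level_rows = [], []
    splits = tenfold_splits(sub, seed=seed, n_splits=n_folds)
    if max_folds is not None:
        splits = splits[:max_folds]
    X_all = sub[feat].to_numpy(dtype=float)
    y_all = sub["pain_label"].to_numpy(dtype=float)
    for fold, (tr, te) in enumerate(splits):
        scaler = MinMaxScaler().fit(X_all[tr])
        X_tr, X_te = scaler.transform(X_all[tr]), scaler.transform(X_all[te])
        batch = _fit_predict(method, X_tr, y_all[tr], X_te, y_all[te],
                             nominal, seed + fold, cfg)
        q = PIQuality.from_batch(batch, nominal, target_range)
        rows.append({**base, "fold": fold, "n_obs": len(batch), **q.as_row()})
        level_rows.extend(_level_bound_rows(batch, {**base, "fold": fold}))
    return rows, level_rows


def evaluate_method(
    method: str,
    regime: str,
    table: pd.DataFrame,
    nominal_levels=NOMINALS,
    seed: int = 0,
    n_folds: int = 10,
    config: dict | None = None,
    k: int = 4,
    target_range: float = 4.0,
    min_rows_personalized: int = 25,
    max_folds: int | None = None,
):
    """Cross-validated PI quality of one method under one regime.

    Returns ``(rows, level_bounds)``: per-(group, fold, nominal) metric
    rows and per-pain-level mean bounds.  Groups are the whole cohort
    (generalized), subjects (personalized) or k-means clusters (hybrid);
    clustering precedes the train/test splits and uses a cohort-wide
    scaler, while per-fold model training always normalizes on the
    training split only.  ``max_folds`` evaluates only the first few of
    the ten folds — the split construction is unchanged — to bound
    compute in simulation studies.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected {METHODS}")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected {REGIMES}")
    cfg = dict(config or {})
    feat = [c for c in table.columns
            if c not in ("subject_id", "pain_label", "cluster_truth")]

    groups: list[tuple[str | int, pd.DataFrame]]
    cluster_sizes: dict[int, int] = {}
    if regime == "generalized":
        groups = [("all", table)]
    elif regime == "personalized":
        groups = []
        for sid, sub in table.groupby(table["subject_id"].astype(str)):
            if len(sub) < min_rows_personalized:
                continue
            groups.append((sid, sub))
    else:
        scaler = MinMaxScaler().fit(table[feat])
        norm = table.copy()
        norm[feat] = scaler.transform(table[feat])
        vectors = build_subject_vectors(norm, feat)
        cm = kmeans_subjects(vectors, k=k, seed=seed)
        groups = []
        sid_series = table["subject_id"].astype(str)
        for c in range(cm.k):
            members = {s for s, lab in cm.assignments.items() if lab == c}
            cluster_sizes[c] = len(members)
            groups.append((c, table[sid_series.isin(members)]))

    rows, level_rows = [], []
    for nominal in nominal_levels:
        for gid, sub in groups:
            base = {"regime": regime, "method": method, "nominal": nominal,
                    "group": gid, "seed": seed}
            if regime == "hybrid":
                base["n_subjects_in_group"] = cluster_sizes[gid]
            r, lr = _cv_one_group(method, sub.reset_index(drop=True), feat,
                                  nominal, seed, cfg, n_folds, base,
                                  target_range, max_folds=max_folds)
            rows.extend(r)
            level_rows.extend(lr)
    return (pd.DataFrame.from_records(rows),
            pd.DataFrame.from_records(level_rows))


def aggregate_rows(rows: pd.DataFrame, by=("regime", "method", "nominal"),
                   weighted: bool = False) -> pd.DataFrame:
    """Aggregate fold/group metric rows to summary rows.

    Default is the unweighted mean of fold metrics; ``weighted=True``
    weights by observation count instead (pooled recomputation), which
    conserves per-cluster metrics into cohort metrics.
    """
    by = list(by)
    metrics = ["picp", "mpiw", "nmpiw", "crossing_fraction"]

    def agg(g: pd.DataFrame) -> pd.Series:
        w = g["n_obs"].to_numpy(float) if weighted else np.ones(len(g))
        out = {m: float(np.average(g[m], weights=w)) for m in metrics}
        out["n_obs"] = int(g["n_obs"].sum())
        return pd.Series(out)

    return (rows.groupby(by, observed=True, sort=True)
            .apply(agg, include_groups=False).reset_index())


def softening_factor_sweep(table: pd.DataFrame, seed: int,
                           n_trials: int = 24, mu: float = 0.85,
                           epochs: int = 60,
                           pretrain_epochs: int = 20) -> pd.DataFrame:
    """Random sweep of the soft-loss dials, recording soft quality.

    Samples ``n_trials`` configurations from the printed tuning ranges
    (confidence level pinned at ``mu``), trains each briefly on the whole
    table, and records the softening factor with the resulting soft width
    MPIW_S and soft coverage PICP_S — the scatter used to study how the
    softening factor trades coverage against width.
    """
    from .losses import loss_S_bound_grads

    feat = [c for c in table.columns
            if c not in ("subject_id", "pain_label", "cluster_truth")]
    X = MinMaxScaler().fit_transform(table[feat]).to_numpy()
    y = table["pain_label"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    space = SearchSpace()
    records = []
    for trial in range(n_trials):
        c = space.sample_config("loss_s", rng, mu=mu)
        p = LossSParams(lam=c["lam"], eta=c["eta"], alpha=1.0 - mu, s=c["s"])
        net = IntervalNet(X.shape[1], (16, 16), seed=trial)
        net, _ = train_soft_gd(
            net, X, y, p,
            GDParams(epochs=epochs, pretrain_epochs=pretrain_epochs,
                     learning_rate=min(c["learning_rate"], 0.05),
                     decay=c["decay"], seed=trial))
        out = net.forward(X)
        batch = IntervalBatch(out[:, 0], out[:, 1], y)
        _, _, _, info = loss_S_bound_grads(batch, p)
        records.append({"s": c["s"], "mpiw_s": info["mpiw_s"],
                        "picp_s": info["picp_s"]})
    return pd.DataFrame.from_records(records)


def binned_softening_gain(sweeps: pd.DataFrame, s_mid: float = 115.0,
                          n_bins: int = 3) -> float:
    """Mean soft-coverage gain of high-s over low-s configurations within
    matched soft-width bins (NaN if no bin holds both groups)."""
    widths = sweeps["mpiw_s"].to_numpy()
    covs = sweeps["picp_s"].to_numpy()
    high = sweeps["s"].to_numpy() > s_mid
    edges = np.quantile(widths, np.linspace(0, 1, n_bins + 1))
    gains = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (widths >= lo) & (widths <= hi)
        if (in_bin & high).any() and (in_bin & ~high).any():
            gains.append(covs[in_bin & high].mean()
                         - covs[in_bin & ~high].mean())
    return float(np.mean(gains)) if gains else float("nan")


def width_at_coverage(picps, mpiws, target: float) -> float:
    """Interpolated mean interval width at a matched achieved coverage.

    Fits a piecewise-linear width-versus-coverage curve through a
    method's (achieved PICP, MPIW) pairs across nominal levels and reads
    it at ``target``.  Outside the achieved range the nearest segment is
    extended linearly, so a method that never reaches the target coverage
    is charged the width its own trend implies rather than its endpoint.
    """
    order = np.argsort(picps)
    p = np.asarray(picps, dtype=float)[order]
    w = np.asarray(mpiws, dtype=float)[order]
    if len(p) == 0:
        raise ValueError("no (coverage, width) points")
    if len(p) == 1 or np.ptp(p) < 1e-9:
        return float(w.mean())
    if target <= p[0]:
        slope = (w[1] - w[0]) / (p[1] - p[0])
        return float(w[0] + slope * (target - p[0]))
    if target >= p[-1]:
        slope = (w[-1] - w[-2]) / (p[-1] - p[-2])
        return float(w[-1] + slope * (target - p[-1]))
    return float(np.interp(target, p, w))


def compare_methods_on_cohort(
    table: pd.DataFrame,
    seed: int = 0,
    nominal_levels=NOMINALS,
    match_coverage: float = 0.85,
    configs: dict | None = None,
) -> pd.DataFrame:
    """Width-versus-coverage comparison of the three methods on one split.

    Each method is trained at every nominal level on the same 90/10
    train/test split (the bootstrap ensemble is trained once and re-read
    at each level, since only the z multiplier changes); widths are then
    compared at ``match_coverage`` via :func:`width_at_coverage`.
    Returns one row per method with achieved coverages, mean widths and
    the matched-coverage width.
    """
    configs = configs or {}
    feat = [c for c in table.columns
            if c not in ("subject_id", "pain_label", "cluster_truth")]
    splits = tenfold_splits(table, seed=seed, n_splits=10)
    tr, te = splits[0]
    X = table[feat].to_numpy(dtype=float)
    y = table["pain_label"].to_numpy(dtype=float)
    scaler = MinMaxScaler().fit(X[tr])
    X_tr, X_te = scaler.transform(X[tr]), scaler.transform(X[te])

    rows = []
    for method in METHODS:
        cfg = dict(configs.get(method, {}))
        picps, widths = [], []
        if method == "bootstrap":
            bp = BootstrapParams(B=cfg.get("B", 20), nominal=0.5,
                                 hidden_layers=cfg.get("hidden_layers",
                                                       (32, 32)),
                                 epochs=cfg.get("epochs", 100),
                                 learning_rate=cfg.get("learning_rate", 0.01),
                                 seed=seed)
            res = bootstrap_pi(X_tr, y[tr], X_te, bp)
            from scipy import stats as _st
            half_unit = (res.upper - res.lower) / (
                2.0 * _st.norm.ppf(0.5 + bp.nominal / 2.0))
            for nom in nominal_levels:
                z = _st.norm.ppf(0.5 + nom / 2.0)
                batch = IntervalBatch(res.mean - z * half_unit,
                                      res.mean + z * half_unit, y[te])
                picps.append(picp_of(batch))
                widths.append(mpiw_of(batch))
        else:
            for nom in nominal_levels:
                batch = _fit_predict(method, X_tr, y[tr], X_te, y[te],
                                     nom, seed, cfg)
                picps.append(picp_of(batch))
                widths.append(mpiw_of(batch))
        rows.append({
            "method": method, "seed": seed,
            "achieved_picp": picps, "mpiw": widths,
            "width_at_match": width_at_coverage(picps, widths,
                                                match_coverage),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def report(rows: pd.DataFrame, level_bounds: pd.DataFrame | None,
           outdir: str | Path, target_range: float = 4.0) -> dict:
    """Write summary tables, per-level bounds, cluster blocks and figures.

    Produces ``summary.csv`` (nominal x PICP/MPIW/NMPIW per regime and
    method, 2-decimal display), ``level_bounds.csv`` (mean lower/upper
    bound per pain level), ``cluster_summary.csv`` (one block per cluster,
    only when hybrid rows are present), ``results.json`` (full precision)
    and ``width_by_nominal.png``.  Deterministic: re-running on the same
    rows writes byte-identical CSV/JSON.
    """
    if rows.empty:
        raise ValueError("no result rows to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    summary = aggregate_rows(rows)
    summary_disp = summary.copy()
    for c in ("picp", "mpiw", "nmpiw", "crossing_fraction"):
        summary_disp[c] = summary_disp[c].round(2)
    path = outdir / "summary.csv"
    summary_disp.to_csv(path, index=False)
    written["summary"] = path

    if level_bounds is not None and not level_bounds.empty:
        lb = (level_bounds
              .groupby(["regime", "method", "nominal", "level"],
                       observed=True, sort=True)[["mean_lower", "mean_upper"]]
              .mean().round(2).reset_index())
        path = outdir / "level_bounds.csv"
        lb.to_csv(path, index=False)
        written["level_bounds"] = path

    hybrid = rows[rows["regime"] == "hybrid"]
    if not hybrid.empty:
        blocks = aggregate_rows(hybrid, by=("group", "nominal"))
        if "n_subjects_in_group" in hybrid.columns:
            sizes = (hybrid.groupby("group", observed=True)
                     ["n_subjects_in_group"].first())
            blocks.insert(1, "n_subjects", blocks["group"].map(sizes).values)
        blocks = blocks.rename(columns={"group": "cluster"})
        for c in ("picp", "mpiw", "nmpiw", "crossing_fraction"):
            blocks[c] = blocks[c].round(2)
        path = outdir / "cluster_summary.csv"
        blocks.to_csv(path, index=False)
        written["cluster_summary"] = path

    payload = {
        "rows": rows.to_dict(orient="records"),
        "summary": summary.to_dict(orient="records"),
        "target_range": target_range,
    }
    path = outdir / "results.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default))
    written["json"] = path

    written["figure"] = _width_bar_chart(summary, outdir)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _width_bar_chart(summary: pd.DataFrame, outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    combos = summary[["regime", "method"]].drop_duplicates()
    nominals = sorted(summary["nominal"].unique())
    width = 0.8 / max(1, len(combos))
    xs = np.arange(len(nominals))
    for i, (_, combo) in enumerate(combos.iterrows()):
        sel = summary[(summary["regime"] == combo["regime"])
                      & (summary["method"] == combo["method"])]
        vals = [float(sel[sel["nominal"] == nom]["mpiw"].mean())
                if (sel["nominal"] == nom).any() else np.nan
                for nom in nominals]
        ax.bar(xs + i * width, vals, width,
               label=f"{combo['regime']}/{combo['method']}")
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels([f"{int(100 * n)}%" for n in nominals])
    ax.set_xlabel("nominal coverage")
    ax.set_ylabel("MPIW")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "width_by_nominal.png"
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
    return path
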