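"""Feature normalization, subject summary vectors, and CV splits."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .synthetic import N_LEVELS

__all__ = ["MinMaxScaler", "build_subject_vectors", "tenfold_splits"]


class MinMaxScaler:
    """Per-feature min-max normalization fitted on a training split.

    ``transform`` maps the fitting data into [0, 1] per feature; values
    outside the fitted range extrapolate linearly (no clipping), which
    keeps the map affine and invertible everywhere.  Fitting a feature
    with a single distinct value raises, naming the feature.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None
        self.columns_: list[str] | None = None

    @staticmethod
    def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        return np.asarray(X, dtype=float), None

    def fit(self, X) -> "MinMaxScaler":
        arr, cols = self._as_array(X)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D feature block")
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        constant = np.flatnonzero(hi <= lo)
        if constant.size:
            names = ([cols[j] for j in constant] if cols is not None
                     else [f"column {j}" for j in constant])
            raise ValueError(
                "constant feature(s) cannot be min-max scaled: "
                + ", ".join(names))
        self.min_, self.max_, self.columns_ = lo, hi, cols
        return self

    def _check(self, arr: np.ndarray) -> None:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        if arr.shape[1] != self.min_.shape[0]:
            raise ValueError(
                f"expected {self.min_.shape[0]} features, got {arr.shape[1]}")

    def transform(self, X):
        arr, _ = self._as_array(X)
        self._check(arr)
        out = (arr - self.min_) / (self.max_ - self.min_)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, columns=X.columns, index=X.index)
        return out

    def inverse_transform(self, X):
        arr, _ = self._as_array(X)
        self._check(arr)
        out = arr * (self.max_ - self.min_) + self.min_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, columns=X.columns, index=X.index)
        return out

    def fit_transform(self, X):
        return self.fit(X).transform(X)

    # -- JSON round-trip --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        payload = json.dumps({
            "min": self.min_.tolist(),
            "max": self.max_.tolist(),
            "columns": self.columns_,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MinMaxScaler":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        sc = cls()
        sc.min_ = np.asarray(d["min"], dtype=float)
        sc.max_ = np.asarray(d["max"], dtype=float)
        sc.columns_ = d["columns"]
        return sc


def fit_minmax(table: pd.DataFrame, feature_cols: list[str]) -> MinMaxScaler:
    """Fit a :class:`MinMaxScaler` on the feature block of a training table."""
    return MinMaxScaler().fit(table[feature_cols])


def build_subject_vectors(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject summary vectors: level-wise feature means, concatenated.

    For every subject the entry for (level ``l``, feature ``j``) is the
    mean of feature ``j`` over that subject's level-``l`` rows; levels are
    concatenated in fixed order 0..4, giving 110 entries for 22 features.
    The table is expected to hold normalized features.  A subject missing
    any pain level raises, listing subject and level.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ("subject_id", "pain_label", "cluster_truth")]
    level = table["pain_label"].round().astype(int)
    if (level < 0).any() or (level >= N_LEVELS).any():
        raise ValueError("pain labels round outside levels 0..4")

    grouped = (table[feature_cols]
               .groupby([table["subject_id"].astype(str), level], observed=True)
               .mean())
    subjects = sorted(table["subject_id"].astype(str).unique())
    missing = [(s, l) for s in subjects for l in range(N_LEVELS)
               if (s, l) not in grouped.index]
    if missing:
        listing = ", ".join(f"{s}:level {l}" for s, l in missing[:10])
        raise ValueError(f"subject(s) missing a pain level: {listing}")

    cols = [f"{f}_L{l}" for l in range(N_LEVELS) for f in feature_cols]
    data = np.empty((len(subjects), len(cols)))
    for i, s in enumerate(subjects):
        data[i] = np.concatenate(
            [grouped.loc[(s, l)].to_numpy() for l in range(N_LEVELS)])
    out = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"),
                       columns=cols)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("subject vectors contain non-finite entries")
    return out


def tenfold_splits(
    table: pd.DataFrame,
    seed: int,
    n_splits: int = 10,
    stratify_by: str = "level",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold split indices over the rows of a feature table.

    Folds partition the rows; each row appears in exactly one test fold.
    ``stratify_by="level"`` (default) stratifies on the rounded pain level
    so every fold sees all five levels; ``stratify_by="subject"``
    stratifies on the subject id instead.  When a stratum holds fewer
    rows than there are folds (small per-subject tables), plain shuffled
    folds are used instead.  Deterministic given ``seed``.
    """
    n = len(table)
    if n < n_splits:
        raise ValueError(f"need at least {n_splits} rows, got {n}")
    if stratify_by == "level":
        strata = table["pain_label"].round().astype(int).to_numpy()
    elif stratify_by == "subject":
        strata = table["subject_id"].astype(str).to_numpy()
    else:
        raise ValueError(f"unknown stratification policy {stratify_by!r}")
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < n_splits:
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n)))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), strata)]


def splits_to_frame(splits) -> pd.DataFrame:
    """Fold assignments as a (row_id, fold) frame for CSV export."""
    records = [(int(i), fold) for fold, (_, test) in enumerate(splits)
               for i in test]
    return (pd.DataFrame(records, columns=["row_id", "fold"])
            .sort_values("row_id", ignore_index=True))
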