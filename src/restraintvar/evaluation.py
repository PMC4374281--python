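"""Scoring predicted restraint variability against true distance deviations.

The central report is the Pearson correlation between predicted sigma and
the actual deviation dd = |d_native - d_template|, computed per
(target, category) group and macro-averaged per category over targets (the
mean of per-target r values, so every target counts equally regardless of
its restraint count).

Two baselines/diagnostics accompany it: a histogram ("bin-and-average")
predictor in the style of classic alignment-quality lookup tables, and a
top-k retrain that checks how much of the forest's accuracy survives when
only its k most important features are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest import RegressionForest, fit_forest, predict_forest
from .io_formats import CATEGORIES

log = logging.getLogger(__name__)

DEFAULT_BIN_FEATURES = ("F3", "F4", "F8", "F9")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; nan when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationReport:
    """Per-(target, category) Pearson r plus per-category macro-averages."""

    per_group: pd.DataFrame  # columns: target, category, r, n
    macro: pd.DataFrame  # columns: category, mean_r, n_targets

    def macro_r(self, category: str) -> float:
        row = self.macro[self.macro["category"] == category]
        if row.empty:
            return float("nan")
        return float(row["mean_r"].iloc[0])


def correlation_report(
    df: pd.DataFrame,
    sigma_col: str = "sigma",
    label_col: str = "dd",
) -> CorrelationReport:
    """Correlate predicted sigma with dd per (target, category) group.

    *df* needs columns ``protein``, ``category``, *sigma_col*, *label_col*.
    Groups with fewer than 3 instances, or with an undefined correlation,
    are omitted with a log entry.  Output ordering is deterministic
    (category canonical order, then target id).
    """
    rows = []
    for (target, category), grp in df.groupby(["protein", "category"], sort=True):
        if len(grp) < 3:
            log.info("group (%s, %s): only %d instances, omitted", target, category, len(grp))
            continue
        r = pearson_r(grp[sigma_col], grp[label_col])
        if np.isnan(r):
            log.info("group (%s, %s): correlation undefined, omitted", target, category)
            continue
        rows.append({"target": target, "category": category, "r": r, "n": len(grp)})
    per_group = pd.DataFrame(rows, columns=["target", "category", "r", "n"])
    if not per_group.empty:
        per_group["category"] = pd.Categorical(
            per_group["category"], categories=list(CATEGORIES), ordered=True
        )
        per_group = per_group.sort_values(["category", "target"]).reset_index(drop=True)
        macro = (
            per_group.groupby("category", observed=True)
            .agg(mean_r=("r", "mean"), n_targets=("r", "size"))
            .reset_index()
        )
    else:
        macro = pd.DataFrame(columns=["category", "mean_r", "n_targets"])
    return CorrelationReport(per_group=per_group, macro=macro)


class HistogramModel:
    """Bin-and-average predictor over up to four named features.

    Training rows are binned on the selected features (equal-frequency bin
    edges by default); a prediction is the mean label of the test row's bin.
    Empty bins fall back to the nearest non-empty bin along the first
    feature (smaller index preferred on distance ties), then to the global
    training mean.
    """

    def __init__(
        self,
        features=DEFAULT_BIN_FEATURES,
        n_bins: int = 10,
        strategy: str = "quantile",
    ):
        if not 1 <= len(features) <= 4:
            raise ValueError("bin spec must name 1..4 features")
        if strategy not in ("quantile", "width"):
            raise ValueError(f"unknown binning strategy {strategy!r}")
        self.features = tuple(features)
        self.n_bins = n_bins
        self.strategy = strategy

    def fit(self, X: pd.DataFrame, y) -> "HistogramModel":
        for f in self.features:
            if f not in X.columns:
                raise ValueError(f"unknown feature name {f!r}")
        y = np.asarray(y, dtype=float)
        self.edges_ = []
        for f in self.features:
            col = X[f].to_numpy(dtype=float)
            if self.strategy == "quantile":
                qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
                edges = np.quantile(col, qs)
            else:
                edges = np.linspace(col.min(), col.max(), self.n_bins + 1)[1:-1]
            self.edges_.append(edges)
        keys = self._bin_keys(X)
        sums: dict[tuple, float] = {}
        cnts: dict[tuple, int] = {}
        for key, val in zip(map(tuple, keys), y):
            sums[key] = sums.get(key, 0.0) + val
            cnts[key] = cnts.get(key, 0) + 1
        self.bin_means_ = {k: sums[k] / cnts[k] for k in sums}
        self.global_mean_ = float(y.mean())
        return self

    def _bin_keys(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for f, edges in zip(self.features, self.edges_):
            cols.append(np.searchsorted(edges, X[f].to_numpy(dtype=float), side="right"))
        return np.stack(cols, axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        keys = self._bin_keys(X)
        out = np.empty(len(keys))
        for i, key in enumerate(map(tuple, keys)):
            if key in self.bin_means_:
                out[i] = self.bin_means_[key]
                continue
            found = None
            for d in range(1, self.n_bins):
                for b0 in (key[0] - d, key[0] + d):
                    cand = (b0,) + key[1:]
                    if cand in self.bin_means_:
                        found = self.bin_means_[cand]
                        break
                if found is not None:
                    break
            out[i] = found if found is not None else self.global_mean_
        return out


def histogram_baseline(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    features=DEFAULT_BIN_FEATURES,
    n_bins: int = 10,
    strategy: str = "quantile",
) -> np.ndarray:
    """Fit the histogram predictor and return test predictions."""
    model = HistogramModel(features, n_bins, strategy).fit(X_train, y_train)
    return model.predict(X_test)


@dataclass
class TopKComparison:
    k: int
    selected: list[str]  # feature names, importance-descending
    macro_full: float
    macro_topk: float

    @property
    def ratio(self) -> float:
        return self.macro_topk / self.macro_full


def _macro_r(pred, y, groups) -> float:
    df = pd.DataFrame({"protein": groups, "category": "ALL", "sigma": pred, "dd": y})
    rows = []
    for target, grp in df.groupby("protein", sort=True):
        if len(grp) < 3:
            continue
        r = pearson_r(grp["sigma"], grp["dd"])
        if not np.isnan(r):
            rows.append(r)
    return float(np.mean(rows)) if rows else float("nan")


def topk_retrain(
    full_forest: RegressionForest,
    importances: np.ndarray,
    feature_names,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    test_groups,
    k: int,
    seed: int | None = None,
) -> TopKComparison:
    """Retrain on the top-k features and compare macro-average r.

    Selects the k features with the largest raw importances (ties toward the
    lower feature index), retrains with the full forest's hyperparameters
    and seed on those columns only, and reports the per-target macro-average
    Pearson r of both forests on the test set, plus their ratio.  With
    k = number of features the retrain is identical and the ratio is exactly
    1.
    """
    p = len(feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if len(importances) != p:
        raise ValueError("importances length mismatch")
    order = np.argsort(-np.asarray(importances), kind="stable")
    sel = np.sort(order[:k])
    seed = full_forest.seed if seed is None else seed
    sub = fit_forest(
        np.asarray(X_train, float)[:, sel],
        y_train,
        params=full_forest.params,
        seed=seed,
        category=full_forest.category,
    )
    pred_full = predict_forest(full_forest, np.asarray(X_test, float))
    pred_topk = predict_forest(sub, np.asarray(X_test, float)[:, sel])
    return TopKComparison(
        k=k,
        selected=[feature_names[i] for i in order[:k]],
        macro_full=_macro_r(pred_full, y_test, test_groups),
        macro_topk=_macro_r(pred_topk, y_test, test_groups),
    )
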