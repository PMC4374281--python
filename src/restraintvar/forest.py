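"""From-scratch random-forest regression with OOB error and permutation
importance.

Trees are CART regression trees: the best split of a node maximises the
reduction of the sum of squared deviations (SSD) of the labels; candidate
thresholds are midpoints between consecutive distinct sorted values of each
candidate feature; values <= threshold route left.  Ties between equal gains
are broken toward the lowest feature index, then the lowest threshold.
Growth stops when a node holds <= min_leaf instances, its labels are
constant, or no split has positive gain; a leaf predicts the mean of the
in-bag labels routed to it, and the forest predicts the arithmetic mean over
trees.

Defaults follow the reference configuration for this problem: 200 trees,
mtry = 6 of 20 features sampled per node, min_leaf = 5, and a bootstrap that
draws ceil(2n/3) samples with replacement per tree (a classic n-draw
bootstrap is available via ``classic_bootstrap``).  Out-of-bag (OOB)
instances of a tree are those never drawn for it; they provide the OOB mean
squared error and the permutation importance (mean increase of a tree's OOB
MSE after randomly permuting one feature among its OOB rows).

Everything is deterministic given a seed: per-tree random substreams are
derived from (seed, tree ordinal).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ForestParams:
    n_trees: int = 200
    mtry: int = 6
    min_leaf: int = 5
    bootstrap_fraction: float = 2.0 / 3.0
    bootstrap: bool = True  # False: in-bag = all rows, no OOB
    classic_bootstrap: bool = False  # True: n draws instead of ceil(frac*n)
    max_instances: int | None = None  # seeded subsample before training

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.max_instances is not None and self.max_instances < 10:
            raise ValueError("max_instances must be >= 10")


@dataclass
class RegressionTree:
    """Array-of-nodes regression tree plus its bag bookkeeping.

    ``feature[i] >= 0`` marks an internal node; leaves have feature -1 and
    carry the in-bag label mean in ``value``.
    """

    feature: np.ndarray  # int32, -1 for leaves
    threshold: np.ndarray  # float64
    left: np.ndarray  # int32 child ids
    right: np.ndarray
    value: np.ndarray  # float64 leaf means (0 for internal nodes)
    count: np.ndarray  # int32 in-bag instances per node
    in_bag: np.ndarray  # index multiset drawn for this tree
    oob: np.ndarray  # indices never drawn

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.intp)
        while True:
            feat = self.feature[node]
            active = np.nonzero(feat >= 0)[0]
            if active.size == 0:
                break
            nd = node[active]
            go_left = X[active, self.feature[nd]] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[node]

    def used_features(self) -> set[int]:
        return set(int(f) for f in self.feature if f >= 0)


@dataclass
class RegressionForest:
    trees: list[RegressionTree]
    params: ForestParams
    seed: int
    n_features: int
    oob_mse: float  # nan when bootstrap is disabled
    category: str | None = None
    raw_importances: np.ndarray | None = None
    subsample: np.ndarray | None = None  # max_instances row selection, if any

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_forest(self, X)

    # -- JSON-friendly serialisation ---------------------------------------

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "n_trees": p.n_trees,
                "mtry": p.mtry,
                "min_leaf": p.min_leaf,
                "bootstrap_fraction": p.bootstrap_fraction,
                "bootstrap": p.bootstrap,
                "classic_bootstrap": p.classic_bootstrap,
                "max_instances": p.max_instances,
            },
            "seed": self.seed,
            "n_features": self.n_features,
            "oob_mse": None if math.isnan(self.oob_mse) else self.oob_mse,
            "category": self.category,
            "raw_importances": (
                None
                if self.raw_importances is None
                else [float(v) for v in self.raw_importances]
            ),
            "subsample": None if self.subsample is None else self.subsample.tolist(),
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "count": t.count.tolist(),
                    "in_bag": t.in_bag.tolist(),
                    "oob": t.oob.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionForest":
        params = ForestParams(**d["params"])
        trees = [
            RegressionTree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=np.float64),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                value=np.asarray(t["value"], dtype=np.float64),
                count=np.asarray(t["count"], dtype=np.int32),
                in_bag=np.asarray(t["in_bag"], dtype=np.int64),
                oob=np.asarray(t["oob"], dtype=np.int64),
            )
            for t in d["trees"]
        ]
        imp = d.get("raw_importances")
        sub = d.get("subsample")
        return cls(
            trees=trees,
            params=params,
            seed=d["seed"],
            n_features=d["n_features"],
            oob_mse=float("nan") if d["oob_mse"] is None else float(d["oob_mse"]),
            category=d.get("category"),
            raw_importances=None if imp is None else np.asarray(imp, dtype=float),
            subsample=None if sub is None else np.asarray(sub, dtype=np.int64),
        )


def find_best_split(
    X: np.ndarray, y: np.ndarray, candidates
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) over the candidate features, or None.

    The gain is the parent SSD minus the summed child SSDs; thresholds are
    midpoints between consecutive distinct sorted values.  Returns None when
    no split has strictly positive gain (e.g. constant labels, or constant
    candidate features).  Ties break toward the lowest feature index, then
    the lowest threshold; gains are compared up to a tiny relative tolerance
    so that mathematically tied splits (which round differently in floating
    point) tie-break deterministically.
    """
    n = len(y)
    if n < 2 or np.ptp(y) == 0:
        return None
    total = y.sum()
    parent = total * total / n
    best: tuple[float, int, float] | None = None
    for f in sorted(int(c) for c in candidates):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cum = np.cumsum(y[order])
        pos = np.nonzero(xs[1:] != xs[:-1])[0] + 1  # left block size
        if pos.size == 0:
            continue
        sl = cum[pos - 1]
        nl = pos.astype(float)
        sr = total - sl
        nr = n - nl
        gain = sl * sl / nl + sr * sr / nr - parent
        g_max = float(gain.max())
        tol = 1e-12 * max(1.0, abs(g_max))
        j = int(np.argmax(gain >= g_max - tol))  # first within-tolerance max
        g = float(gain[j])
        if best is None or g > best[0] + 1e-12 * max(1.0, abs(g), abs(best[0])):
            a, b = float(xs[pos[j] - 1]), float(xs[pos[j]])
            thr = (a + b) / 2.0
            if thr >= b:  # midpoint rounded up to b: routing would empty a child
                thr = a
            best = (g, f, thr)
    if best is None or best[0] <= 0:
        return None
    return best[1], best[2], best[0]


def _build_tree(
    Xb: np.ndarray,
    yb: np.ndarray,
    rng: np.random.Generator,
    params: ForestParams,
) -> tuple[np.ndarray, ...]:
    """Grow one tree on the in-bag data; returns the node arrays."""
    p = Xb.shape[1]
    mtry = min(params.mtry, p)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    count: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        count.append(0)
        return len(feature) - 1

    root = new_node()
    # LIFO stack, children pushed right-then-left so the left subtree is
    # processed first; rng draws therefore follow a fixed depth-first order
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(len(yb)))]
    while stack:
        node, idx = stack.pop()
        ynode = yb[idx]
        count[node] = len(idx)
        split = None
        if len(idx) > params.min_leaf and np.ptp(ynode) != 0:
            cand = rng.choice(p, size=mtry, replace=False)
            split = find_best_split(Xb[idx], ynode, cand)
        if split is None:
            value[node] = float(ynode.mean())
            continue
        f, thr, _ = split
        feature[node] = f
        threshold[node] = thr
        mask = Xb[idx, f] <= thr
        lid = new_node()
        rid = new_node()
        left[node] = lid
        right[node] = rid
        stack.append((rid, idx[~mask]))
        stack.append((lid, idx[mask]))

    return (
        np.asarray(feature, dtype=np.int32),
        np.asarray(threshold, dtype=np.float64),
        np.asarray(left, dtype=np.int32),
        np.asarray(right, dtype=np.int32),
        np.asarray(value, dtype=np.float64),
        np.asarray(count, dtype=np.int32),
    )


def _tree_rng(seed: int, tree_ordinal: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, tree_ordinal)))


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams | None = None,
    seed: int = 0,
    category: str | None = None,
) -> RegressionForest:
    """Train a regression forest; fully deterministic given *seed*."""
    params = params if params is not None else ForestParams()
    params.validate()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(y) < 10:
        raise ValueError(f"need at least 10 instances, got {len(y)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    subsample = None
    if params.max_instances is not None and len(y) > params.max_instances:
        sub_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, 0)))
        subsample = np.sort(
            sub_rng.choice(len(y), size=params.max_instances, replace=False)
        ).astype(np.int64)
        X, y = X[subsample], y[subsample]

    n = len(y)
    trees: list[RegressionTree] = []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    for t in range(params.n_trees):
        rng = _tree_rng(seed, t)
        if params.bootstrap:
            k = n if params.classic_bootstrap else int(math.ceil(params.bootstrap_fraction * n))
            in_bag = rng.integers(0, n, size=k)
            oob = np.setdiff1d(np.arange(n), in_bag, assume_unique=False)
        else:
            in_bag = np.arange(n)
            oob = np.empty(0, dtype=np.int64)
        arrays = _build_tree(X[in_bag], y[in_bag], rng, params)
        tree = RegressionTree(*arrays, in_bag=in_bag.astype(np.int64), oob=oob.astype(np.int64))
        if oob.size:
            oob_sum[oob] += tree.predict(X[oob])
            oob_cnt[oob] += 1
        trees.append(tree)

    covered = oob_cnt > 0
    if covered.any():
        resid = oob_sum[covered] / oob_cnt[covered] - y[covered]
        oob_mse = float(np.mean(resid**2))
    else:
        oob_mse = float("nan")
    return RegressionForest(
        trees=trees,
        params=params,
        seed=seed,
        n_features=X.shape[1],
        oob_mse=oob_mse,
        category=category,
        subsample=subsample,
    )


def predict_forest(forest: RegressionForest, X: np.ndarray) -> np.ndarray:
    """Per-row arithmetic mean of the tree outputs."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"expected {forest.n_features} feature columns, got {X.shape}"
        )
    acc = np.zeros(len(X))
    for tree in forest.trees:
        acc += tree.predict(X)
    return acc / len(forest.trees)


def permutation_importance(
    forest: RegressionForest,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Raw permutation importance per feature (mean OOB-MSE increase).

    For each tree with a non-empty OOB set and each feature, the tree's MSE
    on its OOB rows is re-evaluated with that feature's OOB values randomly
    permuted; the importance of the feature is the mean (over trees) of the
    permuted-minus-intact MSE difference.  A feature used by no tree scores
    exactly 0.  Deterministic given *seed*.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1] != forest.n_features:
        raise ValueError("feature count mismatch")
    if forest.subsample is not None and len(X) != len(forest.subsample):
        # caller passed the pre-subsample training set; apply the recorded
        # selection so tree bag indices line up
        X, y = X[forest.subsample], y[forest.subsample]
    p = forest.n_features
    diffs = np.zeros(p)
    used_trees = 0
    for t, tree in enumerate(forest.trees):
        oob = tree.oob
        if oob.size == 0:
            warnings.warn("tree with empty OOB set skipped in importance")
            continue
        used_trees += 1
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        used = tree.used_features()
        for f in range(p):
            if f not in used:
                continue  # routing cannot change; difference is exactly 0
            # substream per (tree, feature): importances of one feature are
            # unaffected by the presence of other (unused) columns
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(2, t, f))
            )
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            mse = np.mean((tree.predict(Xp) - yo) ** 2)
            diffs[f] += mse - base
    if used_trees == 0:
        warnings.warn("no tree had OOB data; importances undefined, returning zeros")
        return np.zeros(p)
    return diffs / used_trees
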