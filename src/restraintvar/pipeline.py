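"""Orchestration: simulate -> extract -> train -> predict -> evaluate.

These functions are the library behind the command-line interface; they
operate on a benchmark directory with the layout written by
:func:`restraintvar.synthetic.write_benchmark`::

    benchdir/
      manifest.json
      proteins/<id>/template.pdb  native.pdb  alignment.fasta
                    match_scores.tsv  target.ss2  target_burial.tsv
                    template_annot.tsv

and on in-memory :class:`~restraintvar.synthetic.Benchmark` objects.  Fixed
output filenames: ``model.json``, ``train_features.tsv``,
``test_features.tsv``, ``restraints.tsv``, ``report_correlations.tsv``,
``report_importance.tsv``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, restraints, synthetic
from .forest import ForestParams, RegressionForest, fit_forest, permutation_importance, predict_forest
from .io_formats import (
    CATEGORIES,
    PairwiseAlignment,
    ResidueProfiles,
    StructureModel,
    load_forests,
    read_alignment,
    read_profiles,
    read_structure,
    save_forests,
    write_restraint_table,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (mirrors the CLI flags)."""

    benchmark_dir: Path
    output_dir: Path
    categories: tuple[str, ...] = CATEGORIES
    n_trees: int = 200
    mtry: int = 6
    min_leaf: int = 5
    bootstrap_fraction: float = 2.0 / 3.0
    max_instances: int | None = 20000
    seed: int = 0
    sigma_floor: float = 0.05
    sigma_cap: float = 15.0
    consistency_mode: str = "prob"
    baseline_features: tuple[str, ...] = evaluation.DEFAULT_BIN_FEATURES
    baseline_bins: int = 10

    def forest_params(self) -> ForestParams:
        p = ForestParams(
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_leaf=self.min_leaf,
            bootstrap_fraction=self.bootstrap_fraction,
            max_instances=self.max_instances,
        )
        p.validate()
        return p

    def validate(self) -> None:
        self.forest_params()
        if self.consistency_mode not in ("prob", "delta"):
            raise ValueError("consistency_mode must be 'prob' or 'delta'")
        if not (self.sigma_floor > 0 and self.sigma_cap >= self.sigma_floor):
            raise ValueError("need 0 < sigma_floor <= sigma_cap")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")


@dataclass
class ProteinData:
    protein_id: str
    alignment: PairwiseAlignment
    template: StructureModel
    profiles: ResidueProfiles
    native: StructureModel | None = None


def load_benchmark_dir(path: str | Path) -> tuple[list[ProteinData], dict]:
    """Read every protein of a benchmark directory plus its manifest."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    proteins = []
    for pid in manifest["train_ids"] + manifest["test_ids"]:
        d = path / "proteins" / pid
        native_path = d / "native.pdb"
        proteins.append(
            ProteinData(
                protein_id=pid,
                alignment=read_alignment(d / "alignment.fasta", d / "match_scores.tsv"),
                template=read_structure(d / "template.pdb"),
                profiles=read_profiles(
                    d / "target.ss2", d / "target_burial.tsv", d / "template_annot.tsv"
                ),
                native=read_structure(native_path) if native_path.exists() else None,
            )
        )
    return proteins, manifest


def extract_frame(
    proteins,
    categories: tuple[str, ...] = CATEGORIES,
    mode: str = "prob",
    with_labels: bool = True,
) -> pd.DataFrame:
    """Enumerate, (optionally) label and featurise restraints per protein."""
    frames = []
    for pd_ in proteins:
        inst = restraints.enumerate_restraint_pairs(
            pd_.alignment, pd_.template, tuple(categories)
        )
        if with_labels:
            if pd_.native is None:
                raise ValueError(f"{pd_.protein_id}: labels requested but no native")
            inst = restraints.label_instances(inst, pd_.alignment, pd_.native)
        if not inst:
            continue
        frames.append(
            features.feature_matrix(
                inst, pd_.alignment, pd_.profiles, mode, protein_id=pd_.protein_id
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=list(features._METADATA_COLUMNS) + list(features.FEATURE_NAMES)
        )
    return pd.concat(frames, ignore_index=True)


def _protein_data(sp: synthetic.SyntheticProtein) -> ProteinData:
    return ProteinData(
        protein_id=sp.protein_id,
        alignment=sp.alignment,
        template=sp.template,
        profiles=sp.profiles,
        native=sp.native,
    )


def benchmark_frames(
    bench: synthetic.Benchmark,
    categories: tuple[str, ...] = CATEGORIES,
    mode: str = "prob",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(train, test) feature frames of an in-memory benchmark."""
    train = extract_frame([_protein_data(sp) for sp in bench.train], categories, mode)
    test = extract_frame([_protein_data(sp) for sp in bench.test], categories, mode)
    return train, test


# ---------------------------------------------------------------------------
# train / predict / evaluate on feature frames
# ---------------------------------------------------------------------------


def train_forests(
    df: pd.DataFrame,
    categories: tuple[str, ...],
    params: ForestParams,
    seed: int,
    with_importance: bool = True,
) -> dict[str, RegressionForest]:
    """One forest per category with labelled instances; empties are skipped."""
    forests: dict[str, RegressionForest] = {}
    cols = list(features.FEATURE_NAMES)
    for cat in CATEGORIES:
        if cat not in categories:
            continue
        sub = df[df["category"] == cat]
        if len(sub) < 10:
            log.warning("category %s: %d instances, skipped", cat, len(sub))
            continue
        X = sub[cols].to_numpy(dtype=float)
        y = sub["dd"].to_numpy(dtype=float)
        forest = fit_forest(X, y, params=params, seed=seed, category=cat)
        if with_importance:
            forest.raw_importances = permutation_importance(forest, X, y, seed=seed)
        forests[cat] = forest
    return forests


def predict_sigma(
    forests: dict[str, RegressionForest], df: pd.DataFrame
) -> pd.DataFrame:
    """Attach a ``sigma`` column of per-instance forest predictions."""
    cols = list(features.FEATURE_NAMES)
    out = df.copy()
    out["sigma"] = np.nan
    for cat, forest in forests.items():
        mask = out["category"] == cat
        if not mask.any():
            continue
        out.loc[mask, "sigma"] = predict_forest(
            forest, out.loc[mask, cols].to_numpy(dtype=float)
        )
    missing = out["sigma"].isna()
    if missing.any():
        raise ValueError(
            f"no trained forest for categories {sorted(out.loc[missing, 'category'].unique())}"
        )
    return out


def frame_to_instances(df: pd.DataFrame) -> list[restraints.RestraintInstance]:
    return [
        restraints.RestraintInstance(
            category=r.category,
            I=int(r.I),
            J=int(r.J),
            K=int(r.K),
            L=int(r.L),
            role_1=r.role_1,
            role_2=r.role_2,
            d_template=float(r.d_template),
            dd=None if pd.isna(r.dd) else float(r.dd),
            sigma=None if pd.isna(getattr(r, "sigma", np.nan)) else float(r.sigma),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# directory-level commands (the CLI surface)
# ---------------------------------------------------------------------------


def run_simulate(
    outdir: str | Path,
    n_proteins: int,
    length_range: tuple[int, int],
    seed: int,
    params: synthetic.GeneratorParams | None = None,
) -> synthetic.Benchmark:
    bench = synthetic.generate_benchmark(
        n_proteins, length_range, params=params, seed=seed
    )
    synthetic.write_benchmark(bench, outdir)
    return bench


def run_extract(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    config.validate()
    proteins, manifest = load_benchmark_dir(config.benchmark_dir)
    by_id = {p.protein_id: p for p in proteins}
    train = extract_frame(
        [by_id[i] for i in manifest["train_ids"]],
        config.categories,
        config.consistency_mode,
        with_labels=True,
    )
    test = extract_frame(
        [by_id[i] for i in manifest["test_ids"]],
        config.categories,
        config.consistency_mode,
        with_labels=all(by_id[i].native is not None for i in manifest["test_ids"]),
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    train.to_csv(out / "train_features.tsv", sep="\t", index=False)
    test.to_csv(out / "test_features.tsv", sep="\t", index=False)
    return train, test


def _read_features(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def run_train(config: RunConfig) -> dict[str, RegressionForest]:
    """Train per-category forests; writes model.json and reports."""
    config.validate()
    out = Path(config.output_dir)
    train_path = out / "train_features.tsv"
    if not train_path.exists():
        run_extract(config)
    df = _read_features(train_path)
    df = df.dropna(subset=["dd"])
    if df.empty:
        raise ValueError("training requires labelled instances (native structures)")
    forests = train_forests(
        df, config.categories, config.forest_params(), config.seed
    )
    save_forests(forests, out / "model.json")
    report = pd.DataFrame(
        {
            "category": list(forests),
            "n_instances": [
                int((df["category"] == c).sum()) for c in forests
            ],
            "n_used": [
                len(f.subsample) if f.subsample is not None else int((df["category"] == c).sum())
                for c, f in forests.items()
            ],
            "oob_mse": [f.oob_mse for f in forests.values()],
        }
    )
    report.to_csv(out / "report_training.tsv", sep="\t", index=False)
    imp = pd.DataFrame(
        {"feature": list(features.FEATURE_NAMES)}
        | {
            cat: forests[cat].raw_importances
            for cat in forests
            if forests[cat].raw_importances is not None
        }
    )
    imp.to_csv(out / "report_importance.tsv", sep="\t", index=False)
    return forests


def run_predict_evaluate(config: RunConfig) -> dict:
    """Predict sigma on the test split, write restraints and reports."""
    config.validate()
    out = Path(config.output_dir)
    forests = load_forests(out / "model.json")
    test = _read_features(out / "test_features.tsv")
    if test.empty:
        raise ValueError("no test instances")
    missing = set(test["category"].unique()) - set(forests)
    if missing:
        raise ValueError(f"model has no forest for categories {sorted(missing)}")
    pred = predict_sigma(forests, test)
    instances = frame_to_instances(pred)
    table = restraints.write_restraints_with_sigma(
        instances, floor=config.sigma_floor, cap=config.sigma_cap
    )
    write_restraint_table(table, out / "restraints.tsv")

    result: dict = {"n_restraints": len(table)}
    if pred["dd"].notna().all():
        report = evaluation.correlation_report(pred)
        train = _read_features(out / "train_features.tsv").dropna(subset=["dd"])
        rows = []
        for cat in sorted(set(pred["category"])):
            tr = train[train["category"] == cat]
            te = pred[pred["category"] == cat].copy()
            if len(tr) < 10:
                continue
            te["sigma"] = evaluation.histogram_baseline(
                tr,
                tr["dd"].to_numpy(float),
                te,
                features=config.baseline_features,
                n_bins=config.baseline_bins,
            )
            rows.append(evaluation.correlation_report(te).per_group.assign(method="histogram"))
        base = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        full = report.per_group.assign(method="forest")
        combined = pd.concat([full, base], ignore_index=True)
        combined.to_csv(out / "report_correlations.tsv", sep="\t", index=False)
        result["forest_macro"] = {
            c: report.macro_r(c) for c in sorted(set(pred["category"]))
        }
        if not base.empty:
            result["baseline_macro"] = {
                c: float(base[base["category"] == c]["r"].mean())
                for c in sorted(set(base["category"]))
            }
    else:
        log.info("test natives unavailable: restraints written, evaluation skipped")
        result["evaluation"] = "skipped (no labels)"
    return result


def run_all(config: RunConfig, n_proteins: int, length_range=(80, 200)) -> dict:
    run_simulate(config.benchmark_dir, n_proteins, length_range, config.seed)
    run_extract(config)
    run_train(config)
    return run_predict_evaluate(config)


# ---------------------------------------------------------------------------
# the scaled-down benchmark study (used by the acceptance machinery)
# ---------------------------------------------------------------------------


def run_benchmark_study(
    seed: int = 1,
    n_proteins: int = 60,
    length_range: tuple[int, int] = (80, 200),
    category: str = "CACA",
    n_trees: int = 100,
    mtry: int = 6,
    min_leaf: int = 5,
    max_instances: int | None = 20000,
    topk: int = 10,
    params: synthetic.GeneratorParams | None = None,
) -> dict:
    """Generate a benchmark, train one category, and evaluate end to end.

    Returns per-protein correlation results for the forest and the
    histogram baseline, raw permutation importances, and the top-k retrain
    comparison.
    """
    bench = synthetic.generate_benchmark(
        n_proteins, length_range, params=params, seed=seed
    )
    train_df, test_df = benchmark_frames(bench, (category,))
    fp = ForestParams(
        n_trees=n_trees, mtry=mtry, min_leaf=min_leaf, max_instances=max_instances
    )
    cols = list(features.FEATURE_NAMES)
    X_train = train_df[cols].to_numpy(float)
    y_train = train_df["dd"].to_numpy(float)
    X_test = test_df[cols].to_numpy(float)
    y_test = test_df["dd"].to_numpy(float)

    forest = fit_forest(X_train, y_train, params=fp, seed=seed, category=category)
    importances = permutation_importance(forest, X_train, y_train, seed=seed)
    forest.raw_importances = importances

    pred = test_df.copy()
    pred["sigma"] = predict_forest(forest, X_test)
    report = evaluation.correlation_report(pred)

    base = test_df.copy()
    base["sigma"] = evaluation.histogram_baseline(
        train_df, y_train, test_df
    )
    base_report = evaluation.correlation_report(base)

    comparison = evaluation.topk_retrain(
        forest,
        importances,
        cols,
        X_train,
        y_train,
        X_test,
        y_test,
        test_df["protein"].to_numpy(),
        k=topk,
        seed=seed,
    )
    order = np.argsort(-importances, kind="stable")
    ranks = {cols[i]: int(rank + 1) for rank, i in enumerate(order)}
    return {
        "bench": bench,
        "category": category,
        "n_train_instances": len(train_df),
        "n_test_instances": len(test_df),
        "forest": forest,
        "importances": importances,
        "importance_ranks": ranks,
        "forest_report": report,
        "forest_macro_r": report.macro_r(category),
        "baseline_report": base_report,
        "baseline_macro_r": base_report.macro_r(category),
        "topk": comparison,
        "oob_mse": forest.oob_mse,
    }
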