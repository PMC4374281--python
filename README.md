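# restraintvar

Predicting the variability of distance restraints in template-based protein
modeling with a from-scratch random-forest regressor.

## The problem

In single-template comparative modeling, the model chain is built by
optimizing spatial restraints copied from a homologous solved structure
(the template): for a pair of aligned residues, the inter-atomic distance
*d* of the target is restrained toward the template distance *d′* with a
harmonic term

V(d) = ½ ((d − d′) / σ)²,

the negative log of a Gaussian probability density for the deviation
Δd = |d_native − d_template|.  The width σ decides how strongly each
restraint is enforced.  Restraints taken from well-aligned, conserved
regions deserve a small σ; restraints crossing badly aligned or shifted
regions deserve a large one, otherwise they trap the optimizer away from
the native structure.  Estimating σ accurately from the alignment alone is
therefore the crux of restraint-based chain building, and is the job of
this package.

`restraintvar` predicts σ = ⟨Δd⟩ per restraint with a random-forest
regressor over 20 features of the target–template alignment: sequence
separation, template distance, per-position profile match scores and their
span average, gap counts and nearest-gap reciprocals in both alignment
rows, predicted-vs-observed secondary-structure and burial consistency,
and three composite products of these.  The predicted mean absolute
deviation converts exactly to the Gaussian standard deviation used by
harmonic-restraint packages through σ_sd = √(π/2) · ⟨Δd⟩.

Restraints come in four atom-pair categories with template-distance
cutoffs: Cα–Cα (14.5 Å), amide-N–carbonyl-O (10.0 Å), main-chain–side-chain
(8.0 Å) and side-chain–side-chain (5.0 Å), with the side chain represented
by its heavy-atom centroid; one forest is trained per category.

The forest is written from scratch (CART regression trees, variance-
reduction splits at midpoint thresholds, 200 trees by default, 6 of 20
features sampled per node, leaves of ≤ 5 instances, a ⌈2n/3⌉-draw bootstrap
with out-of-bag error, and OOB permutation importance), because the
training procedure and the importance estimates are the scientific content
here — scikit-learn appears only as an independent cross-check in the test
suite.

Because real training data (non-redundant native structures plus fold-
recognition alignments) cannot ship with a package, `restraintvar`
includes a synthetic benchmark generator that emulates it end to end:
self-avoiding template traces, natives displaced according to a latent
per-residue quality track, alignments with gap blocks and register errors,
match scores and profiles degraded in proportion to the same track.  Every
file format (PDB, gapped FASTA, ss2-style profiles, TSVs, model JSON) is
read and written, so the pipeline runs identically on real inputs.

## Worked example

```python
from restraintvar import generate_benchmark, fit_forest, predict_forest, ForestParams
from restraintvar.pipeline import benchmark_frames
from restraintvar.evaluation import correlation_report, histogram_baseline
from restraintvar.features import FEATURE_NAMES

bench = generate_benchmark(n_proteins=20, length_range=(80, 160), seed=0)
train, test = benchmark_frames(bench, ("CACA",))
cols = list(FEATURE_NAMES)
forest = fit_forest(
    train[cols].to_numpy(), train["dd"].to_numpy(),
    ForestParams(n_trees=60, mtry=6, min_leaf=5, max_instances=20000),
    seed=0, category="CACA",
)
pred = test.copy()
pred["sigma"] = predict_forest(forest, test[cols].to_numpy())
report = correlation_report(pred)
base = test.copy()
base["sigma"] = histogram_baseline(train, train["dd"].to_numpy(), test)
print(f"train/test instances: {len(train)}/{len(test)}")
print(f"OOB MSE: {forest.oob_mse:.3f} A^2")
print(report.per_group.to_string(index=False))
print(f"forest macro r:   {report.macro_r('CACA'):.3f}")
print(f"baseline macro r: {correlation_report(base).macro_r('CACA'):.3f}")
```

prints

```
train/test instances: 17792/5771
OOB MSE: 1.343 A^2
target category        r    n
  P004     CACA 0.251931 1714
  P005     CACA 0.181712 1486
  P012     CACA 0.252688 1336
  P016     CACA 0.232817 1235
forest macro r:   0.230
baseline macro r: 0.077
```

Sixteen training proteins yield ~18k Cα–Cα restraint instances; on the
four held-out proteins the predicted σ correlates with the true deviation
Δd at r ≈ 0.18–0.25 per protein (macro-average 0.230), three times the
correlation achieved by a classic four-feature histogram ("bin and
average") baseline on the same data (0.077).  The OOB mean squared error
is the forest's internal estimate of E[(σ − Δd)²] in Å².

The same pipeline is scriptable from the shell:

```sh
restraintvar simulate --outdir bench --n-proteins 20 --seed 0
restraintvar run-all --benchmark-dir bench --output-dir out --seed 0 \
    --categories caca,no,ms,ss
```

which writes `model.json`, per-instance `restraints.tsv` (σ clipped to
[0.05, 15] Å), `report_correlations.tsv` and `report_importance.tsv` under
`out/`.

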