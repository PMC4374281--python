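# Methods

## Model

A restraint ties the distance *d* between two target atoms to the
corresponding template distance *d′* with the harmonic energy
V(d) = ½((d − d′)/σ)².  This is the negative log-likelihood of a Gaussian
model for the deviation Δd = |d_native − d_template|, so σ should estimate
the typical size of that deviation.  `restraintvar` regresses
σ = ⟨Δd⟩ directly; the exact half-normal identity
⟨|X|⟩ = √(2/π)·σ_sd for X ~ N(0, σ_sd²) converts predictions to and from
the Gaussian-standard-deviation convention used by restraint optimizers
(`convert_sigma`, both directions, exact inverses).

Restraint instances are enumerated per category (Cα–Cα, N–O,
main-chain–side-chain, side-chain–side-chain) over all aligned residue
pairs whose *template* distance is strictly below 14.5 / 10.0 / 8.0 /
5.0 Å respectively.  The side chain is a single centroid pseudo-atom (SC,
mean of the side-chain heavy atoms); this keeps the target↔template atom
correspondence well defined under any residue substitution.  N–O and
CA–SC pairs are ordered (the two ends carry different atom roles); Cα–Cα
and SC–SC are unordered with I < J.  Same-residue pairs are excluded, and
no further minimum sequence separation is imposed.

## Features

Twenty features per instance, for target endpoints I < J aligned with
template endpoints K < L (ordered categories use the sorted endpoints for
the span and gap features):

| group | features |
| --- | --- |
| separation | F1 = \|I−J\|, F2 = F1 / N_res |
| geometry | F3 = d′ (Å) |
| alignment quality | F4 = m_I·m_J (product of endpoint match scores), F5 = mean match score over all aligned columns between and at the endpoints |
| gaps | F6/F10 = gap characters strictly between the endpoints in the target/template row, F7 = F6/F1, F11 = F10/\|K−L\|, F8/F9/F12/F13 = reciprocal column distance from each endpoint to its nearest same-row gap (0 for a gapless row, 1 for an adjacent gap) |
| profile consistency | F14/F15 = target's predicted probability of the template's observed secondary-structure state at each end; F16/F17 the same for two-state burial |
| composites | F18 = F4·F14·F15·F16·F17, F19 = F18/(1+F6+F10), F20 = F19/(1+F8+F9+F12+F13) |

Gap distances are measured in alignment columns (a gap occupies no residue
index, so a residue-index metric would be ill-defined); this reproduces the
natural limits — adjacent gap ⇒ 1, gapless row ⇒ 0.  F6/F10 count gap
*characters*, not gap blocks.  The consistency features default to the
probabilistic reading p(state_template); a `delta` mode (argmax match,
0/1) is available because the discrete reading is equally defensible —
both are implemented, neither is claimed canonical.

## Random forest

CART regression trees: a split maximises the reduction of the label sum of
squared deviations; candidate thresholds are midpoints between consecutive
distinct sorted values of each candidate feature; values ≤ threshold route
left; growth stops at ≤ `min_leaf` instances, constant labels, or no
positive-gain split; a leaf predicts its in-bag label mean and the forest
the arithmetic mean over trees.

Defaults: 200 trees; `mtry` = 6 features drawn without replacement per
*node*; `min_leaf` = 5; bootstrap = ⌈2n/3⌉ draws *with replacement* (the
classic n-draw bootstrap is a switch).  The never-drawn rows of each tree
form its out-of-bag (OOB) set, giving the OOB MSE and the permutation
importance: for each tree and feature, the increase of the tree's OOB MSE
after permuting that feature among the tree's OOB rows, averaged over
trees.  Raw (unnormalised) importances are reported.  `max_instances`
subsamples the training set uniformly without replacement before
training, mirroring the usual practice of training on a random fraction
of the available restraint instances.

Numerical choices:

* Gains are compared with a 1e-12 relative tolerance so that
  mathematically tied splits (whose floating-point gains round
  differently) tie-break deterministically toward the lowest feature
  index, then the lowest threshold.  The test suite holds the tree to an
  exhaustive-search CART oracle computed in exact rational arithmetic.
* A midpoint that rounds up to the right-hand value (adjacent floats)
  would empty a child; it falls back to the left value.
* Template and native distances are computed with one shared formula so
  that Δd is exactly zero when native and template coincide.
* All randomness flows from a single integer seed through named
  substreams ((seed, tree ordinal) for bags and node sampling, a separate
  stream for subsampling, per-(tree, feature) streams for importance
  permutations), so forests, model files and importances are bit-
  reproducible and importances of one feature are unaffected by the
  presence of unused columns.

Degenerate inputs: fewer than 10 training rows, non-finite labels or
features, and prediction-time column-count mismatches are errors; trees
whose OOB set is empty are skipped (with a warning) in OOB averages.

## Evaluation

Predicted σ is scored against the true Δd by Pearson correlation per
(protein, category) group; groups with fewer than 3 instances or zero
variance are omitted.  Category-level numbers are macro-averages (mean of
per-protein r), so each protein counts equally regardless of size.  Two
diagnostics accompany the forest: a histogram baseline that bins the
training instances on four features (default F3, F4, F8, F9; 10
equal-frequency bins each; empty bins fall back to the nearest non-empty
bin along the first feature, then the global mean) and predicts the bin
mean — the classic lookup-table approach to σ estimation, labelled
"histogram", not attributed to any specific package — and a top-k retrain
that keeps the k most important features and retrains with identical
hyperparameters and seed, reporting the ratio of macro-average r values
(with k = all features the ratio is exactly 1 by construction).

## Synthetic benchmark generator

The generator produces, per protein: a template Cα trace (3.8 Å steps,
bend angles uniform in [90°, 130°], random torsions, rejection of steps
closer than 3.5 Å to any earlier Cα, restart on dead ends), N/O
pseudo-atoms at fixed local-frame offsets (~1.4 Å and ~2.3 Å from Cα) and
an SC centroid at a perpendicular offset of U(1.5, 3.0) Å, absent with
probability 0.07 (such residues are glycines).

A latent per-residue quality track q ∈ (0,1) is piecewise constant over
segments of geometric length (mean 12) with values Beta(4, 2).  The
native is the template with per-residue rigid displacements of magnitude
|N(0, s(q))| with s(q) = 0.3·q + 6.0·(1−q) Å, directions smoothed along
the chain with a 5-residue window to mimic rigid-segment motion.  The
alignment is the identity mapping broken by gap blocks (probability 0.3
per segment boundary, length 1–5, assigned to either row with equal
probability) and, with probability 0.5 per protein, a ±1 register shift
across the lowest-quality segment — a misalignment that produces wrong
template distances without any displacement.  Match scores are
clamp(q + N(0, 0.15), 0, 1) per aligned column.  Profiles mix the true
one-hot state with a uniform distribution: p = (1−u)·onehot + u·uniform,
u = 0.6·(1−q); the template's observed states are the segment states
(H/E/C cycling) and a burial call from the 0.25 distance-to-centroid
quantile.  Everything is deterministic given a seed; benchmarks split
whole proteins 80/20 so that evaluation is strictly cross-protein.

What the generator emulates: the causal chain from local alignment
quality to restraint error, gap structure, register errors, and profile
degradation that co-varies with alignment quality.  What it does not:
real protein geometry (compactness, secondary-structure geometry,
side-chain packing), sequence-dependent substitution patterns, and
realistic predictor error models — in particular the profile features are
*deterministic* functions of the latent quality, i.e. cleaner than any
real secondary-structure predictor would be.  Passing benchmarks here
demonstrates that the pipeline recovers the planted statistical structure,
not that a particular correlation level carries over to real data.

Benchmark problem sizes: the standard study uses 60 proteins of length
80–200 (≈ 7×10⁴–8×10⁴ Cα–Cα instances), a 100-tree forest and a training
subsample of 20 000 instances — the package's scaled-down analogue of
training on a random fraction of a multi-million-instance restraint
database.

## Known limitations

* The benchmark's labels carry large irreducible noise: the per-residue
  displacement magnitude is a half-normal draw, so even the exact
  conditional mean E[Δd | latent state] correlates with the realized Δd
  only up to ≈ 0.36 mean per-protein r on held-out proteins (measured by
  regenerating the same proteins' displacements with fresh noise and
  correlating the two label realizations).  The forest reaches ≈ 0.30,
  i.e. ~84% of that ceiling; the histogram baseline reaches ≈ 0.18.
* Because the synthetic profile features read the latent quality without
  noise, the consistency features (F14–F17) and their composites dominate
  the permutation-importance ranking on synthetic data; the span-average
  match score F5 leads the match-score group but ranks behind them.  On
  real data, where profile predictions carry substantial independent
  error, the balance between these groups will differ.
* The generator's chains are more extended than real folds, so Cα–Cα
  restraints are biased toward short sequence separations.
* Restraint files are the package's own TSV; emitting another package's
  native restraint format is out of scope, as is the chain-building
  optimization itself.
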