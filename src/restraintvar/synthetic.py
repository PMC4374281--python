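"""Synthetic target--template benchmark generator.

Real training data for restraint-variability prediction consists of
non-redundant native structures, templates found by fold recognition, and
profile-profile alignments.  This module emulates that setting with full
control over the ground truth:

* a *template* chain is a self-avoiding CA trace (3.8 angstrom steps, bend
  angles 90--130 degrees) decorated with N/O pseudo-atoms at fixed
  local-frame offsets and a side-chain centroid SC at a perpendicular
  offset (absent for a small fraction of residues, which become glycines);
* a latent per-residue *quality track* q in (0, 1) is piecewise constant
  over segments with geometric lengths; low q marks badly-modelled regions;
* the *native* is the template with per-residue rigid displacements whose
  magnitude grows as q drops -- |N(0, s(q))| with s(q) = s_min q +
  s_max (1 - q) -- and whose directions are smoothed along the chain to
  mimic rigid-segment shifts;
* the *alignment* is the identity mapping broken by gap blocks inserted at
  segment boundaries and, optionally, a +-1 register shift inside the
  lowest-quality segment; match scores are q plus Gaussian noise, clamped
  to [0, 1];
* *profiles* mix the true one-hot secondary-structure/burial state with a
  uniform distribution in proportion to (1 - q), so predictions degrade
  exactly where the alignment does.

Restraint deviations dd extracted downstream are therefore driven by local
alignment quality, template distance and sequence separation -- the
statistical structure the predictor assumes.  Everything is deterministic
given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    PairwiseAlignment,
    Residue,
    ResidueProfiles,
    StructureModel,
    write_alignment_rows,
    write_profiles,
    write_structure,
)

SS_CYCLE = ("H", "E", "C")


@dataclass
class GeneratorParams:
    """Tunable knobs of the generator; defaults are the study conditions."""

    # geometry
    step_length: float = 3.8  # CA-CA step (angstrom)
    bend_min_deg: float = 90.0
    bend_max_deg: float = 130.0
    clash_distance: float = 3.5
    max_step_retries: int = 100
    max_restarts: int = 50
    sc_absent_prob: float = 0.07
    sc_length_min: float = 1.5
    sc_length_max: float = 3.0
    # latent quality
    segment_mean_length: float = 12.0
    q_beta_a: float = 4.0
    q_beta_b: float = 2.0
    # native perturbation
    displacement_min: float = 0.3  # s(q=1), angstrom
    displacement_max: float = 6.0  # s(q=0), angstrom
    direction_smooth_window: int = 5
    # alignment errors
    gap_block_prob: float = 0.3
    gap_block_max: int = 5
    register_shift_prob: float = 0.5
    # observables
    match_noise: float = 0.15
    profile_noise_scale: float = 0.6
    burial_quantile: float = 0.25

    def validate(self) -> None:
        if not (0 < self.step_length):
            raise ValueError("step_length must be positive")
        if not (0 < self.bend_min_deg <= self.bend_max_deg < 180):
            raise ValueError("bend angles must satisfy 0 < min <= max < 180")
        if self.displacement_min < 0 or self.displacement_max < 0:
            raise ValueError("displacement scales must be non-negative")
        if not (0 <= self.gap_block_prob <= 1):
            raise ValueError("gap_block_prob must be a probability")
        if self.gap_block_max < 1:
            raise ValueError("gap_block_max must be >= 1")


@dataclass
class SyntheticProtein:
    """One generated benchmark case plus its latent ground truth.

    ``quality`` and ``displacement`` are per *master* residue (the union of
    target and template residues before gap-block removal); ``target_map``
    and ``template_map`` give each master residue's 1-based index in the
    target/native and template structures, or 0 where absent.
    """

    protein_id: str
    template: StructureModel
    native: StructureModel
    alignment: PairwiseAlignment
    profiles: ResidueProfiles
    quality: np.ndarray
    displacement: np.ndarray
    target_map: np.ndarray
    template_map: np.ndarray
    target_seq: str
    template_seq: str


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(u @ ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _try_trace(length: int, p: GeneratorParams, rng: np.random.Generator):
    pts = [np.zeros(3), np.array([p.step_length, 0.0, 0.0])]
    for _ in range(2, length):
        placed = False
        for _attempt in range(p.max_step_retries):
            theta = np.deg2rad(rng.uniform(p.bend_min_deg, p.bend_max_deg))
            phi = rng.uniform(-np.pi, np.pi)
            u = _unit(pts[-1] - pts[-2])
            v = _perp(u)
            w = np.cross(u, v)
            alpha = np.pi - theta  # angle between previous and new step
            d = np.cos(alpha) * u + np.sin(alpha) * (np.cos(phi) * v + np.sin(phi) * w)
            cand = pts[-1] + p.step_length * d
            dists = np.linalg.norm(np.asarray(pts) - cand, axis=1)
            if np.all(dists >= p.clash_distance):
                pts.append(cand)
                placed = True
                break
        if not placed:
            return None
    return np.asarray(pts)


def _ca_trace(length: int, p: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    for _ in range(p.max_restarts):
        pts = _try_trace(length, p, rng)
        if pts is not None:
            return pts
    raise RuntimeError(
        f"could not place a clash-free {length}-residue trace after "
        f"{p.max_restarts} restarts (step {p.step_length}, clash "
        f"{p.clash_distance})"
    )


def _local_frames(ca: np.ndarray):
    n = len(ca)
    frames = []
    for i in range(n):
        lo = max(i - 1, 0)
        hi = min(i + 1, n - 1)
        u = _unit(ca[hi] - ca[lo])
        b1 = _perp(u)
        b2 = np.cross(u, b1)
        frames.append((u, b1, b2))
    return frames


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_protein(
    length: int,
    params: GeneratorParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    protein_id: str = "synthetic",
) -> SyntheticProtein:
    """Generate one synthetic target--template case.

    *length* is the master chain length (before gap-block removal) and must
    lie in [30, 500].  Fully deterministic given *seed*.
    """
    if not 30 <= length <= 500:
        raise ValueError("length must be in [30, 500]")
    p = params if params is not None else GeneratorParams()
    p.validate()
    rng = np.random.default_rng(seed)

    # (a) template geometry
    ca = _ca_trace(length, p, rng)
    frames = _local_frames(ca)
    atoms_n = np.array([ca[i] - 1.2 * frames[i][0] + 0.8 * frames[i][1] for i in range(length)])
    atoms_o = np.array([ca[i] + 0.6 * frames[i][0] + 2.2 * frames[i][2] for i in range(length)])
    sc_present = np.empty(length, dtype=bool)
    atoms_sc = np.zeros((length, 3))
    for i in range(length):
        absent = rng.random() < p.sc_absent_prob
        sc_present[i] = not absent
        if not absent:
            ln = rng.uniform(p.sc_length_min, p.sc_length_max)
            atoms_sc[i] = ca[i] - ln * frames[i][1]

    # (b) latent quality track: piecewise constant, geometric segment lengths
    seg_id = np.empty(length, dtype=int)
    seg_values = []
    seg_bounds = []  # start index of each segment
    pos = 0
    while pos < length:
        seg_len = int(rng.geometric(1.0 / p.segment_mean_length))
        val = rng.beta(p.q_beta_a, p.q_beta_b)
        seg_bounds.append(pos)
        seg_values.append(val)
        seg_id[pos : pos + seg_len] = len(seg_values) - 1
        pos += seg_len
    q = np.array([seg_values[s] for s in seg_id])

    # (c) native = template + quality-dependent per-residue displacement
    scale = p.displacement_min * q + p.displacement_max * (1.0 - q)
    mag = np.abs(rng.normal(0.0, 1.0, size=length)) * scale
    raw_dir = rng.normal(size=(length, 3))
    win = max(1, p.direction_smooth_window)
    kernel = np.ones(win) / win
    sm = np.empty_like(raw_dir)
    for k in range(3):
        sm[:, k] = np.convolve(raw_dir[:, k], kernel, mode="same")
    norms = np.linalg.norm(sm, axis=1)
    bad = norms < 1e-12
    sm[bad] = raw_dir[bad]
    norms = np.linalg.norm(sm, axis=1)
    norms[norms < 1e-12] = 1.0
    disp = (sm / norms[:, None]) * mag[:, None]

    # (d) membership: gap blocks at segment boundaries
    membership = np.zeros(length, dtype=int)  # 0 both, 1 target-only, 2 template-only
    for start in seg_bounds[1:]:
        if rng.random() < p.gap_block_prob:
            k = int(rng.integers(1, p.gap_block_max + 1))
            which = 1 if rng.random() < 0.5 else 2
            membership[start : start + k] = which

    target_map = np.zeros(length, dtype=int)
    template_map = np.zeros(length, dtype=int)
    t = k_ = 0
    for m in range(length):
        if membership[m] != 2:
            t += 1
            target_map[m] = t
        if membership[m] != 1:
            k_ += 1
            template_map[m] = k_

    # columns as (target_idx | None, template_idx | None, master-for-quality)
    cols: list[tuple[int | None, int | None, int]] = []
    for m in range(length):
        if membership[m] == 0:
            cols.append((int(target_map[m]), int(template_map[m]), m))
        elif membership[m] == 1:
            cols.append((int(target_map[m]), None, m))
        else:
            cols.append((None, int(template_map[m]), m))

    # optional +-1 register shift inside the lowest-quality segment
    lowest_seg = int(np.argmin(seg_values))
    run = _longest_aligned_run(cols, seg_id, lowest_seg)
    if run is not None and (run[1] - run[0] + 1) >= 3 and rng.random() < p.register_shift_prob:
        direction = 1 if rng.random() < 0.5 else -1
        cols = _apply_register_shift(cols, run, direction)

    # (e) match scores on the final aligned columns
    match_scores: dict[int, float] = {}
    for c, (ti, ki, m) in enumerate(cols):
        if ti is not None and ki is not None:
            match_scores[c] = float(
                np.clip(q[m] + rng.normal(0.0, p.match_noise), 0.0, 1.0)
            )

    # (f) structures, profiles, sequences
    aa = np.where(sc_present, "A", "G")
    template_residues = []
    native_residues = []
    for m in range(length):
        atoms_t = {"CA": ca[m].copy(), "N": atoms_n[m].copy(), "O": atoms_o[m].copy()}
        if sc_present[m]:
            atoms_t["SC"] = atoms_sc[m].copy()
        if template_map[m]:
            template_residues.append(Residue(int(template_map[m]), str(aa[m]), atoms_t))
        if target_map[m]:
            atoms_nv = {role: xyz + disp[m] for role, xyz in atoms_t.items()}
            native_residues.append(Residue(int(target_map[m]), str(aa[m]), atoms_nv))

    template = StructureModel(f"{protein_id}_template", template_residues)
    native = StructureModel(f"{protein_id}_native", native_residues)

    ss_state = np.array([SS_CYCLE[s % 3] for s in seg_id])
    centroid = ca.mean(axis=0)
    dist_c = np.linalg.norm(ca - centroid, axis=1)
    buried = dist_c <= np.quantile(dist_c, p.burial_quantile)

    u_mix = p.profile_noise_scale * (1.0 - q)
    t_mask = target_map > 0
    n_t = int(t_mask.sum())
    target_ss = np.empty((n_t, 3))
    target_burial = np.empty((n_t, 2))
    row = 0
    for m in range(length):
        if not t_mask[m]:
            continue
        onehot = np.array([ss_state[m] == s for s in ("H", "E", "C")], dtype=float)
        target_ss[row] = (1.0 - u_mix[m]) * onehot + u_mix[m] / 3.0
        bhot = np.array([buried[m], not buried[m]], dtype=float)
        target_burial[row] = (1.0 - u_mix[m]) * bhot + u_mix[m] / 2.0
        row += 1
    k_mask = template_map > 0
    profiles = ResidueProfiles(
        target_ss,
        target_burial,
        [str(s) for s in ss_state[k_mask]],
        ["B" if b else "E" for b in buried[k_mask]],
    )

    alignment = PairwiseAlignment(
        target_id=f"{protein_id}_target",
        template_id=f"{protein_id}_template",
        columns=[(ti, ki) for ti, ki, _ in cols],
        match_scores=match_scores,
        target_length=n_t,
    )
    return SyntheticProtein(
        protein_id=protein_id,
        template=template,
        native=native,
        alignment=alignment,
        profiles=profiles,
        quality=q,
        displacement=mag,
        target_map=target_map,
        template_map=template_map,
        target_seq="".join(aa[t_mask]),
        template_seq="".join(aa[k_mask]),
    )


def _longest_aligned_run(cols, seg_id, segment: int):
    """Longest run of consecutive aligned columns inside *segment*."""
    best = None
    start = None
    for c, (ti, ki, m) in enumerate(cols + [(None, None, -1)]):
        inside = ti is not None and ki is not None and m >= 0 and seg_id[m] == segment
        if inside and start is None:
            start = c
        elif not inside and start is not None:
            if best is None or (c - 1 - start) > (best[1] - best[0]):
                best = (start, c - 1)
            start = None
    return best


def _apply_register_shift(cols, run, direction: int):
    a, b = run
    sub = cols[a : b + 1]
    ts = [c[0] for c in sub]
    ks = [c[1] for c in sub]
    ms = [c[2] for c in sub]
    m_len = len(sub)
    if direction == 1:
        new = (
            [(None, ks[0], ms[0])]
            + [(ts[i], ks[i + 1], ms[i]) for i in range(m_len - 1)]
            + [(ts[m_len - 1], None, ms[m_len - 1])]
        )
    else:
        new = (
            [(ts[0], None, ms[0])]
            + [(ts[i + 1], ks[i], ms[i + 1]) for i in range(m_len - 1)]
            + [(None, ks[m_len - 1], ms[m_len - 1])]
        )
    return cols[:a] + new + cols[b + 1 :]


# ---------------------------------------------------------------------------
# benchmark sets
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    proteins: list[SyntheticProtein]
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    params: GeneratorParams
    lengths: list[int] = field(default_factory=list)
    protein_seeds: list[int] = field(default_factory=list)

    @property
    def train(self) -> list[SyntheticProtein]:
        ids = set(self.train_ids)
        return [sp for sp in self.proteins if sp.protein_id in ids]

    @property
    def test(self) -> list[SyntheticProtein]:
        ids = set(self.test_ids)
        return [sp for sp in self.proteins if sp.protein_id in ids]


def generate_benchmark(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 200),
    params: GeneratorParams | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> Benchmark:
    """Generate independent proteins and a whole-protein train/test split.

    The split assigns entire proteins (default 80/20) so that evaluation is
    cross-protein; per-protein seeds are derived from *seed*, so proteins
    are pairwise independent.
    """
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    lo, hi = length_range
    params = params if params is not None else GeneratorParams()
    master = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    lengths = [int(v) for v in master.integers(lo, hi + 1, size=n_proteins)]
    protein_seeds = [int(v) for v in master.integers(0, 2**31 - 1, size=n_proteins)]
    proteins = [
        generate_protein(
            lengths[i], params, protein_seeds[i], protein_id=f"P{i + 1:03d}"
        )
        for i in range(n_proteins)
    ]
    n_test = max(1, round(test_fraction * n_proteins))
    order = master.permutation(n_proteins)
    test_ids = sorted(proteins[i].protein_id for i in order[:n_test])
    train_ids = sorted(proteins[i].protein_id for i in order[n_test:])
    return Benchmark(
        proteins=proteins,
        train_ids=train_ids,
        test_ids=test_ids,
        seed=seed,
        params=params,
        lengths=lengths,
        protein_seeds=protein_seeds,
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Write every protein's artifacts plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in bench.proteins:
        d = outdir / "proteins" / sp.protein_id
        d.mkdir(parents=True, exist_ok=True)
        write_structure(sp.template, d / "template.pdb")
        write_structure(sp.native, d / "native.pdb")
        target_row, template_row = _alignment_rows(sp)
        write_alignment_rows(
            sp.alignment.target_id,
            sp.alignment.template_id,
            target_row,
            template_row,
            [sp.alignment.match_scores[c] for c in sorted(sp.alignment.match_scores)],
            d / "alignment.fasta",
            d / "match_scores.tsv",
        )
        write_profiles(
            sp.profiles,
            sp.target_seq,
            d / "target.ss2",
            d / "target_burial.tsv",
            d / "template_annot.tsv",
        )
        with open(d / "quality.tsv", "w") as fh:
            fh.write("master_index\tq\tdisplacement\n")
            for m in range(len(sp.quality)):
                fh.write(f"{m + 1}\t{sp.quality[m]:.6f}\t{sp.displacement[m]:.6f}\n")
    manifest = {
        "seed": bench.seed,
        "params": dataclasses.asdict(bench.params),
        "lengths": bench.lengths,
        "protein_seeds": bench.protein_seeds,
        "train_ids": bench.train_ids,
        "test_ids": bench.test_ids,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _alignment_rows(sp: SyntheticProtein) -> tuple[str, str]:
    t_row = []
    k_row = []
    for ti, ki in sp.alignment.columns:
        t_row.append("-" if ti is None else sp.target_seq[ti - 1])
        k_row.append("-" if ki is None else sp.template_seq[ki - 1])
    return "".join(t_row), "".join(k_row)
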