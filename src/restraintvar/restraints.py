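"""Restraint-pair enumeration, labels, sigma conventions and harmonic energy.

For a target--template alignment, every aligned residue pair whose
template inter-atomic distance lies strictly below a category cutoff yields
one restraint instance.  Categories and cutoffs (angstrom):

========  =======================  ======
category  atom pair                cutoff
========  =======================  ======
CACA      CA--CA (unordered)        14.5
NO        amide N -- carbonyl O     10.0
MS        main chain (CA) -- SC      8.0
SS        SC -- SC (unordered)       5.0
========  =======================  ======

SC is the side-chain centroid pseudo-atom.  NO and MS pairs are ordered
(the roles at the two ends differ); CACA and SS are unordered with I < J.
The regression label of an instance is dd = |d_native - d_template|, the
absolute deviation between the native and template distances.

Two sigma conventions coexist: the mean absolute deviation <|dd|> predicted
by the forest, and the standard deviation of the zero-mean Gaussian used by
harmonic-restraint modeling packages; for a half-normal |X| with
X ~ N(0, sigma^2) they differ by the exact factor sqrt(2/pi).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import (
    CATEGORIES,
    CUTOFFS,
    PairwiseAlignment,
    RestraintRow,
    RestraintTable,
    StructureModel,
    ValidationError,
)

log = logging.getLogger(__name__)

SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

#: atom roles at the two ends of each category (template side)
ATOM_ROLES = {
    "CACA": ("CA", "CA"),
    "NO": ("N", "O"),
    "MS": ("CA", "SC"),
    "SS": ("SC", "SC"),
}
ORDERED_CATEGORIES = frozenset({"NO", "MS"})


def _distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance, computed identically everywhere in this module.

    Using one formula for template distances and native distances keeps
    dd = |d_native - d_template| exactly 0 in the identity case.
    """
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1)))


def _pair_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs distance matrix with the same arithmetic as _distance."""
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1))


@dataclass
class RestraintInstance:
    """One atom pair: category, aligned indices, template distance, label."""

    category: str
    I: int  # target index, end 1
    J: int  # target index, end 2
    K: int  # template index aligned with I
    L: int  # template index aligned with J
    role_1: str
    role_2: str
    d_template: float
    features: np.ndarray | None = None  # 20-vector, filled by features module
    dd: float | None = None  # |d_native - d_template|
    sigma: float | None = None  # predicted variability


def enumerate_restraint_pairs(
    alignment: PairwiseAlignment,
    template: StructureModel,
    categories: tuple[str, ...] = CATEGORIES,
    *,
    skip_report: dict | None = None,
) -> list[RestraintInstance]:
    """Enumerate restraint instances for the requested categories.

    An instance is kept iff the template distance is strictly below the
    category cutoff.  Pairs whose required atoms are missing are skipped;
    when *skip_report* is a dict it receives per-category skip counts.
    Output order is deterministic: categories in canonical order, then
    (I, J) ascending.
    """
    pairs = [(t, k) for _, t, k in alignment.aligned_columns()]
    max_k = max((k for _, k in pairs), default=0)
    if max_k > len(template.residues):
        raise ValidationError(
            "alignment references template residues beyond the structure"
        )
    n = len(pairs)
    out: list[RestraintInstance] = []
    if skip_report is not None:
        skip_report.clear()

    # coordinates per role for the aligned template residues (nan = missing)
    coords: dict[str, np.ndarray] = {}
    for role in ("CA", "N", "O", "SC"):
        arr = np.full((n, 3), np.nan)
        for i, (_, k) in enumerate(pairs):
            xyz = template.atom(k, role)
            if xyz is not None:
                arr[i] = xyz
        coords[role] = arr

    for cat in CATEGORIES:
        if cat not in categories:
            continue
        role_1, role_2 = ATOM_ROLES[cat]
        a, b = coords[role_1], coords[role_2]
        ok_a = np.isfinite(a[:, 0])
        ok_b = np.isfinite(b[:, 0])
        dist = _pair_distances(np.nan_to_num(a), np.nan_to_num(b))
        cutoff = CUTOFFS[cat]
        ordered = cat in ORDERED_CATEGORIES
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        domain = (ii != jj) if ordered else (ii < jj)
        usable = ok_a[:, None] & ok_b[None, :]
        # SC absence is an expected data property, not a defect; only count
        # missing main-chain atoms (CA/N/O) as skips
        miss_main = np.zeros((n, n), dtype=bool)
        if role_1 != "SC":
            miss_main |= ~ok_a[:, None]
        if role_2 != "SC":
            miss_main |= ~ok_b[None, :]
        n_skip = int(np.count_nonzero(domain & miss_main))
        keep = domain & usable & (dist < cutoff)
        for i, j in np.argwhere(keep):
            I, K = pairs[i]
            J, L = pairs[j]
            out.append(
                RestraintInstance(
                    category=cat,
                    I=I,
                    J=J,
                    K=K,
                    L=L,
                    role_1=role_1,
                    role_2=role_2,
                    d_template=float(dist[i, j]),
                )
            )
        if n_skip:
            log.info("category %s: %d pairs skipped (missing atoms)", cat, n_skip)
        if skip_report is not None:
            skip_report[cat] = n_skip
    out.sort(key=lambda r: (CATEGORIES.index(r.category), r.I, r.J))
    return out


def label_instances(
    instances: list[RestraintInstance],
    alignment: PairwiseAlignment,
    native: StructureModel,
    *,
    drop_report: dict | None = None,
) -> list[RestraintInstance]:
    """Attach dd = |d_native - d_template| labels from the native structure.

    Instances whose native atoms are missing are dropped (counted in
    *drop_report* when given).  Returns new instances; the input is not
    mutated.
    """
    kept: list[RestraintInstance] = []
    dropped = 0
    for inst in instances:
        a = native.atom(inst.I, inst.role_1)
        b = native.atom(inst.J, inst.role_2)
        if a is None or b is None:
            dropped += 1
            continue
        d_native = _distance(a, b)
        kept.append(replace(inst, dd=abs(d_native - inst.d_template)))
    if dropped:
        log.info("label_instances: dropped %d instances (missing native atoms)", dropped)
    if drop_report is not None:
        drop_report["dropped"] = dropped
    return kept


def convert_sigma(value, direction: str):
    """Convert between the mean-absolute-deviation and Gaussian-sd scales.

    ``modeller_to_rf`` multiplies by sqrt(2/pi) (Gaussian sd -> <|dd|>);
    ``rf_to_modeller`` multiplies by sqrt(pi/2).  Accepts scalars or arrays;
    the two directions are exact inverses.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("sigma values must be finite and non-negative")
    if direction == "modeller_to_rf":
        out = arr * SQRT_2_OVER_PI
    elif direction == "rf_to_modeller":
        out = arr / SQRT_2_OVER_PI
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) else out


def harmonic_energy(d, d_prime, sigma):
    """Harmonic restraint energy 1/2 ((d - d') / sigma)^2 (dimensionless)."""
    sig = np.asarray(sigma, dtype=float)
    if np.any(sig <= 0):
        raise ValidationError("sigma must be positive")
    val = 0.5 * ((np.asarray(d, float) - np.asarray(d_prime, float)) / sig) ** 2
    return float(val) if val.ndim == 0 else val


def restraint_table_energy(table: RestraintTable, structure: StructureModel) -> float:
    """Sum of harmonic energies of a restraint table over a structure.

    Rows whose atoms are absent from the structure are skipped with a log
    entry.
    """
    total = 0.0
    skipped = 0
    for row in table.rows:
        a = structure.atom(row.I, row.role_1)
        b = structure.atom(row.J, row.role_2)
        if a is None or b is None:
            skipped += 1
            continue
        d = _distance(a, b)
        total += harmonic_energy(d, row.d_template, row.sigma)
    if skipped:
        log.info("restraint_table_energy: %d rows skipped (missing atoms)", skipped)
    return total


def write_restraints_with_sigma(
    instances: list[RestraintInstance],
    floor: float = 0.05,
    cap: float = 15.0,
) -> RestraintTable:
    """Build a validated RestraintTable from instances with predicted sigma.

    Sigma values are clipped to [floor, cap]; rows are ordered by category
    (canonical order) then (I, J).
    """
    if not (floor > 0):
        raise ValueError("sigma floor must be positive")
    if cap < floor:
        raise ValueError("sigma cap must be >= floor")
    rows = []
    for inst in sorted(
        instances, key=lambda r: (CATEGORIES.index(r.category), r.I, r.J)
    ):
        if inst.sigma is None:
            raise ValidationError(
                f"instance {inst.category} {inst.I}-{inst.J} has no predicted sigma"
            )
        rows.append(
            RestraintRow(
                category=inst.category,
                I=inst.I,
                J=inst.J,
                role_1=inst.role_1,
                role_2=inst.role_2,
                d_template=inst.d_template,
                sigma=float(np.clip(inst.sigma, floor, cap)),
                dd=inst.dd,
            )
        )
    return RestraintTable(rows)
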