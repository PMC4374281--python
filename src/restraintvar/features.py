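"""The 20-dimensional feature vector of a restraint instance.

For a restraint between target positions I < J (aligned with template
positions K < L), with per-column match scores m and gap bookkeeping done in
alignment columns:

=====  ==============================================================
F1     |I - J| (target sequence separation)
F2     |I - J| / N_res,target
F3     d_template (angstrom)
F4     m_{I,K} * m_{J,L}
F5     mean match score over aligned columns between and at I and J
F6     number of gap characters in the target row strictly between I and J
F7     F6 / |I - J|
F8     1 / (column distance from I to its nearest target-row gap)
F9     same as F8 at J
F10    number of gap characters in the template row strictly between K and L
F11    F10 / |K - L|
F12    1 / (column distance from K to its nearest template-row gap)
F13    same as F12 at L
F14    secondary-structure consistency at (I, K)
F15    secondary-structure consistency at (J, L)
F16    burial consistency at (I, K)
F17    burial consistency at (J, L)
F18    F4 * F14 * F15 * F16 * F17
F19    F18 / (1 + F6 + F10)
F20    F19 / (1 + F8 + F9 + F12 + F13)
=====  ==============================================================

The nearest-gap reciprocals are 0 when the row contains no gap, and 1 when a
gap sits in the column adjacent to the residue.  Consistency scores default
to the probabilistic reading (the target's predicted probability of the
template's observed state); a "delta" mode returning a 0/1 argmax match is
available.  For the ordered categories (NO, MS) the span and gap features
use (min(I, J), max(I, J)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import (
    GAP,
    PairwiseAlignment,
    ResidueProfiles,
    SS_STATES,
    BURIAL_STATES,
    ValidationError,
)
from .restraints import RestraintInstance

N_FEATURES = 20
FEATURE_NAMES = tuple(f"F{i}" for i in range(1, N_FEATURES + 1))

_METADATA_COLUMNS = (
    "protein",
    "category",
    "I",
    "J",
    "K",
    "L",
    "role_1",
    "role_2",
    "d_template",
    "dd",
)


class AlignmentIndex:
    """Precomputed column tables for O(1) per-instance feature lookups."""

    def __init__(self, alignment: PairwiseAlignment):
        self.alignment = alignment
        cols = alignment.columns
        ncol = len(cols)
        self.col_of_target = alignment.column_of_target()
        self.col_of_template = alignment.column_of_template()

        gap_t = np.array([c[0] is GAP for c in cols], dtype=bool)
        gap_k = np.array([c[1] is GAP for c in cols], dtype=bool)
        aligned = ~gap_t & ~gap_k
        scores = np.zeros(ncol)
        for c, s in alignment.match_scores.items():
            scores[c] = s

        # prefix sums over columns: x[a..b] inclusive = cum[b+1] - cum[a]
        self.cum_score = np.concatenate([[0.0], np.cumsum(scores * aligned)])
        self.cum_aligned = np.concatenate([[0], np.cumsum(aligned)])
        self.cum_gap_t = np.concatenate([[0], np.cumsum(gap_t)])
        self.cum_gap_k = np.concatenate([[0], np.cumsum(gap_k)])
        self.scores = scores
        self.gap_dist_t = _nearest_gap_distances(gap_t)
        self.gap_dist_k = _nearest_gap_distances(gap_k)

    def gap_reciprocal(self, row: str, col: int) -> float:
        dist = (self.gap_dist_t if row == "target" else self.gap_dist_k)[col]
        return 0.0 if np.isinf(dist) else 1.0 / dist


def _nearest_gap_distances(gap_mask: np.ndarray) -> np.ndarray:
    """Column distance from each column to the nearest gap column (inf if none)."""
    n = len(gap_mask)
    dist = np.full(n, np.inf)
    last = None
    for c in range(n):
        if gap_mask[c]:
            last = c
        if last is not None:
            dist[c] = c - last
    last = None
    for c in range(n - 1, -1, -1):
        if gap_mask[c]:
            last = c
        if last is not None:
            dist[c] = min(dist[c], last - c)
    return dist


def nearest_gap_reciprocal(
    alignment: PairwiseAlignment, row: str, residue_index: int
) -> float:
    """Reciprocal of the column distance to the nearest gap in *row*.

    The distance is measured in alignment columns from the residue's column
    to the nearest column holding a gap in the same row, searched in both
    directions over the whole alignment; the result is 0 when the row has no
    gap at all.
    """
    if row not in ("target", "template"):
        raise ValueError(f"row must be 'target' or 'template', got {row!r}")
    idx = AlignmentIndex(alignment)
    col_map = idx.col_of_target if row == "target" else idx.col_of_template
    if residue_index not in col_map:
        raise ValidationError(f"{row} residue {residue_index} not in alignment")
    return idx.gap_reciprocal(row, col_map[residue_index])


def span_average_match(alignment: PairwiseAlignment, I: int, J: int) -> float:
    """Mean match score over aligned columns between and at positions I, J."""
    if not I < J:
        raise ValueError("require I < J")
    idx = AlignmentIndex(alignment)
    col_map = idx.col_of_target
    for pos in (I, J):
        if pos not in col_map or alignment.columns[col_map[pos]][1] is GAP:
            raise ValidationError(f"target residue {pos} is not aligned")
    return _span_average(idx, col_map[I], col_map[J])


def _span_average(idx: AlignmentIndex, c_lo: int, c_hi: int) -> float:
    num = idx.cum_score[c_hi + 1] - idx.cum_score[c_lo]
    den = idx.cum_aligned[c_hi + 1] - idx.cum_aligned[c_lo]
    return num / den


def consistency_scores(
    profiles: ResidueProfiles,
    target_index: int,
    template_index: int,
    mode: str = "prob",
) -> tuple[float, float]:
    """Secondary-structure and burial consistency between aligned residues.

    In the default ``"prob"`` mode the score is the target's predicted
    probability of the template residue's observed state.  In ``"delta"``
    mode it is 1 when the target's argmax class equals the template state,
    else 0.
    """
    if mode not in ("prob", "delta"):
        raise ValueError(f"unknown consistency mode {mode!r}")
    try:
        ss_state = profiles.template_ss[template_index - 1]
        acc_state = profiles.template_burial[template_index - 1]
        ss_probs = profiles.target_ss[target_index - 1]
        acc_probs = profiles.target_burial[target_index - 1]
    except IndexError as exc:
        raise ValidationError(
            f"missing annotation for pair ({target_index}, {template_index})"
        ) from exc
    if template_index < 1 or target_index < 1:
        raise ValidationError("residue indices are 1-based")
    if mode == "prob":
        ss = float(ss_probs[SS_STATES.index(ss_state)])
        acc = float(acc_probs[BURIAL_STATES.index(acc_state)])
    else:
        ss = float(SS_STATES[int(np.argmax(ss_probs))] == ss_state)
        acc = float(BURIAL_STATES[int(np.argmax(acc_probs))] == acc_state)
    return ss, acc


def compute_feature_vector(
    instance: RestraintInstance,
    alignment: PairwiseAlignment,
    profiles: ResidueProfiles,
    mode: str = "prob",
    index: AlignmentIndex | None = None,
) -> np.ndarray:
    """Compute the full 20-feature vector for one restraint instance."""
    idx = index if index is not None else AlignmentIndex(alignment)
    I, J = sorted((instance.I, instance.J))
    K, L = sorted((instance.K, instance.L))
    cI, cJ = idx.col_of_target[I], idx.col_of_target[J]
    cK, cL = idx.col_of_template[K], idx.col_of_template[L]

    f = np.empty(N_FEATURES)
    sep = J - I
    f[0] = sep
    f[1] = sep / alignment.target_length
    f[2] = instance.d_template
    f[3] = idx.scores[cI] * idx.scores[cJ]
    f[4] = _span_average(idx, cI, cJ)
    f[5] = idx.cum_gap_t[cJ] - idx.cum_gap_t[cI + 1]  # strictly between
    f[6] = f[5] / sep
    f[7] = idx.gap_reciprocal("target", cI)
    f[8] = idx.gap_reciprocal("target", cJ)
    f[9] = idx.cum_gap_k[cL] - idx.cum_gap_k[cK + 1]
    f[10] = f[9] / (L - K)
    f[11] = idx.gap_reciprocal("template", cK)
    f[12] = idx.gap_reciprocal("template", cL)
    f[13], f[15] = consistency_scores(profiles, I, K, mode)
    f[14], f[16] = consistency_scores(profiles, J, L, mode)
    f[17] = f[3] * f[13] * f[14] * f[15] * f[16]
    f[18] = f[17] / (1.0 + f[5] + f[9])
    f[19] = f[18] / (1.0 + f[7] + f[8] + f[11] + f[12])
    return f


def feature_matrix(
    instances: list[RestraintInstance],
    alignment: PairwiseAlignment,
    profiles: ResidueProfiles,
    mode: str = "prob",
    protein_id: str | None = None,
) -> pd.DataFrame:
    """Feature vectors plus instance metadata as a DataFrame.

    Columns: protein, category, I, J, K, L, role_1, role_2, d_template, dd,
    F1..F20.  This is the export/audit format used for training.
    """
    idx = AlignmentIndex(alignment)
    rows = np.empty((len(instances), N_FEATURES))
    for i, inst in enumerate(instances):
        rows[i] = compute_feature_vector(inst, alignment, profiles, mode, idx)
    meta = pd.DataFrame(
        {
            "protein": protein_id if protein_id is not None else alignment.target_id,
            "category": [r.category for r in instances],
            "I": [r.I for r in instances],
            "J": [r.J for r in instances],
            "K": [r.K for r in instances],
            "L": [r.L for r in instances],
            "role_1": [r.role_1 for r in instances],
            "role_2": [r.role_2 for r in instances],
            "d_template": [r.d_template for r in instances],
            "dd": [r.dd if r.dd is not None else np.nan for r in instances],
        }
    )
    feats = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return pd.concat([meta, feats], axis=1)
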