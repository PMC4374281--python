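import numpy as np
import pytest

from restraintvar.io_formats import (
    PairwiseAlignment,
    Residue,
    ResidueProfiles,
    StructureModel,
)

# ---------------------------------------------------------------------------
# the fixed 15-residue fixture alignment (two gap blocks, listed scores)
# ---------------------------------------------------------------------------

FIXTURE_T_ROW = "ACDEF--GHIKLMNP-QR"  # 15 target residues, gaps at cols 5, 6, 15
FIXTURE_K_ROW = "ACDEFGHIK-LMNPQRST"  # 18 template residues minus 1 gap at col 9
FIXTURE_SCORES = [
    0.82, 0.77, 0.64, 0.55, 0.41,
    0.33, 0.29, 0.48,
    0.52, 0.61, 0.70, 0.74, 0.69,
    0.58,
]  # one per aligned column, in column order (14 aligned columns)


def _columns_from_rows(t_row: str, k_row: str):
    cols = []
    ti = ki = 0
    for ct, ck in zip(t_row, k_row):
        t = k = None
        if ct != "-":
            ti += 1
            t = ti
        if ck != "-":
            ki += 1
            k = ki
        cols.append((t, k))
    return cols


def make_alignment(t_row: str, k_row: str, scores, target_length=None):
    cols = _columns_from_rows(t_row, k_row)
    aligned = [c for c, (t, k) in enumerate(cols) if t is not None and k is not None]
    assert len(scores) == len(aligned), "fixture score count mismatch"
    n_t = sum(1 for t, _ in cols if t is not None)
    return PairwiseAlignment(
        target_id="target",
        template_id="template",
        columns=cols,
        match_scores=dict(zip(aligned, scores)),
        target_length=target_length if target_length is not None else n_t,
    )


def make_profiles(n_target: int, n_template: int, seed=0):
    """Valid profiles with reproducible, non-degenerate probabilities."""
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet((4, 2, 3), size=n_target)
    acc = rng.dirichlet((3, 3), size=n_target)
    ss_states = [("H", "E", "C")[i % 3] for i in range(n_template)]
    acc_states = [("B", "E")[i % 2] for i in range(n_template)]
    return ResidueProfiles(raw, acc, list(ss_states), list(acc_states))


@pytest.fixture
def fixture15():
    """The 15-residue alignment with two gap blocks plus matching profiles."""
    aln = make_alignment(FIXTURE_T_ROW, FIXTURE_K_ROW, FIXTURE_SCORES)
    n_template = sum(1 for c in FIXTURE_K_ROW if c != "-")
    profiles = make_profiles(15, n_template, seed=42)
    return {
        "alignment": aln,
        "profiles": profiles,
        "t_row": FIXTURE_T_ROW,
        "k_row": FIXTURE_K_ROW,
        "scores": FIXTURE_SCORES,
    }


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def line_structure(n: int, spacing: float = 3.8, with_all_atoms=True, sid="toy"):
    """n residues on the x axis; N/O/SC at fixed small offsets from CA."""
    residues = []
    for i in range(n):
        ca = np.array([i * spacing, 0.0, 0.0])
        atoms = {"CA": ca}
        if with_all_atoms:
            atoms["N"] = ca + np.array([0.0, 1.4, 0.0])
            atoms["O"] = ca + np.array([0.0, -1.4, 0.5])
            atoms["SC"] = ca + np.array([0.0, 0.0, 2.0])
        residues.append(Residue(i + 1, "A", atoms))
    return StructureModel(sid, residues)


def random_structure(n: int, rng, box: float = 20.0, sc_prob: float = 0.9, sid="rand"):
    """n residues at uniform positions in a box (no geometry constraints)."""
    residues = []
    for i in range(n):
        ca = rng.uniform(0, box, 3)
        atoms = {
            "CA": ca,
            "N": ca + rng.normal(0, 0.5, 3),
            "O": ca + rng.normal(0, 0.5, 3),
        }
        if rng.random() < sc_prob:
            atoms["SC"] = ca + rng.normal(0, 1.0, 3)
        residues.append(Residue(i + 1, "A", atoms))
    return StructureModel(sid, residues)


def identity_alignment(n: int, score: float = 0.5):
    return make_alignment("A" * n, "A" * n, [score] * n)
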