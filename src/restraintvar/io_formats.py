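"""Readers, writers and domain containers for every external representation.

The package works with five kinds of files:

* pairwise target--template alignments: two-row gapped FASTA plus a sidecar
  TSV with one match score per aligned column;
* protein structures: PDB, reduced to per-residue pseudo-atoms (CA, N, O and
  a side-chain centroid SC);
* per-residue profiles: an ss2-style table of predicted secondary-structure
  probabilities and a TSV of two-state burial probabilities for the target,
  and a TSV of observed SS/burial states for the template;
* restraint tables: TSV rows of harmonic-restraint parameters;
* trained models: a versioned JSON dump of regression forests.

All residue indices are 1-based; coordinates and distances are in angstroms.
Gaps in alignments are represented by ``None``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import seq3

log = logging.getLogger(__name__)

GAP = None

#: Atom-pair categories and their template-distance cutoffs (angstrom).
CATEGORIES = ("CACA", "NO", "MS", "SS")
CUTOFFS = {"CACA": 14.5, "NO": 10.0, "MS": 8.0, "SS": 5.0}

SS_STATES = ("H", "E", "C")
BURIAL_STATES = ("B", "E")

MODEL_FORMAT = "restraintvar-forest"
MODEL_VERSION = 1

# atom names never counted as side chain when forming the SC centroid
_MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class FormatError(ValueError):
    """A file does not conform to the documented format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class PairwiseAlignment:
    """A gapped two-row target--template alignment.

    ``columns[c]`` is a pair ``(target_index, template_index)`` where either
    entry may be ``None`` (a gap), never both.  ``match_scores`` maps the
    0-based column position of every *aligned* column (both rows non-gap) to
    its real-valued match score.  ``target_length`` is the full chain length
    of the target sequence, used to normalise sequence separations.
    """

    target_id: str
    template_id: str
    columns: list[tuple[int | None, int | None]]
    match_scores: dict[int, float]
    target_length: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t_seen: list[int] = []
        k_seen: list[int] = []
        for c, (t, k) in enumerate(self.columns):
            if t is GAP and k is GAP:
                raise ValidationError(f"column {c} has a gap in both rows")
            if t is not GAP:
                t_seen.append(t)
            if k is not GAP:
                k_seen.append(k)
        for name, seen in (("target", t_seen), ("template", k_seen)):
            if seen and seen != list(range(seen[0], seen[0] + len(seen))):
                raise ValidationError(
                    f"{name} indices are not strictly increasing and contiguous"
                )
        aligned = {
            c for c, (t, k) in enumerate(self.columns) if t is not GAP and k is not GAP
        }
        if set(self.match_scores) != aligned:
            raise ValidationError(
                "match scores must be defined exactly for aligned columns"
            )
        if not all(math.isfinite(v) for v in self.match_scores.values()):
            raise ValidationError("non-finite match score")
        if t_seen and self.target_length < max(t_seen):
            raise ValidationError("target_length smaller than max target index")

    # -- convenience views -------------------------------------------------

    def aligned_columns(self) -> list[tuple[int, int, int]]:
        """All aligned columns as (column, target_index, template_index)."""
        return [
            (c, t, k)
            for c, (t, k) in enumerate(self.columns)
            if t is not GAP and k is not GAP
        ]

    def column_of_target(self) -> dict[int, int]:
        return {t: c for c, (t, _) in enumerate(self.columns) if t is not GAP}

    def column_of_template(self) -> dict[int, int]:
        return {k: c for c, (_, k) in enumerate(self.columns) if k is not GAP}


def _row_to_indices(row: str) -> list[int | None]:
    out: list[int | None] = []
    i = 0
    for ch in row:
        if ch in "-.":
            out.append(GAP)
        else:
            i += 1
            out.append(i)
    return out


def read_alignment(
    alignment_path: str | Path,
    scores_path: str | Path,
    *,
    target_length: int | None = None,
) -> PairwiseAlignment:
    """Read a two-row gapped FASTA alignment and its match-score sidecar.

    The first FASTA record is the target row, the second the template row.
    The scores file carries one finite real per aligned column, in column
    order; blank lines, ``#`` comments and a single non-numeric header line
    are ignored.  When *target_length* is not given, the number of target
    residues present in the alignment is used.
    """
    records = list(SeqIO.parse(str(alignment_path), "fasta"))
    if len(records) != 2:
        raise FormatError(
            f"{alignment_path}: expected exactly 2 FASTA records, got {len(records)}"
        )
    t_row, k_row = (str(r.seq).upper() for r in records)
    if len(t_row) != len(k_row):
        raise FormatError(f"{alignment_path}: rows have unequal lengths")
    t_idx = _row_to_indices(t_row)
    k_idx = _row_to_indices(k_row)
    columns = list(zip(t_idx, k_idx))
    for c, (t, k) in enumerate(columns):
        if t is GAP and k is GAP:
            raise FormatError(f"{alignment_path}: column {c} is gap/gap")

    scores = _read_score_file(scores_path)
    aligned_cols = [c for c, (t, k) in enumerate(columns) if t is not GAP and k is not GAP]
    if len(scores) != len(aligned_cols):
        raise FormatError(
            f"{scores_path}: {len(scores)} scores for {len(aligned_cols)} aligned columns"
        )
    match_scores = dict(zip(aligned_cols, scores))
    n_target = sum(1 for t, _ in columns if t is not GAP)
    return PairwiseAlignment(
        target_id=records[0].id,
        template_id=records[1].id,
        columns=columns,
        match_scores=match_scores,
        target_length=target_length if target_length is not None else n_target,
    )


def _read_score_file(path: str | Path) -> list[float]:
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()[-1]
            try:
                val = float(tok)
            except ValueError:
                if lineno == 1 or not scores:
                    continue  # header line
                raise FormatError(f"{path}:{lineno}: not a number: {tok!r}")
            if not math.isfinite(val):
                raise FormatError(f"{path}:{lineno}: non-finite score")
            scores.append(val)
    return scores


def write_alignment(
    alignment: PairwiseAlignment,
    alignment_path,
    scores_path,
    *,
    target_seq: str | None = None,
    template_seq: str | None = None,
) -> None:
    """Write the two-row FASTA and the match-score sidecar TSV.

    PairwiseAlignment does not track residue letters; callers that know the
    sequences can pass them, otherwise rows are written with 'X'.
    """

    def row(which: int, seq: str | None) -> str:
        out = []
        for col in alignment.columns:
            idx = col[which]
            if idx is GAP:
                out.append("-")
            elif seq is not None and idx <= len(seq):
                out.append(seq[idx - 1])
            else:
                out.append("X")
        return "".join(out)

    write_alignment_rows(
        alignment.target_id,
        alignment.template_id,
        row(0, target_seq),
        row(1, template_seq),
        [alignment.match_scores[c] for c in sorted(alignment.match_scores)],
        alignment_path,
        scores_path,
    )


def write_alignment_rows(
    target_id: str,
    template_id: str,
    target_row: str,
    template_row: str,
    scores: Sequence[float],
    alignment_path,
    scores_path,
) -> None:
    with open(alignment_path, "w") as fh:
        fh.write(f">{target_id}\n{target_row}\n>{template_id}\n{template_row}\n")
    with open(scores_path, "w") as fh:
        fh.write("match_score\n")
        for s in scores:
            fh.write(f"{s:.6f}\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass
class Residue:
    index: int  # 1-based, by order of appearance
    aa: str  # one-letter code
    atoms: dict[str, np.ndarray]  # role -> xyz (angstrom)
    auth_id: str | None = None  # author residue number, metadata only


@dataclass
class StructureModel:
    """Per-residue pseudo-atom coordinates (roles CA, N, O, SC)."""

    structure_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev = 0
        for res in self.residues:
            if res.index <= prev:
                raise ValidationError("residue indices not strictly increasing")
            prev = res.index
            if "CA" not in res.atoms:
                raise ValidationError(f"residue {res.index} lacks CA")
            for role, xyz in res.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValidationError(
                        f"non-finite coordinate for {role}@{res.index}"
                    )

    def atom(self, index: int, role: str) -> np.ndarray | None:
        res = self._by_index().get(index)
        if res is None:
            return None
        return res.atoms.get(role)

    def _by_index(self) -> dict[int, Residue]:
        cache = getattr(self, "_index_cache", None)
        if cache is None or len(cache) != len(self.residues):
            cache = {r.index: r for r in self.residues}
            object.__setattr__(self, "_index_cache", cache)
        return cache

    def __len__(self) -> int:
        return len(self.residues)


def read_structure(pdb_path: str | Path, *, chain: str | None = None) -> StructureModel:
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Uses the first MODEL and, unless *chain* names one, the first chain.
    For alternate locations the highest-occupancy copy of each atom name is
    kept.  CA, N and O are taken verbatim; SC is the centroid of all
    side-chain heavy atoms (heavy atoms excluding N, CA, C, O, OXT) and is
    absent when a residue has none (e.g. glycine).  Residues are renumbered
    1..n by order of appearance; author numbering is kept as metadata.
    Residues without a CA are skipped with a warning.
    """
    try:
        st = gemmi.read_structure(str(pdb_path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise FormatError(f"{pdb_path}: cannot parse PDB: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{pdb_path}: no models")
    model = st[0]
    if len(model) == 0:
        raise FormatError(f"{pdb_path}: no chains")
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise FormatError(f"{pdb_path}: chain {chain!r} not found")

    residues: list[Residue] = []
    idx = 0
    for res in ch:
        if res.is_water():
            continue
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            cur = best.get(atom.name)
            if cur is None or atom.occ > cur.occ:
                best[atom.name] = atom
        if "CA" not in best:
            warnings.warn(
                f"{pdb_path}: residue {res.name} {res.seqid.num} has no CA; skipped"
            )
            continue
        atoms: dict[str, np.ndarray] = {}
        for role in ("CA", "N", "O"):
            if role in best:
                p = best[role].pos
                atoms[role] = np.array([p.x, p.y, p.z])
        side = [best[name] for name in best if name not in _MAIN_CHAIN_ATOMS]
        if side:
            atoms["SC"] = np.mean(
                [[a.pos.x, a.pos.y, a.pos.z] for a in side], axis=0
            )
        info = gemmi.find_tabulated_residue(res.name)
        aa = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
        idx += 1
        residues.append(Residue(idx, aa, atoms, auth_id=str(res.seqid.num)))
    return StructureModel(structure_id=Path(pdb_path).stem, residues=residues)


def write_structure(model: StructureModel, pdb_path: str | Path) -> None:
    """Write a :class:`StructureModel` as a minimal PDB file.

    The SC pseudo-atom is emitted as a CB atom so that re-reading the file
    recovers it as the (single-atom) side-chain centroid.
    """
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    ch = gemmi.Chain("A")
    elements = {"CA": "C", "N": "N", "O": "O", "SC": "C"}
    names = {"CA": "CA", "N": "N", "O": "O", "SC": "CB"}
    for res in model.residues:
        gr = gemmi.Residue()
        try:
            gr.name = seq3(res.aa).upper()
        except KeyError:
            gr.name = "UNK"
        gr.seqid = gemmi.SeqId(res.index, " ")
        for role in ("N", "CA", "O", "SC"):
            xyz = res.atoms.get(role)
            if xyz is None:
                continue
            at = gemmi.Atom()
            at.name = names[role]
            at.element = gemmi.Element(elements[role])
            at.pos = gemmi.Position(*map(float, xyz))
            at.occ = 1.0
            gr.add_atom(at)
        ch.add_residue(gr)
    gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(pdb_path))


# ---------------------------------------------------------------------------
# residue profiles
# ---------------------------------------------------------------------------


@dataclass
class ResidueProfiles:
    """Target prediction profiles plus template observed annotations.

    ``target_ss`` is an (N, 3) array of probabilities in state order H, E, C;
    ``target_burial`` an (N, 2) array in state order B (buried), E (exposed).
    Template annotations are one observed state letter per template residue.
    """

    target_ss: np.ndarray
    target_burial: np.ndarray
    template_ss: list[str]
    template_burial: list[str]

    def __post_init__(self) -> None:
        self.target_ss = np.asarray(self.target_ss, dtype=float)
        self.target_burial = np.asarray(self.target_burial, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.target_ss.ndim != 2 or self.target_ss.shape[1] != 3:
            raise ValidationError("target_ss must be (N, 3)")
        if self.target_burial.ndim != 2 or self.target_burial.shape[1] != 2:
            raise ValidationError("target_burial must be (N, 2)")
        if len(self.target_ss) != len(self.target_burial):
            raise ValidationError("ss and burial profiles differ in length")
        for arr, lo, hi, what in (
            (self.target_ss, 0.95, 1.05, "secondary-structure"),
            (self.target_burial, 0.99, 1.01, "burial"),
        ):
            if arr.size == 0:
                continue
            if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
                raise ValidationError(f"{what} probabilities outside [0, 1]")
            sums = arr.sum(axis=1)
            if np.any(sums < lo) or np.any(sums > hi):
                raise ValidationError(f"{what} probabilities do not sum to ~1")
        if any(s not in SS_STATES for s in self.template_ss):
            raise ValidationError("template SS state outside {H, E, C}")
        if any(s not in BURIAL_STATES for s in self.template_burial):
            raise ValidationError("template burial state outside {B, E}")
        if len(self.template_ss) != len(self.template_burial):
            raise ValidationError("template annotations differ in length")

    def ss_probability(self, target_index: int, state: str) -> float:
        return float(self.target_ss[target_index - 1, SS_STATES.index(state)])

    def burial_probability(self, target_index: int, state: str) -> float:
        return float(self.target_burial[target_index - 1, BURIAL_STATES.index(state)])


def _parse_float_rows(path, n_cols: int, what: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            try:
                vals = [float(t) for t in toks[-n_cols:]]
            except ValueError:
                if not rows:
                    continue  # header
                raise FormatError(f"{path}:{lineno}: cannot parse {what} row")
            if len(vals) != n_cols:
                raise FormatError(f"{path}:{lineno}: expected {n_cols} values")
            rows.append(vals)
    return np.array(rows, dtype=float).reshape(-1, n_cols)


def read_profiles(
    ss2_path: str | Path,
    acc_path: str | Path,
    template_annot_path: str | Path,
) -> ResidueProfiles:
    """Read target ss2/burial profiles and template state annotations.

    The ss2-style file carries, per target residue, three probabilities in
    column order C, H, E (the psipred ss2 convention; leading index/aa/state
    columns are ignored).  The burial file carries two probabilities per
    target residue in order B, E.  The template annotation TSV carries one SS
    state and one burial state per template residue.  Probability rows whose
    sum is within the documented tolerance are renormalised to 1; rows
    outside it are a format error.
    """
    raw_ss = _parse_float_rows(ss2_path, 3, "ss2")
    if np.any(raw_ss < 0) or np.any(raw_ss > 1):
        raise FormatError(f"{ss2_path}: probability outside [0, 1]")
    sums = raw_ss.sum(axis=1)
    if np.any(sums < 0.95) or np.any(sums > 1.05):
        raise FormatError(f"{ss2_path}: probability triplet sums outside [0.95, 1.05]")
    # reorder C,H,E -> H,E,C and renormalise
    ss = raw_ss[:, [1, 2, 0]] / sums[:, None]

    raw_acc = _parse_float_rows(acc_path, 2, "burial")
    if np.any(raw_acc < 0) or np.any(raw_acc > 1):
        raise FormatError(f"{acc_path}: probability outside [0, 1]")
    asums = raw_acc.sum(axis=1)
    if np.any(asums < 0.99) or np.any(asums > 1.01):
        raise FormatError(f"{acc_path}: probability pair sums outside [0.99, 1.01]")
    acc = raw_acc / asums[:, None]

    if len(ss) != len(acc):
        raise FormatError("ss2 and burial files disagree on target length")

    tpl_ss: list[str] = []
    tpl_acc: list[str] = []
    with open(template_annot_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if toks[-2:] == ["ss", "burial"] or toks[-2:] == ["ss_state", "burial_state"]:
                continue  # header
            if len(toks) < 2:
                raise FormatError(f"{template_annot_path}:{lineno}: expected 2 states")
            s, b = toks[-2], toks[-1]
            if s not in SS_STATES or b not in BURIAL_STATES:
                raise FormatError(
                    f"{template_annot_path}:{lineno}: bad state pair {s!r}/{b!r}"
                )
            tpl_ss.append(s)
            tpl_acc.append(b)
    return ResidueProfiles(ss, acc, tpl_ss, tpl_acc)


def write_profiles(
    profiles: ResidueProfiles,
    target_seq: str,
    ss2_path,
    acc_path,
    template_annot_path,
) -> None:
    with open(ss2_path, "w") as fh:
        fh.write("# ss2-style: index aa state p(C) p(H) p(E)\n\n")
        for i, (ph, pe, pc) in enumerate(profiles.target_ss):
            state = SS_STATES[int(np.argmax([ph, pe, pc]))]
            aa = target_seq[i] if i < len(target_seq) else "X"
            fh.write(f"{i + 1:4d} {aa} {state} {pc:7.3f} {ph:7.3f} {pe:7.3f}\n")
    with open(acc_path, "w") as fh:
        fh.write("index\tp_buried\tp_exposed\n")
        for i, (pb, pe) in enumerate(profiles.target_burial):
            fh.write(f"{i + 1}\t{pb:.6f}\t{pe:.6f}\n")
    with open(template_annot_path, "w") as fh:
        fh.write("index\tss\tburial\n")
        for i, (s, b) in enumerate(zip(profiles.template_ss, profiles.template_burial)):
            fh.write(f"{i + 1}\t{s}\t{b}\n")


# ---------------------------------------------------------------------------
# restraint tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RestraintRow:
    category: str
    I: int
    J: int
    role_1: str
    role_2: str
    d_template: float  # d' (angstrom)
    sigma: float  # angstrom
    dd: float | None = None  # |d_native - d_template|, when known


@dataclass
class RestraintTable:
    """A serialisable list of harmonic restraints."""

    rows: list[RestraintRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for r in self.rows:
            if r.category not in CATEGORIES:
                raise FormatError(f"unknown category {r.category!r}")
            if not (r.d_template > 0):
                raise ValidationError(f"d_template must be positive, got {r.d_template}")
            if r.d_template >= CUTOFFS[r.category]:
                raise ValidationError(
                    f"d_template {r.d_template} >= cutoff for {r.category}"
                )
            if not (r.sigma > 0):
                raise ValidationError(f"sigma must be positive, got {r.sigma}")
            if r.dd is not None and r.dd < 0:
                raise ValidationError("dd must be non-negative")

    def __len__(self) -> int:
        return len(self.rows)


_RESTRAINT_HEADER = ["category", "I", "J", "role_1", "role_2", "d_template", "sigma", "dd"]


def write_restraint_table(table: RestraintTable, path: str | Path) -> None:
    """Write a restraint table as TSV with fixed 6-decimal formatting."""
    table.validate()
    with open(path, "w") as fh:
        fh.write("\t".join(_RESTRAINT_HEADER) + "\n")
        for r in table.rows:
            dd = "" if r.dd is None else f"{r.dd:.6f}"
            fh.write(
                f"{r.category}\t{r.I}\t{r.J}\t{r.role_1}\t{r.role_2}\t"
                f"{r.d_template:.6f}\t{r.sigma:.6f}\t{dd}\n"
            )


def read_restraint_table(path: str | Path) -> RestraintTable:
    rows: list[RestraintRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _RESTRAINT_HEADER:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) != len(_RESTRAINT_HEADER):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            cat, i, j, r1, r2, dt, sg, dd = toks
            rows.append(
                RestraintRow(
                    category=cat,
                    I=int(i),
                    J=int(j),
                    role_1=r1,
                    role_2=r2,
                    d_template=float(dt),
                    sigma=float(sg),
                    dd=float(dd) if dd else None,
                )
            )
    return RestraintTable(rows)


# ---------------------------------------------------------------------------
# trained models
# ---------------------------------------------------------------------------


def save_forests(forests: Mapping[str, "object"], path: str | Path) -> None:
    """Save per-category trained forests as versioned JSON.

    JSON float serialisation uses shortest round-trip repr, so a loaded
    forest predicts bit-identically to the saved one.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "forests": {cat: f.to_dict() for cat, f in forests.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_forests(path: str | Path) -> dict[str, "object"]:
    from .forest import RegressionForest

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: cannot read model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: model version {payload.get('version')!r} != {MODEL_VERSION}"
        )
    return {
        cat: RegressionForest.from_dict(d) for cat, d in payload["forests"].items()
    }
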