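import math

import numpy as np
import pytest

from restraintvar.io_formats import Residue, StructureModel, ValidationError
from restraintvar.restraints import (
    SQRT_2_OVER_PI,
    convert_sigma,
    enumerate_restraint_pairs,
    harmonic_energy,
    label_instances,
    restraint_table_energy,
    write_restraints_with_sigma,
)

from conftest import identity_alignment, line_structure, random_structure
from _oracles import oracle_pair_counts


def two_residue_structure(d: float) -> StructureModel:
    return StructureModel(
        "pair",
        [
            Residue(1, "A", {"CA": np.zeros(3)}),
            Residue(2, "A", {"CA": np.array([d, 0.0, 0.0])}),
        ],
    )


class TestEnumeration:
    def test_cutoff_is_strict(self):
        aln = identity_alignment(2)
        assert enumerate_restraint_pairs(aln, two_residue_structure(14.6), ("CACA",)) == []
        kept = enumerate_restraint_pairs(aln, two_residue_structure(14.4), ("CACA",))
        assert len(kept) == 1
        assert kept[0].d_template == pytest.approx(14.4)

    def test_single_residue_gives_nothing(self):
        aln = identity_alignment(1)
        template = line_structure(1)
        assert enumerate_restraint_pairs(aln, template) == []

    def test_four_collinear_residues_give_six_caca(self):
        # pairwise CA distances are 3.8, 7.6, 11.4 (all < 14.5): C(4,2) = 6
        aln = identity_alignment(4)
        inst = enumerate_restraint_pairs(aln, line_structure(4), ("CACA",))
        assert len(inst) == 6
        assert all(i.I < i.J for i in inst)

    def test_ordered_categories_enumerate_both_directions(self):
        aln = identity_alignment(2)
        template = line_structure(2, spacing=3.8)
        no = enumerate_restraint_pairs(aln, template, ("NO",))
        assert sorted((i.I, i.J) for i in no) == [(1, 2), (2, 1)]

    def test_ss_pairs_skip_missing_centroids(self):
        aln = identity_alignment(3)
        residues = line_structure(3, spacing=2.0).residues  # SC pairs within 5 A
        del residues[1].atoms["SC"]  # glycine-like
        template = StructureModel("t", residues)
        ss = enumerate_restraint_pairs(aln, template, ("SS",))
        assert sorted((i.I, i.J) for i in ss) == [(1, 3)]

    def test_counts_match_all_pairs_oracle_on_random_toys(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            template = random_structure(n, rng)
            aln = identity_alignment(n)
            inst = enumerate_restraint_pairs(aln, template)
            got = {c: sum(1 for i in inst if i.category == c) for c in ("CACA", "NO", "MS", "SS")}
            atoms = {
                r.index: {role: tuple(xyz) for role, xyz in r.atoms.items()}
                for r in template.residues
            }
            pairs = [(t, k) for _, t, k in aln.aligned_columns()]
            assert got == oracle_pair_counts(pairs, atoms)

    def test_output_order_is_deterministic(self):
        rng = np.random.default_rng(5)
        template = random_structure(12, rng)
        aln = identity_alignment(12)
        a = enumerate_restraint_pairs(aln, template)
        b = enumerate_restraint_pairs(aln, template)
        assert [(i.category, i.I, i.J) for i in a] == [(i.category, i.I, i.J) for i in b]
        keys = [(i.category, i.I, i.J) for i in a]
        order = {"CACA": 0, "NO": 1, "MS": 2, "SS": 3}
        assert keys == sorted(keys, key=lambda t: (order[t[0]], t[1], t[2]))


class TestLabels:
    def test_identical_native_gives_zero_dd(self):
        aln = identity_alignment(5)
        template = line_structure(5)
        inst = enumerate_restraint_pairs(aln, template)
        labelled = label_instances(inst, aln, template)
        assert labelled and all(i.dd == 0.0 for i in labelled)

    def test_simple_deviation(self):
        aln = identity_alignment(2)
        labelled = label_instances(
            enumerate_restraint_pairs(aln, two_residue_structure(7.0), ("CACA",)),
            aln,
            two_residue_structure(10.0),
        )
        assert labelled[0].dd == pytest.approx(3.0)

    def test_dd_matches_recomputation_from_raw_coordinates(self):
        rng = np.random.default_rng(11)
        n = 15
        template = random_structure(n, rng, sid="tpl")
        native = random_structure(n, rng, sid="nat")
        aln = identity_alignment(n)
        inst = enumerate_restraint_pairs(aln, template)
        labelled = label_instances(inst, aln, native)
        nat_atoms = {r.index: r.atoms for r in native.residues}
        for i in labelled:
            a = nat_atoms[i.I].get(i.role_1)
            b = nat_atoms[i.J].get(i.role_2)
            expected = abs(math.dist(a, b) - i.d_template)
            assert i.dd == pytest.approx(expected, abs=1e-12)

    def test_missing_native_atoms_are_dropped(self):
        aln = identity_alignment(3)
        template = line_structure(3)
        native_res = line_structure(3).residues
        del native_res[2].atoms["SC"]
        native = StructureModel("nat", native_res)
        inst = enumerate_restraint_pairs(aln, template, ("SS",))
        report = {}
        labelled = label_instances(inst, aln, native, drop_report=report)
        assert report["dropped"] == len(inst) - len(labelled) > 0


class TestSigmaConversion:
    def test_known_value(self):
        assert convert_sigma(1.0, "modeller_to_rf") == pytest.approx(0.7978845608, abs=1e-9)

    def test_zero_maps_to_zero(self):
        assert convert_sigma(0.0, "modeller_to_rf") == 0.0
        assert convert_sigma(0.0, "rf_to_modeller") == 0.0

    def test_directions_are_exact_inverses(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, 100)
        back = convert_sigma(convert_sigma(x, "modeller_to_rf"), "rf_to_modeller")
        assert np.allclose(back, x, rtol=1e-15, atol=0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            convert_sigma(-0.5, "modeller_to_rf")

    def test_mean_absolute_deviation_of_gaussian(self):
        # <|X|> for X ~ N(0, sigma^2) equals sqrt(2/pi) * sigma
        rng = np.random.default_rng(123)
        for sigma in (0.5, 2.0):
            draws = np.abs(rng.normal(0, sigma, 10**6))
            assert draws.mean() == pytest.approx(SQRT_2_OVER_PI * sigma, rel=5e-3)


class TestHarmonicEnergy:
    def test_closed_forms(self):
        assert harmonic_energy(5.0, 5.0, 1.3) == 0.0
        assert harmonic_energy(6.0, 5.0, 1.0) == pytest.approx(0.5)
        assert harmonic_energy(5.0, 3.0, 1.0) == pytest.approx(2.0)

    def test_random_triples_match_direct_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            d, dp = rng.uniform(0, 15, 2)
            s = rng.uniform(0.05, 5)
            assert harmonic_energy(d, dp, s) == pytest.approx(0.5 * ((d - dp) / s) ** 2, rel=1e-12)

    def test_sign_symmetry_and_sigma_scaling(self):
        assert harmonic_energy(7.0, 5.0, 1.1) == harmonic_energy(3.0, 5.0, 1.1)
        assert harmonic_energy(6.0, 5.0, 0.5) == pytest.approx(4 * harmonic_energy(6.0, 5.0, 1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            harmonic_energy(1.0, 1.0, 0.0)

    def test_table_energy_sums_rows(self):
        aln = identity_alignment(3)
        template = line_structure(3)
        inst = enumerate_restraint_pairs(aln, template, ("CACA",))
        for i in inst:
            i.sigma = 1.0
        table = write_restraints_with_sigma(inst)
        # native displaced along x by stretching: energies recomputed by hand
        native = line_structure(3, spacing=4.0)
        expected = sum(
            0.5 * ((abs(r.I - r.J) * 4.0 - r.d_template) / r.sigma) ** 2 for r in table.rows
        )
        assert restraint_table_energy(table, native) == pytest.approx(expected, rel=1e-12)


class TestRestraintWriting:
    def _instances(self, sigmas):
        aln = identity_alignment(len(sigmas) + 1)
        template = line_structure(len(sigmas) + 1)
        inst = enumerate_restraint_pairs(aln, template, ("CACA",))[: len(sigmas)]
        for i, s in zip(inst, sigmas):
            i.sigma = s
        return inst

    def test_floor_and_cap_clipping(self):
        inst = self._instances([0.001, 20.0, 1.0])
        table = write_restraints_with_sigma(inst, floor=0.05, cap=15.0)
        assert sorted(r.sigma for r in table.rows) == [0.05, 1.0, 15.0]

    def test_row_conservation(self):
        inst = self._instances([1.0] * 3)
        table = write_restraints_with_sigma(inst)
        assert len(table) == 3
        assert {r.category for r in table.rows} == {"CACA"}

    def test_invalid_floor_rejected(self):
        with pytest.raises(ValueError):
            write_restraints_with_sigma(self._instances([1.0]), floor=0.0)

    def test_missing_sigma_rejected(self):
        inst = self._instances([1.0])
        inst[0].sigma = None
        with pytest.raises(ValidationError):
            write_restraints_with_sigma(inst)
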