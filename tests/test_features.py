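import numpy as np
import pytest

from restraintvar.features import (
    FEATURE_NAMES,
    compute_feature_vector,
    consistency_scores,
    feature_matrix,
    nearest_gap_reciprocal,
    span_average_match,
)
from restraintvar.io_formats import ResidueProfiles, ValidationError
from restraintvar.restraints import RestraintInstance, enumerate_restraint_pairs

from conftest import (
    FIXTURE_K_ROW,
    FIXTURE_SCORES,
    FIXTURE_T_ROW,
    identity_alignment,
    line_structure,
    make_alignment,
    make_profiles,
)
from _oracles import oracle_features


def instance(I, J, K, L, d=5.0, category="CACA"):
    return RestraintInstance(
        category=category, I=I, J=J, K=K, L=L, role_1="CA", role_2="CA", d_template=d
    )


class TestNearestGapReciprocal:
    def test_adjacent_gap_gives_unity(self):
        aln = make_alignment("AC-DE", "ACFDE", [0.5, 0.5, 0.5, 0.5])
        assert nearest_gap_reciprocal(aln, "target", 2) == 1.0  # residue C at col 1

    def test_gapless_row_gives_zero(self):
        aln = make_alignment("ACDE", "ACDE", [0.5] * 4)
        assert nearest_gap_reciprocal(aln, "target", 3) == 0.0
        assert nearest_gap_reciprocal(aln, "template", 3) == 0.0

    def test_distance_counted_in_columns_both_directions(self):
        # 12 columns; target-row gap at column 9 (0-based); residue at column 5
        t_row = "ABCDEFGHI-KL"
        k_row = "ABCDEFGHIJKL"
        scores = [0.5] * 11
        aln = make_alignment(t_row, k_row, scores)
        # residue at column 5 is the 6th target residue; gap is 4 columns away
        assert nearest_gap_reciprocal(aln, "target", 6) == 0.25

    def test_unknown_residue_rejected(self):
        aln = identity_alignment(4)
        with pytest.raises(ValidationError):
            nearest_gap_reciprocal(aln, "target", 99)


class TestSpanAverageMatch:
    def test_two_term_mean(self):
        aln = make_alignment("AB", "AB", [0.4, 0.8])
        assert span_average_match(aln, 1, 2) == pytest.approx(0.6)

    def test_constant_scores(self):
        aln = identity_alignment(6, score=0.37)
        assert span_average_match(aln, 2, 5) == pytest.approx(0.37)

    def test_span_with_target_gap_skips_unaligned_columns(self):
        # 5 columns, target gap at column 2: aligned scores 0.2 0.4 0.6 0.8
        aln = make_alignment("AB-CD", "ABXCD", [0.2, 0.4, 0.6, 0.8])
        assert span_average_match(aln, 1, 4) == pytest.approx(0.5)

    def test_unaligned_endpoint_rejected(self):
        aln = make_alignment("ABC", "A-C", [0.2, 0.8])
        with pytest.raises(ValidationError):
            span_average_match(aln, 1, 2)  # target residue 2 aligned to gap


class TestConsistencyScores:
    def _profiles(self, ss_row, acc_row=(0.5, 0.5), tpl=("H", "B")):
        return ResidueProfiles(
            np.array([ss_row]), np.array([acc_row]), [tpl[0]], [tpl[1]]
        )

    def test_probability_lookup(self):
        prof = self._profiles([0.9, 0.05, 0.05])
        ss, _ = consistency_scores(prof, 1, 1, mode="prob")
        assert ss == pytest.approx(0.9)

    def test_one_hot_limit_both_modes_agree(self):
        match = self._profiles([1.0, 0.0, 0.0], (1.0, 0.0), ("H", "B"))
        miss = self._profiles([0.0, 1.0, 0.0], (1.0, 0.0), ("H", "B"))
        for mode in ("prob", "delta"):
            assert consistency_scores(match, 1, 1, mode) == (1.0, 1.0)
            assert consistency_scores(miss, 1, 1, mode)[0] == 0.0

    def test_uniform_profile_gives_one_third(self):
        prof = self._profiles([1 / 3, 1 / 3, 1 / 3])
        for state in ("H", "E", "C"):
            prof.template_ss[0] = state
            assert consistency_scores(prof, 1, 1, "prob")[0] == pytest.approx(1 / 3)

    def test_missing_annotation_rejected(self):
        prof = self._profiles([0.9, 0.05, 0.05])
        with pytest.raises(ValidationError):
            consistency_scores(prof, 1, 5)


class TestComputeFeatureVector:
    def test_separation_features(self):
        aln = identity_alignment(50)
        prof = make_profiles(50, 50)
        f = compute_feature_vector(instance(3, 10, 3, 10), aln, prof)
        assert f[0] == 7
        assert f[1] == pytest.approx(0.14)

    def test_gapless_identity_degenerate_case(self):
        aln = identity_alignment(20)
        prof = make_profiles(20, 20)
        f = compute_feature_vector(instance(4, 9, 4, 9), aln, prof)
        assert f[5] == f[6] == f[9] == f[10] == 0  # F6, F7, F10, F11
        assert f[7] == f[8] == f[11] == f[12] == 0  # F8, F9, F12, F13
        assert f[18] == f[17]  # F19 = F18
        assert f[19] == f[18]  # F20 = F19

    def test_ordered_instance_uses_sorted_endpoints(self):
        aln = identity_alignment(20)
        prof = make_profiles(20, 20)
        fwd = compute_feature_vector(instance(4, 9, 4, 9, category="NO"), aln, prof)
        rev = compute_feature_vector(instance(9, 4, 9, 4, category="NO"), aln, prof)
        assert np.array_equal(fwd, rev)

    def test_fixture_matches_string_scanning_oracle(self, fixture15):
        aln = fixture15["alignment"]
        prof = fixture15["profiles"]
        # enumerate CACA pairs over a toy template with one residue per
        # template index, then check every feature against the oracle
        n_template = sum(1 for c in FIXTURE_K_ROW if c != "-")
        template = line_structure(n_template)
        inst = enumerate_restraint_pairs(aln, template, ("CACA",))
        assert inst, "fixture must enumerate at least one pair"
        for i in inst:
            got = compute_feature_vector(i, aln, prof)
            expected = oracle_features(
                FIXTURE_T_ROW,
                FIXTURE_K_ROW,
                FIXTURE_SCORES,
                prof.target_ss,
                prof.target_burial,
                prof.template_ss,
                prof.template_burial,
                aln.target_length,
                i.I,
                i.J,
                i.d_template,
            )
            assert got == pytest.approx(expected, abs=1e-12)

    def test_gap_adjacency_statements_hold_on_fixture(self, fixture15):
        aln = fixture15["alignment"]
        # target residue 5 (F, column 4) sits next to the target gap block
        assert nearest_gap_reciprocal(aln, "target", 5) == 1.0
        # template row of a gapless alignment scores zero
        gapless = identity_alignment(8)
        assert nearest_gap_reciprocal(gapless, "template", 4) == 0.0


class TestFeatureInvariants:
    def _fixture_frame(self, fixture15):
        aln = fixture15["alignment"]
        prof = fixture15["profiles"]
        n_template = sum(1 for c in FIXTURE_K_ROW if c != "-")
        template = line_structure(n_template)
        inst = enumerate_restraint_pairs(aln, template)
        return feature_matrix(inst, aln, prof)

    def test_composite_feature_orderings(self, fixture15):
        df = self._fixture_frame(fixture15)
        assert (df["F18"] <= df["F4"] + 1e-12).all()
        assert (df["F19"] <= df["F18"] + 1e-12).all()
        assert (df["F20"] <= df["F19"] + 1e-12).all()

    def test_padding_columns_only_affect_gap_reciprocals(self, fixture15):
        prof = fixture15["profiles"]
        base = make_alignment(FIXTURE_T_ROW, FIXTURE_K_ROW, FIXTURE_SCORES)
        # pad past the end with target-row gap columns: extra template
        # residues exist but are unaligned; the target chain is unchanged
        padded = make_alignment(
            FIXTURE_T_ROW + "--",
            FIXTURE_K_ROW + "WW",
            FIXTURE_SCORES,
        )
        assert padded.target_length == base.target_length
        inst = instance(2, 7, 2, 7)
        f_base = compute_feature_vector(inst, base, prof)
        f_pad = compute_feature_vector(inst, padded, prof)
        moved = {7, 8, 11, 12}  # 0-based indices of F8, F9, F12, F13
        for i in range(20):
            if i in moved or i >= 17:  # composites inherit the change
                continue
            assert f_pad[i] == pytest.approx(f_base[i], abs=1e-12), FEATURE_NAMES[i]
        # reciprocals may only increase toward the new target-row gaps
        assert f_pad[7] >= f_base[7] and f_pad[8] >= f_base[8]

    def test_inserting_gap_in_span_never_decreases_gap_count(self, fixture15):
        prof = fixture15["profiles"]
        base = make_alignment("ABCDEFGH", "ABCDEFGH", [0.5] * 8)
        gapped = make_alignment("ABCD-EFGH", "ABCDXEFGH", [0.5] * 8)
        inst_b = instance(2, 7, 2, 7)
        f_b = compute_feature_vector(inst_b, base, make_profiles(8, 8))
        inst_g = instance(2, 7, 2, 8)  # template index shifts past the gap
        f_g = compute_feature_vector(inst_g, gapped, make_profiles(8, 9))
        assert f_g[5] + f_g[9] >= f_b[5] + f_b[9]  # F6 + F10
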