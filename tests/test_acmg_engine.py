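import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brca2hdr.acmg_engine import (
    KNOWN_DIVERGENT_ROWS,
    CombinerConfig,
    EvidenceInputError,
    EvidenceProfile,
    InSilicoVerdict,
    assign_frequency_code,
    assign_functional_code,
    assign_insilico_code,
    combine_evidence,
    combine_evidence_points,
    reclassification_summary,
    replay_table1,
)
from brca2hdr.hdr_quant import FunctionCall
from brca2hdr.variant_model import EvidenceCode, Strength, Tier

NF, F, IND = (
    FunctionCall.NON_FUNCTIONAL,
    FunctionCall.FUNCTIONAL,
    FunctionCall.INDETERMINATE,
)


def profile(*labels, gated_bs3=False, variant="v"):
    codes = []
    for label in labels:
        code = EvidenceCode.parse(label)
        if code.code_id == "BS3" and gated_bs3:
            code = EvidenceCode("BS3", gated=True)
        codes.append(code)
    return EvidenceProfile(variant, tuple(codes))


class TestFunctionalCode:
    def test_nonfunctional_yields_ps3(self):
        code = assign_functional_code(NF)
        assert code.code_id == "PS3" and code.applied_strength is Strength.STRONG

    def test_functional_with_splice_flag_is_gated(self):
        code = assign_functional_code(F, splice_impact_predicted=True)
        assert code.code_id == "BS3" and code.gated

    def test_indeterminate_yields_nothing(self):
        assert assign_functional_code(IND) is None


class TestInSilicoCode:
    @pytest.mark.parametrize(
        "score,verdict",
        [
            (0.50, InSilicoVerdict.PP3),
            (0.03, InSilicoVerdict.BP4),
            (0.20, InSilicoVerdict.INCONCLUSIVE),
            (0.431, InSilicoVerdict.INCONCLUSIVE),  # strict inequality
            (0.0560, InSilicoVerdict.INCONCLUSIVE),
        ],
    )
    def test_bayesdel_bands(self, score, verdict):
        assert assign_insilico_code(bayesdel_score=score) is verdict

    def test_provean_for_non_snv(self):
        assert assign_insilico_code(provean_score=-7.5) is InSilicoVerdict.PP3
        assert assign_insilico_code(provean_score=-2.0) is InSilicoVerdict.INCONCLUSIVE

    def test_exactly_one_score_required(self):
        with pytest.raises(EvidenceInputError):
            assign_insilico_code(bayesdel_score=0.5, provean_score=-7)
        with pytest.raises(EvidenceInputError):
            assign_insilico_code()


class TestFrequencyCode:
    def test_bs1_band_matches_printed_example(self):
        # 0.020% AFR filtering allele frequency -> BS1
        code = assign_frequency_code(0.00020, carrier_count=50)
        assert code.code_id == "BS1"

    def test_ba1_above_point_one_percent(self):
        assert assign_frequency_code(0.002, 500).code_id == "BA1"

    def test_single_carrier_gives_pm2_supporting(self):
        code = assign_frequency_code(1 / 282_912, carrier_count=1)
        assert code.code_id == "PM2"
        assert code.applied_strength is Strength.SUPPORTING

    def test_rare_but_multicarrier_gives_nothing(self):
        assert assign_frequency_code(5e-5, carrier_count=10) is None

    def test_negative_inputs_rejected(self):
        with pytest.raises(EvidenceInputError):
            assign_frequency_code(-0.1, 0)


class TestProfileInvariants:
    def test_pp3_bp4_mutually_exclusive(self):
        with pytest.raises(ValueError):
            profile("PP3", "BP4")

    def test_single_frequency_code(self):
        with pytest.raises(ValueError):
            EvidenceProfile(
                "v", (EvidenceCode("BA1", Strength.STAND_ALONE), EvidenceCode("BS1"))
            )

    def test_no_duplicate_ids(self):
        with pytest.raises(ValueError):
            profile("PS3", "PS3")


class TestCategoricalCombiner:
    @pytest.mark.parametrize(
        "labels,tier",
        [
            # combinations mirrored from transcribed classification rows
            (("PS3", "PM1_supp", "PP1"), Tier.LP),  # p.Ala2730Pro
            (("PS3", "PM2_supp"), Tier.VUS),  # p.Ala2780Asp
            (("PS3", "PM1", "PP1", "PM3_st", "PM2_supp"), Tier.P),  # p.Leu3101Arg
            (("PS3", "PM1", "PM5", "PP1", "PP3", "PM2_supp"), Tier.P),  # p.Asp2723Ala
            (("BS3",), Tier.LB),  # strong benign alone suffices
            ((), Tier.VUS),
            (("BA1",), Tier.B),
            (("BS3", "BS1"), Tier.B),
            (("PM1", "PM5", "PM3"), Tier.LP),  # three moderates
        ],
    )
    def test_rule_combinations(self, labels, tier):
        assert combine_evidence(profile(*labels)).tier is tier

    def test_conflict_policies_on_mixed_profile(self):
        # p.Ala3028Pro: PS3 + PM1 + PP1_mod + PM3 + PM2_supp vs BP4
        labels = ("PS3", "PM1", "PP1_mod", "PM3", "PM2_supp", "BP4")
        dominant = combine_evidence(
            profile(*labels), CombinerConfig(conflict_policy="pathogenic_dominant")
        )
        strict = combine_evidence(
            profile(*labels), CombinerConfig(conflict_policy="strict_vus")
        )
        assert dominant.tier is Tier.P and dominant.conflict_flag
        assert strict.tier is Tier.VUS and strict.conflict_flag

    def test_benign_result_stands_against_lone_pm2(self):
        result = combine_evidence(profile("BS3", "PM2_supp"))
        assert result.tier is Tier.LB and result.conflict_flag

    def test_larger_pathogenic_side_blocks_benign(self):
        result = combine_evidence(profile("BS3", "PM1", "PM2_supp"))
        assert result.tier is Tier.VUS and result.conflict_flag

    def test_gated_bs3_never_yields_benign(self):
        assert combine_evidence(profile("BS3")).tier is Tier.LB
        assert combine_evidence(profile("BS3", gated_bs3=True)).tier is Tier.VUS

    def test_svi_toggle_restores_2015_behaviour(self):
        config = CombinerConfig(svi_bs3_sufficient=False)
        assert combine_evidence(profile("BS3"), config).tier is Tier.VUS

    def test_policies_agree_on_single_direction(self):
        for labels in (("PS3", "PM1"), ("BS3", "BP4"), ("PM2_supp",)):
            a = combine_evidence(
                profile(*labels), CombinerConfig(conflict_policy="strict_vus")
            )
            b = combine_evidence(
                profile(*labels), CombinerConfig(conflict_policy="pathogenic_dominant")
            )
            assert a.tier is b.tier

    @settings(deadline=None, max_examples=100)
    @given(
        labels=st.lists(
            st.sampled_from(
                ["PS3", "PM1", "PM1_supp", "PM5", "PP1", "PP1_mod", "PM3",
                 "PM3_st", "PP3", "BS3", "BP2", "BP4"]
            ),
            unique_by=lambda s: s.split("_")[0],
            max_size=6,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance(self, labels, seed):
        """The categorical result depends only on the code multiset."""
        import random

        labels = [l for l in labels if not (l == "BP4" and "PP3" in labels)]
        shuffled = labels[:]
        random.Random(seed).shuffle(shuffled)
        assert (
            combine_evidence(profile(*labels)).tier
            is combine_evidence(profile(*shuffled)).tier
        )


TIER_RANK = {Tier.B: -2, Tier.LB: -1, Tier.VUS: 0, Tier.LP: 1, Tier.P: 2}


class TestPointsBackend:
    @pytest.mark.parametrize(
        "labels,tier",
        [
            (("PS3", "PM1_supp", "PP1"), Tier.LP),  # 4+1+1 = 6
            (("PS3", "PM2_supp", "BP4"), Tier.VUS),  # 4+1-1 = 4; p.Leu2753Pro
            (("BS3",), Tier.LB),  # -4
            (("PS3", "PM1", "PM3_st", "PM2_supp"), Tier.P),  # 4+2+4+1 = 11
            (("BS1", "BS3",), Tier.B),  # -8
        ],
    )
    def test_point_sums(self, labels, tier):
        assert combine_evidence_points(profile(*labels)).tier is tier

    @settings(deadline=None, max_examples=100)
    @given(
        labels=st.lists(
            st.sampled_from(
                ["PS3", "PM1", "PM5", "PP1", "PP3", "BS3", "BP2", "BP4"]
            ),
            unique_by=lambda s: s,
            max_size=5,
        ),
        extra=st.sampled_from(["PM3", "PP1_mod", "PM1_supp", "BS1", "BA1"]),
    )
    def test_monotonicity(self, labels, extra):
        """Adding a pathogenic code never moves the tier benign-ward and
        adding a benign code never moves it pathogenic-ward."""
        base_ids = {l.split("_")[0] for l in labels}
        extra_code = EvidenceCode.parse(extra)
        if extra_code.code_id in base_ids:
            return
        if "PP3" in base_ids and extra_code.code_id == "BP4":
            return
        freq = {"BA1", "BS1", "PM2"}
        if extra_code.code_id in freq and base_ids & freq:
            return
        try:
            before = combine_evidence_points(profile(*labels))
            after = combine_evidence_points(profile(*labels, extra))
        except ValueError:
            return
        if extra_code.direction.value == "pathogenic":
            assert TIER_RANK[after.tier] >= TIER_RANK[before.tier]
        else:
            assert TIER_RANK[after.tier] <= TIER_RANK[before.tier]


class TestReclassificationSummary:
    def test_direct_counts(self):
        pairs = [(Tier.VUS, Tier.LP), (Tier.VUS, Tier.VUS), (Tier.LB, Tier.LB)]
        summary = reclassification_summary(pairs)
        assert summary.n_vus_before == 2
        assert summary.n_vus_resolved == 1
        assert summary.resolution_rate == 0.5
        assert summary.n_to_lpp == 1 and summary.n_to_lbb == 0

    def test_identical_pairs_have_zero_off_diagonal(self):
        pairs = [(t, t) for t in Tier] * 3
        matrix = reclassification_summary(pairs).matrix
        off = matrix.to_numpy().sum() - sum(
            matrix.loc[t.value, t.value] for t in Tier
        )
        assert off == 0

    def test_matrix_total_matches_pairs(self):
        pairs = [(Tier.VUS, Tier.LP)] * 5 + [(Tier.VUS, Tier.LB)] * 7
        summary = reclassification_summary(pairs)
        assert summary.matrix.to_numpy().sum() == 12
        assert summary.n_to_lpp == 5 and summary.n_to_lbb == 7


class TestTable1Replay:
    def test_consistent_rows_all_match(self):
        """Rows outside the frozen divergent set reproduce exactly; divergent
        rows (undisclosed internal evidence) all sit above the engine tier."""
        df = replay_table1()
        assert len(df) == 63  # observed rows
        consistent = df[~df["hgvs_p"].isin(KNOWN_DIVERGENT_ROWS)]
        assert consistent["match"].all()
        divergent = df[df["hgvs_p"].isin(KNOWN_DIVERGENT_ROWS)]
        assert set(divergent["hgvs_p"]) == KNOWN_DIVERGENT_ROWS
        assert not divergent["match"].any()
        rank = {"VUS": 0, "LP": 1, "P": 2}
        assert all(
            rank[r.printed_tier] > rank[r.engine_tier]
            for r in divergent.itertuples()
        )

    def test_every_observed_row_keeps_ps3(self):
        df = replay_table1()
        assert df["codes"].str.contains("PS3").all()
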