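import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from brca2hdr.calibration import (
    CalibrationInputError,
    ControlSet,
    ControlVariant,
    EvidenceStrength,
    StrengthMap,
    Truth,
    calibration_report,
    compute_oddspath,
    confusion_counts,
    exact_binomial_ci,
    oddspath_to_strength,
    read_controls,
    write_controls,
)
from brca2hdr.hdr_quant import FunctionCall

NF, F, IND = (
    FunctionCall.NON_FUNCTIONAL,
    FunctionCall.FUNCTIONAL,
    FunctionCall.INDETERMINATE,
)


class TestConfusionCounts:
    def test_perfect_separation_on_default_design(self, perfect_calls):
        controls = ControlSet.from_counts()
        cc = confusion_counts(perfect_calls(controls), controls)
        assert (cc.tp, cc.fn, cc.tn, cc.fp, cc.n_indeterminate) == (20, 0, 46, 0, 0)
        assert cc.sensitivity == 1.0 and cc.specificity == 1.0

    def test_all_indeterminate(self):
        controls = ControlSet.from_counts()
        calls = {v.variant_id: IND for v in controls.variants}
        cc = confusion_counts(calls, controls)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (0, 0, 0, 0)
        assert cc.n_indeterminate == 66

    def test_false_negative_is_listed(self, perfect_calls):
        controls = ControlSet.from_counts()
        calls = perfect_calls(controls)
        victim = controls.variants[0].variant_id
        calls[victim] = F
        cc = confusion_counts(calls, controls)
        assert cc.fn == 1
        assert victim in cc.misclassified_ids

    def test_missing_call_errors_with_variant(self, perfect_calls):
        controls = ControlSet.from_counts(2, 2, 0, 0)
        calls = perfect_calls(controls)
        missing = controls.variants[-1].variant_id
        del calls[missing]
        with pytest.raises(CalibrationInputError, match=missing):
            confusion_counts(calls, controls)

    def test_order_invariance(self, perfect_calls):
        controls = ControlSet.from_counts(5, 7, 0, 0)
        calls = perfect_calls(controls)
        shuffled = ControlSet(tuple(reversed(controls.variants)))
        a = confusion_counts(calls, controls)
        b = confusion_counts(calls, shuffled)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)


def _oracle_ci(x, n, level=0.95):
    """Brute-force Clopper-Pearson: invert the binomial tail probabilities."""
    alpha = 1 - level
    lower = 0.0
    if x > 0:
        lower = optimize.brentq(
            lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13,
        )
    upper = 1.0
    if x < n:
        upper = optimize.brentq(
            lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13,
        )
    return lower, upper


class TestExactBinomialCI:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (20, 20, (0.025 ** (1 / 20), 1.0)),
            (0, 20, (0.0, 1 - 0.025 ** (1 / 20))),
            (1, 1, (0.025, 1.0)),
        ],
    )
    def test_closed_forms(self, x, n, expected):
        lo, hi = exact_binomial_ci(x, n)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert hi == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("x,n", [(3, 10), (7, 19), (46, 46), (0, 5), (13, 200)])
    def test_agrees_with_tail_inversion_oracle(self, x, n):
        lo, hi = exact_binomial_ci(x, n)
        olo, ohi = _oracle_ci(x, n)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)


class TestOddsPath:
    def test_full_control_set_gives_forty_six(self, perfect_calls):
        controls = ControlSet.from_counts()
        result = compute_oddspath(controls, perfect_calls(controls))
        assert result.oddspath == 46.0
        assert result.strength is EvidenceStrength.STRONG
        assert result.p1 == pytest.approx(20 / 66)
        assert result.p2 == pytest.approx(20 / 21)
        assert result.corrected

    def test_held_out_subset_gives_thirty_two(self, perfect_calls):
        controls = ControlSet.from_counts()
        result = compute_oddspath(controls.held_out_subset(), perfect_calls(controls))
        assert result.oddspath == 32.0

    def test_minimal_one_one_set(self, perfect_calls):
        controls = ControlSet.from_counts(1, 1, 0, 0)
        result = compute_oddspath(controls, perfect_calls(controls))
        assert result.p1 == 0.5
        assert result.p2 == 0.5
        assert result.oddspath == 1.0

    @settings(deadline=None, max_examples=60)
    @given(p=st.integers(1, 100), b=st.integers(1, 100))
    def test_perfect_separation_theorem(self, p, b):
        """Perfect separation + the TP/(TP+1) correction gives oddspath == b."""
        controls = ControlSet.from_counts(p, b, 0, 0)
        calls = {
            v.variant_id: NF if v.truth is Truth.PATHOGENIC else F
            for v in controls.variants
        }
        assert compute_oddspath(controls, calls).oddspath == float(b)

    def test_benign_direction_mirrors(self, perfect_calls):
        controls = ControlSet.from_counts()
        result = compute_oddspath(controls, perfect_calls(controls), direction="benign")
        # reciprocal equals the pathogenic-control count exactly
        assert 1 / result.oddspath == pytest.approx(20.0)
        assert result.strength is EvidenceStrength.STRONG

    def test_imperfect_separation_uses_raw_proportion(self, perfect_calls):
        controls = ControlSet.from_counts(10, 10, 0, 0)
        calls = perfect_calls(controls)
        benign_id = [v for v in controls.variants if v.truth is Truth.BENIGN][0].variant_id
        calls[benign_id] = NF  # one false positive
        result = compute_oddspath(controls, calls)
        assert not result.corrected
        assert result.p2 == pytest.approx(10 / 11)
        assert result.oddspath == pytest.approx(10.0)

    def test_no_abnormal_readouts_errors(self):
        controls = ControlSet.from_counts(2, 2, 0, 0)
        calls = {v.variant_id: F for v in controls.variants}
        with pytest.raises(CalibrationInputError, match="abnormal"):
            compute_oddspath(controls, calls)

    def test_zero_p2_gives_zero_oddspath(self):
        controls = ControlSet.from_counts(2, 2, 0, 0)
        calls = {
            v.variant_id: F if v.truth is Truth.PATHOGENIC else NF
            for v in controls.variants
        }
        result = compute_oddspath(controls, calls)
        assert result.oddspath == 0.0


class TestStrengthMap:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (46.0, EvidenceStrength.STRONG),
            (18.7, EvidenceStrength.MODERATE),  # strict '>' at the boundary
            (400.0, EvidenceStrength.VERY_STRONG),
            (3.0, EvidenceStrength.SUPPORTING),
            (1.0, EvidenceStrength.INSUFFICIENT),
        ],
    )
    def test_pathogenic_tiers(self, value, expected):
        assert oddspath_to_strength(value) is expected

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.05, EvidenceStrength.STRONG),
            (1 / 18.7, EvidenceStrength.MODERATE),
            (0.6, EvidenceStrength.INSUFFICIENT),
        ],
    )
    def test_benign_tiers_reciprocal(self, value, expected):
        assert oddspath_to_strength(value, direction="benign") is expected

    def test_cutoffs_must_decrease(self):
        with pytest.raises(ValueError):
            StrengthMap(very_strong=10, strong=18.7, moderate=4.3, supporting=2.1)


class TestCalibrationReport:
    def test_full_and_held_out_sections(self, perfect_calls):
        controls = ControlSet.from_counts()
        report = calibration_report(controls, perfect_calls(controls))
        assert report["full"]["sensitivity"] == 1.0
        assert report["full"]["specificity"] == 1.0
        assert report["full"]["oddspath_pathogenic"]["oddspath"] == 46.0
        assert report["held_out"]["oddspath_pathogenic"]["oddspath"] == 32.0
        lo, _ = report["full"]["sensitivity_ci"]
        assert lo == pytest.approx(0.832, abs=5e-4)

    def test_controls_round_trip(self, tmp_path):
        controls = ControlSet.from_counts(3, 4, 1, 2)
        path = tmp_path / "controls.tsv"
        write_controls(controls, path)
        assert read_controls(path) == controls
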