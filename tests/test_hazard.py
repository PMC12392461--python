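import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bphazard.hazard import (
    CensoredInputError,
    classify_substitute,
    classify_tr,
    cumulative_sr_score,
    rep,
    specificity_ratio,
    sr_score,
    toxic_ratio,
)
from bphazard.pipeline import round_sig


class TestRep:
    def test_bp_mibk_is_26x_bpa(self):
        assert round_sig(rep(3.70e-7, 1.43e-8)) == 26

    def test_bpa_vs_estradiol(self):
        assert round_sig(rep(3.70e-7, 1.98e-11), 3) == 18700

    def test_identity(self):
        assert rep(2.2e-6, 2.2e-6) == 1.0

    def test_censored_input_flagged(self):
        with pytest.raises(CensoredInputError):
            rep(None, 1e-6)
        with pytest.raises(CensoredInputError):
            rep(1e-6, None)

    @given(a=st.floats(1e-12, 1e-2), b=st.floats(1e-12, 1e-2))
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_symmetry(self, a, b):
        assert rep(a, b) * rep(b, a) == pytest.approx(1.0, rel=1e-12)


class TestToxicRatio:
    @pytest.mark.parametrize(
        "baseline, experimental, expected",
        [(1e-5, 1e-5, 1.0), (2.6e-4, 2.6e-5, 10.0), (2.6e-5, 2.6e-4, 0.1)],
    )
    def test_ratio(self, baseline, experimental, expected):
        assert toxic_ratio(baseline, experimental) == pytest.approx(expected)

    @given(
        a=st.floats(1e-9, 1e-2),
        b=st.floats(1e-9, 1e-2),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, a, b, k):
        assert toxic_ratio(k * a, k * b) == pytest.approx(
            toxic_ratio(a, b), rel=1e-9
        )

    @pytest.mark.parametrize(
        "tr, band",
        [
            (10.0, "specific"),
            (50.0, "specific"),
            (1.0, "baseline"),
            (9.99, "baseline"),
            (0.11, "baseline"),
            (0.1, "below_baseline"),
            (0.05, "below_baseline"),
        ],
    )
    def test_banding(self, tr, band):
        assert classify_tr(tr) == band


class TestSpecificityRatio:
    def test_cytotoxicity_source_preferred(self):
        sr, source = specificity_ratio(7.00e-5, 1e-3, 3.70e-7)
        assert sr == pytest.approx(189, rel=5e-3)
        assert source == "cytotoxicity"

    def test_effect_at_cytotoxic_concentration(self):
        sr, _ = specificity_ratio(1e-5, None, 1e-5)
        assert sr == 1.0

    def test_baseline_fallback(self):
        sr, source = specificity_ratio(None, 1e-4, 1e-5)
        assert sr == 10.0
        assert source == "baseline"

    def test_no_ic10_at_all(self):
        with pytest.raises(ValueError):
            specificity_ratio(None, None, 1e-6)


class TestSrScore:
    def test_midpoint(self):
        assert sr_score(5.0) == 0.5

    def test_effect_at_cytotoxicity_scores_near_zero(self):
        assert sr_score(1.0) == pytest.approx(0.0180, abs=5e-5)

    def test_specific_activation_scores_near_one(self):
        assert sr_score(10.0) == pytest.approx(0.9933, abs=5e-5)
        assert sr_score(10.0) < 1.0  # the asymptote is not clipped

    @given(x=st.floats(0, 4.9))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_about_midpoint(self, x):
        assert sr_score(5 + x) + sr_score(5 - x) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_monotone(self):
        # strict within the numerically representable range; the transform
        # saturates to 1.0 in double precision for SR beyond ~40
        srs = [0.1, 0.5, 1, 2, 5, 8, 10, 20, 30]
        scores = [sr_score(s) for s in srs]
        assert all(a < b for a, b in zip(scores, scores[1:]))


class TestCumulativeScore:
    def test_saturated_battery_scores_six(self):
        assert round(cumulative_sr_score([100.0] * 6)) == 6

    def test_empty_battery(self):
        assert cumulative_sr_score([]) == 0.0

    def test_single_midpoint(self):
        assert cumulative_sr_score([5.0]) == 0.5

    def test_monotone_under_added_endpoint(self):
        base = cumulative_sr_score([5.0, 20.0])
        assert cumulative_sr_score([5.0, 20.0, 0.5]) > base


class TestSubstitutionCall:
    @pytest.mark.parametrize(
        "sigma, sigma_ref, rep_ic10, expected",
        [
            (2.0, 1.54, 1.5, "regrettable"),
            (0.01, 1.54, 0.0084, "not_flagged"),
            (1.54, 1.54, 2.0, "regrettable"),  # "equal or higher" boundary
            (2.0, 1.54, 1.0, "not_flagged"),  # REP must strictly exceed 1
        ],
    )
    def test_rule(self, sigma, sigma_ref, rep_ic10, expected):
        assert classify_substitute(sigma, sigma_ref, rep_ic10) == expected
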