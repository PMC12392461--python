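import numpy as np
import pandas as pd
import pytest

from bphazard.dose_response import (
    benchmark_concentration,
    emax_percent,
    fit_curve,
    fits_to_frame,
    frame_to_fits,
    format_censored,
    mask_cytotoxic,
    median_ic10,
    parse_benchmark,
)
from bphazard.simulate import GeneratorSpec, simulate_concentration_response


def points_on_curve(top, ec50, hill, concentrations):
    resp = top / (1.0 + (ec50 / np.asarray(concentrations)) ** hill)
    return pd.DataFrame({"concentration_M": concentrations, "response": resp})


class TestMasking:
    def test_strict_threshold(self):
        pts = pd.DataFrame(
            {"concentration_M": [1e-7, 1e-6, 1e-5], "response": [1, 5, 20]}
        )
        out = mask_cytotoxic(pts, 5e-6)
        assert list(out["concentration_M"]) == [1e-7, 1e-6]

    def test_censored_ic10_keeps_everything(self):
        pts = pd.DataFrame({"concentration_M": [1e-7, 1e-5], "response": [1, 20]})
        assert len(mask_cytotoxic(pts, None)) == 2

    def test_all_masked_gives_empty_then_censored_fit(self):
        pts = pd.DataFrame({"concentration_M": [1e-5, 2e-5], "response": [20, 30]})
        masked = mask_cytotoxic(pts, 1e-6)
        assert len(masked) == 0
        fit = fit_curve(masked, c_max=2e-5)
        assert not fit.active and fit.benchmark is None


class TestLogLogisticFit:
    @pytest.mark.parametrize("top", [12, 25, 38, 66, 100])
    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0])
    def test_inversion_consistency_on_exact_data(self, top, hill):
        """Fit + inversion reproduces the generating benchmark to <=0.1%."""
        ec50 = 1e-6
        conc = ec50 * np.logspace(-3, 3, 13)
        fit = fit_curve(points_on_curve(top, ec50, hill, conc), c_max=conc.max())
        assert fit.top == pytest.approx(top, rel=1e-3)
        assert fit.ec50 == pytest.approx(ec50, rel=1e-3)
        assert fit.hill == pytest.approx(hill, rel=1e-3)
        truth = ec50 / (top / 10.0 - 1.0) ** (1.0 / hill)
        bench, _ = benchmark_concentration(fit, "EC10")
        assert bench == pytest.approx(truth, rel=1e-3)

    def test_closed_form_benchmark(self):
        conc = np.logspace(-9, -3, 13)
        fit = fit_curve(points_on_curve(38.0, 1e-6, 1.0, conc))
        # c = ec50 / (38/10 - 1)
        assert fit.benchmark == pytest.approx(1e-6 / 2.8, rel=1e-3)
        assert fit.benchmark == pytest.approx(3.57e-7, rel=1e-2)

    def test_subthreshold_plateau_is_censored(self):
        conc = np.logspace(-9, -3, 13)
        fit = fit_curve(points_on_curve(8.0, 1e-6, 1.0, conc))
        assert fit.top == pytest.approx(8.0, rel=1e-3)
        assert not fit.active
        assert fit.benchmark is None

    def test_ic_type_fit_on_inhibition_scale(self):
        conc = np.logspace(-8, -2, 13)
        fit = fit_curve(
            points_on_curve(100.0, 1e-4, 1.5, conc), benchmark_type="IC10"
        )
        assert fit.top == pytest.approx(100.0, rel=1e-3)
        assert fit.benchmark == pytest.approx(1e-4 / 9.0 ** (1 / 1.5), rel=1e-3)

    def test_noisy_recovery_of_top(self):
        spec = GeneratorSpec(
            true_top=38.0, true_ec50=1e-6, true_hill=1.0, noise_sd=5.0, seed=7
        )
        fit = fit_curve(simulate_concentration_response(spec))
        assert emax_percent(fit) == pytest.approx(38.0, abs=5.0)

    def test_too_few_concentrations_raise(self):
        pts = pd.DataFrame({"concentration_M": [1e-6, 1e-5], "response": [5, 20]})
        with pytest.raises(ValueError, match="distinct concentrations"):
            fit_curve(pts)

    def test_ec10_invariant_to_masked_high_concentrations(self):
        ec50 = 1e-6
        conc = ec50 * np.logspace(-3, 3, 13)
        pts = points_on_curve(40.0, ec50, 1.0, conc)
        ic10 = 3e-5
        base = fit_curve(mask_cytotoxic(pts, ic10), c_max=conc.max())
        extra = pd.concat(
            [
                pts,
                pd.DataFrame(
                    {"concentration_M": [5e-5, 1e-4], "response": [90.0, 95.0]}
                ),
            ]
        )
        refit = fit_curve(mask_cytotoxic(extra, ic10), c_max=conc.max())
        assert refit.benchmark == pytest.approx(base.benchmark, rel=1e-9)

    def test_ec10_increasing_in_ec50_and_below_ec50(self):
        conc = np.logspace(-9, -2, 15)
        benches = []
        for ec50 in (1e-7, 1e-6, 1e-5):
            fit = fit_curve(points_on_curve(40.0, ec50, 1.0, conc))
            benches.append(fit.benchmark)
            assert fit.benchmark < ec50  # top > 20 puts EC10 left of EC50
        assert benches[0] < benches[1] < benches[2]


class TestInductionRatio:
    def test_exact_crossing(self):
        conc = np.linspace(1e-7, 1e-5, 10)
        ir = 1.0 + 0.5 * conc / 2e-6  # crosses 1.5 at exactly 2e-6
        pts = pd.DataFrame({"concentration_M": conc, "response": ir})
        fit = fit_curve(pts, model="linear_low_effect")
        assert fit.benchmark == pytest.approx(2e-6, rel=1e-9)
        assert fit.benchmark_se == pytest.approx(0.0, abs=1e-12)

    def test_flat_response_censored(self):
        conc = np.linspace(1e-7, 1e-5, 8)
        pts = pd.DataFrame({"concentration_M": conc, "response": np.ones(8)})
        fit = fit_curve(pts, model="linear_low_effect")
        assert not fit.active


class TestMedianIC10:
    @pytest.mark.parametrize(
        "values, expected, n_censored",
        [
            ([1e-5, 2e-5, 3e-5], 2e-5, 0),
            ([1e-5], 1e-5, 0),
            ([1e-5, 2e-5, None], 1.5e-5, 1),
            ([None, None], None, 2),
        ],
    )
    def test_median_excludes_censored(self, values, expected, n_censored):
        med, nc = median_ic10(values)
        assert nc == n_censored
        if expected is None:
            assert med is None
        else:
            assert med == pytest.approx(expected)


class TestCensoringRoundTrip:
    def test_marker_strings(self):
        assert format_censored(1.8e-2) == ">0.018"
        assert parse_benchmark(">1.8e-2") == (None, 1.8e-2)
        assert parse_benchmark("3.7e-07")[0] == pytest.approx(3.7e-7)
        assert parse_benchmark("") == (None, None)

    def test_fit_table_round_trip(self):
        conc = np.logspace(-9, -3, 13)
        active = fit_curve(
            points_on_curve(38.0, 1e-6, 1.0, conc), compound_id="A", assay_id="ERalpha"
        )
        censored = fit_curve(
            points_on_curve(8.0, 1e-6, 1.0, conc), compound_id="B", assay_id="ERalpha"
        )
        frame = fits_to_frame([active, censored])
        back = frame_to_fits(frame)
        assert back[0].benchmark == pytest.approx(active.benchmark, rel=1e-6)
        assert back[1].benchmark is None
        assert back[1].censor_bound == pytest.approx(conc.max(), rel=1e-6)
        assert frame.loc[1, "benchmark"].startswith(">")
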