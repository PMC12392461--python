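"""Concentration-response curve fitting and benchmark concentrations.

Effect data are fitted with a three-parameter log-logistic model with the
bottom fixed at zero,

    y(c) = top / (1 + (ec50 / c) ** hill),

where ``y`` is the response in percent of the reference compound's maximum
(or percent inhibition for cytotoxicity).  Benchmark concentrations are read
off the fitted curve by inversion:

* EC10 - concentration where the fitted response crosses 10% of the
  *reference* maximum (y = 10 on the normalised scale, not 10% of the
  compound's own plateau; the distinction matters for partial agonists).
* IC10 - the same at 10% inhibition of viability/confluency.
* EC_IR1.5 - concentration where the induction ratio of the oxidative
  stress assay crosses 1.5; derived from a linear fit of (IR - 1) versus
  concentration over the low-effect region by default.

Concentrations at or above the cytotoxicity IC10 are removed before effect
curves are fitted (``mask_cytotoxic``), so that benchmarks reflect specific
activity rather than cytotoxic burst.  Benchmarks that are not reached below
the highest tested concentration are censored ("> c_max") and excluded from
downstream ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CurveFit",
    "mask_cytotoxic",
    "fit_curve",
    "fit_induction_ratio_linear",
    "benchmark_concentration",
    "emax_percent",
    "median_ic10",
    "fits_to_frame",
    "frame_to_fits",
    "format_censored",
    "parse_benchmark",
]

#: Benchmark response thresholds on the normalised scale.
THRESHOLDS = {"EC10": 10.0, "IC10": 10.0, "EC_IR1.5": 1.5}

_N_FREE_PARAMS = 3  # top, log10 ec50, hill


@dataclass
class CurveFit:
    """A fitted concentration-response curve plus its derived benchmark.

    ``benchmark`` is ``None`` when censored; ``censor_bound`` then carries
    the highest tested concentration, so the record prints as
    ``"> {censor_bound}"``.  ``cov`` is the covariance of
    (top, log10 ec50, hill) from the least-squares fit and feeds the
    first-order benchmark standard error.
    """

    compound_id: str = ""
    assay_id: str = ""
    model: str = "log_logistic"
    top: float = float("nan")
    ec50: float = float("nan")
    hill: float = float("nan")
    cov: np.ndarray | None = None
    benchmark_type: str = "EC10"
    benchmark: float | None = None
    benchmark_se: float | None = None
    censor_bound: float | None = None
    active: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return "no_convergence" not in self.flags and "no_data" not in self.flags


def mask_cytotoxic(points: pd.DataFrame, ic10: float | None) -> pd.DataFrame:
    """Drop response points at concentrations at or above the cytotoxicity IC10.

    ``ic10=None`` denotes a censored IC10 ("> c_max"), in which case no
    masking applies.  Row order is preserved.
    """
    if ic10 is None:
        return points
    if ic10 <= 0:
        raise ValueError(f"ic10 must be positive, got {ic10}")
    return points[points["concentration_M"] < ic10]


def _log_logistic(log_c: np.ndarray, top: float, log_ec50: float, hill: float) -> np.ndarray:
    return top / (1.0 + 10.0 ** (hill * (log_ec50 - log_c)))


def fit_curve(
    points: pd.DataFrame,
    model: str = "log_logistic",
    benchmark_type: str = "EC10",
    fixed_bottom: float = 0.0,
    c_max: float | None = None,
    compound_id: str = "",
    assay_id: str = "",
) -> CurveFit:
    """Least-squares log-logistic fit in log10-concentration space.

    Parameters
    ----------
    points : DataFrame
        Columns ``concentration_M`` (mol/L, > 0) and ``response``
        (normalised %, or induction ratio for ``model="linear_low_effect"``).
    model : {"log_logistic", "linear_low_effect"}
        The linear model is the conventional choice for the oxidative-stress
        induction ratio; see :func:`fit_induction_ratio_linear`.
    c_max : float, optional
        Highest tested concentration; defaults to the maximum in ``points``.
        Used as the censoring bound.

    Returns
    -------
    CurveFit with the benchmark of ``benchmark_type`` already derived.
    Non-convergence yields a censored record flagged ``no_convergence``
    rather than an exception.
    """
    if fixed_bottom != 0.0:
        raise NotImplementedError("only bottom = 0 is supported")
    if model == "linear_low_effect":
        return fit_induction_ratio_linear(
            points, c_max=c_max, compound_id=compound_id, assay_id=assay_id
        )
    if model != "log_logistic":
        raise ValueError(f"unknown model {model!r}")

    fit = CurveFit(
        compound_id=compound_id,
        assay_id=assay_id,
        model=model,
        benchmark_type=benchmark_type,
        censor_bound=c_max,
    )
    if len(points) == 0:
        fit.flags.append("no_data")
        return fit
    conc = np.asarray(points["concentration_M"], dtype=float)
    resp = np.asarray(points["response"], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    n_distinct = len(np.unique(conc))
    if n_distinct < _N_FREE_PARAMS:
        raise ValueError(
            f"need at least {_N_FREE_PARAMS} distinct concentrations, got {n_distinct}"
        )
    if c_max is None:
        fit.censor_bound = float(conc.max())

    log_c = np.log10(conc)
    top0 = max(float(np.nanmax(resp)), 1.0)
    # crude EC50 guess: concentration closest to half the apparent top
    half_idx = int(np.argmin(np.abs(resp - top0 / 2.0)))
    p0 = (top0, log_c[half_idx], 1.0)
    bounds = ([0.0, log_c.min() - 3.0, 0.05], [200.0, log_c.max() + 3.0, 10.0])
    try:
        popt, pcov = curve_fit(
            _log_logistic, log_c, resp, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        fit.flags.append("no_convergence")
        return fit
    if not np.all(np.isfinite(popt)):
        fit.flags.append("no_convergence")
        return fit

    fit.top = float(popt[0])
    fit.ec50 = float(10.0 ** popt[1])
    fit.hill = float(popt[2])
    fit.cov = pcov
    bench, se = _invert_log_logistic(fit, THRESHOLDS[benchmark_type])
    _attach_benchmark(fit, bench, se)
    return fit


def fit_induction_ratio_linear(
    points: pd.DataFrame,
    ir_cap: float = 5.0,
    c_max: float | None = None,
    compound_id: str = "",
    assay_id: str = "",
) -> CurveFit:
    """EC_IR1.5 from a zero-intercept linear fit of (IR - 1) vs concentration.

    Only the low-effect region (IR <= ``ir_cap``) enters the fit; the
    induction ratio of an untreated control is 1 by construction, so the
    line is forced through (0, 0) on the (concentration, IR - 1) plane.
    The benchmark is the concentration where the fitted line reaches
    IR = 1.5, i.e. 0.5 / slope.
    """
    fit = CurveFit(
        compound_id=compound_id,
        assay_id=assay_id,
        model="linear_low_effect",
        benchmark_type="EC_IR1.5",
        censor_bound=c_max,
    )
    if len(points) == 0:
        fit.flags.append("no_data")
        return fit
    conc_all = np.asarray(points["concentration_M"], dtype=float)
    if fit.censor_bound is None:
        fit.censor_bound = float(conc_all.max())
    low = points[points["response"] <= ir_cap]
    if len(low) == 0:
        fit.flags.append("no_convergence")
        return fit
    conc = np.asarray(low["concentration_M"], dtype=float)
    excess = np.asarray(low["response"], dtype=float) - 1.0
    slope = float(np.sum(conc * excess) / np.sum(conc**2))
    dof = len(conc) - 1
    if slope <= 0:
        fit.flags.append("nonpositive_slope")
        return fit
    resid = excess - slope * conc
    var_slope = (
        float(np.sum(resid**2)) / dof / float(np.sum(conc**2)) if dof > 0 else 0.0
    )
    bench = 0.5 / slope
    se = 0.5 * math.sqrt(var_slope) / slope**2
    fit.top = float("nan")
    fit.ec50 = float("nan")
    fit.hill = float("nan")
    _attach_benchmark(fit, bench, se)
    return fit


def _invert_log_logistic(fit: CurveFit, threshold: float) -> tuple[float | None, float | None]:
    """Closed-form inversion c = ec50 / (top/y - 1)**(1/hill) with a
    first-order (delta-method) standard error from the fit covariance."""
    if fit.top <= threshold:
        return None, None
    ratio = fit.top / threshold - 1.0
    log_bench = math.log10(fit.ec50) - math.log10(ratio) / fit.hill
    bench = 10.0 ** log_bench
    se = None
    if fit.cov is not None and np.all(np.isfinite(fit.cov)):
        ln10 = math.log(10.0)
        # gradient of log10(benchmark) wrt (top, log10 ec50, hill)
        g = np.array(
            [
                -1.0 / (fit.hill * ln10 * ratio * threshold),
                1.0,
                math.log10(ratio) / fit.hill**2,
            ]
        )
        var_log = float(g @ fit.cov @ g)
        if var_log >= 0:
            se = ln10 * bench * math.sqrt(var_log)
    return bench, se


def _attach_benchmark(fit: CurveFit, bench: float | None, se: float | None) -> None:
    if bench is None:
        fit.flags.append("below_threshold")
        fit.active = False
        fit.benchmark = None
        return
    if fit.censor_bound is not None and bench > fit.censor_bound:
        fit.flags.append("above_cmax")
        fit.active = False
        fit.benchmark = None
        return
    fit.benchmark = bench
    fit.benchmark_se = se
    fit.active = True


def benchmark_concentration(
    fit: CurveFit, benchmark_type: str | None = None
) -> tuple[float | None, float | None]:
    """Benchmark concentration (mol/L) and SE for a converged fit.

    Re-derives the benchmark when ``benchmark_type`` differs from the one
    stored on the fit.  Returns ``(None, None)`` when the fitted plateau sits
    below the threshold (censored, not an error).
    """
    if not fit.converged:
        raise ValueError("fit did not converge; no benchmark available")
    if benchmark_type is None or benchmark_type == fit.benchmark_type:
        return fit.benchmark, fit.benchmark_se
    if fit.model != "log_logistic":
        raise ValueError("benchmark re-derivation requires a log-logistic fit")
    return _invert_log_logistic(fit, THRESHOLDS[benchmark_type])


def emax_percent(fit: CurveFit) -> float:
    """Maximum efficacy: the fitted plateau in % of the reference maximum."""
    if not fit.converged:
        raise ValueError("fit did not converge; no Emax available")
    return fit.top


def median_ic10(ic10_values: list[float | None]) -> tuple[float | None, int]:
    """Median of uncensored IC10 values across cell lines.

    Censored entries (``None``) are excluded; their count is returned
    alongside.  All-censored input yields ``(None, n_censored)``.
    """
    uncensored = [v for v in ic10_values if v is not None]
    n_censored = len(ic10_values) - len(uncensored)
    if not uncensored:
        return None, n_censored
    return float(np.median(uncensored)), n_censored


def format_censored(bound: float | None) -> str:
    """Censoring marker, e.g. ``">1.8e-02"``."""
    return "" if bound is None else f">{bound:.6g}"


def parse_benchmark(text: str | float) -> tuple[float | None, float | None]:
    """Parse a benchmark cell: a number, or a ``">bound"`` censoring marker.

    Returns ``(value, censor_bound)``; exactly one is non-None for valid
    input, both are ``None`` for empty cells.
    """
    if isinstance(text, float):
        return (None, None) if math.isnan(text) else (text, None)
    s = str(text).strip()
    if not s:
        return None, None
    if s.startswith(">"):
        return None, float(s[1:])
    return float(s), None


_FIT_COLUMNS = [
    "compound_id",
    "assay_id",
    "model",
    "top",
    "ec50",
    "hill",
    "benchmark_type",
    "benchmark",
    "benchmark_se",
    "active",
    "flags",
]


def fits_to_frame(fits: list[CurveFit]) -> pd.DataFrame:
    """Tabulate fits; censored benchmarks become ``">bound"`` strings."""
    rows = []
    for f in fits:
        rows.append(
            {
                "compound_id": f.compound_id,
                "assay_id": f.assay_id,
                "model": f.model,
                "top": f.top,
                "ec50": f.ec50,
                "hill": f.hill,
                "benchmark_type": f.benchmark_type,
                "benchmark": f"{f.benchmark:.6g}"
                if f.benchmark is not None
                else format_censored(f.censor_bound),
                "benchmark_se": f.benchmark_se,
                "active": f.active,
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows, columns=_FIT_COLUMNS)


def frame_to_fits(df: pd.DataFrame) -> list[CurveFit]:
    """Inverse of :func:`fits_to_frame` (covariances are not round-tripped)."""
    fits = []
    for _, row in df.iterrows():
        bench, bound = parse_benchmark(row["benchmark"])
        fits.append(
            CurveFit(
                compound_id=row["compound_id"],
                assay_id=row["assay_id"],
                model=row["model"],
                top=float(row["top"]),
                ec50=float(row["ec50"]),
                hill=float(row["hill"]),
                benchmark_type=row["benchmark_type"],
                benchmark=bench,
                benchmark_se=None
                if pd.isna(row["benchmark_se"])
                else float(row["benchmark_se"]),
                censor_bound=bound,
                active=bool(row["active"]),
                flags=[f for f in str(row["flags"]).split(";") if f and f != "nan"],
            )
        )
    return fits
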