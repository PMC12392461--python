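"""Ratio metrics and cumulative scoring for comparative hazard assessment.

All metrics are unitless ratios of molar benchmark concentrations:

* REP  - relative effect potency, EC10(reference) / EC10(test); > 1 means
  the test compound is more potent than the reference.
* TR   - toxic ratio, predicted baseline IC10 / experimental IC10; TR >= 10
  flags a specific cytotoxicity mechanism, 0.1 < TR < 10 is the baseline
  band.
* SR   - specificity ratio, IC10 / EC10 (or EC_IR1.5): how far a specific
  effect sits below cytotoxic concentrations.  When no experimental IC10
  exists the predicted baseline IC10 substitutes (SR_baseline fallback).
* SR-Score - a logistic transform of SR with midpoint 5,
  1 / (1 + exp(-(SR - 5))), mapping "specifically activated" onto (0, 1).
* Cumulative SR-Score - the sum of SR-Scores over all active endpoints of
  the battery; bounded by the battery size and measures breadth of specific
  bioactivity.

A substitute is flagged "regrettable" when its Cumulative SR-Score is at
least that of the reference compound and its cytotoxicity REP exceeds 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "rep",
    "toxic_ratio",
    "classify_tr",
    "specificity_ratio",
    "sr_score",
    "cumulative_sr_score",
    "classify_substitute",
    "EndpointScore",
    "HazardProfile",
    "SR_SCORE_MIDPOINT",
]

#: Midpoint of the logistic SR -> SR-Score transform.
SR_SCORE_MIDPOINT = 5.0


class CensoredInputError(ValueError):
    """A ratio was requested from a censored benchmark concentration."""


def _require_positive(name: str, value: float | None) -> float:
    if value is None:
        raise CensoredInputError(f"{name} is censored; ratio undefined")
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


def rep(ec_reference: float | None, ec_test: float | None) -> float:
    """Relative effect potency: EC10(reference) / EC10(test)."""
    a = _require_positive("ec_reference", ec_reference)
    b = _require_positive("ec_test", ec_test)
    return a / b


def toxic_ratio(ic10_baseline: float, ic10_experimental: float | None) -> float:
    """Toxic ratio: predicted baseline IC10 / experimental IC10."""
    a = _require_positive("ic10_baseline", ic10_baseline)
    b = _require_positive("ic10_experimental", ic10_experimental)
    return a / b


def classify_tr(tr: float) -> str:
    """Band a toxic ratio: ``specific`` (>= 10), ``baseline`` (0.1-10), or
    ``below_baseline`` (<= 0.1)."""
    if tr <= 0:
        raise ValueError(f"TR must be positive, got {tr}")
    if tr >= 10.0:
        return "specific"
    if tr > 0.1:
        return "baseline"
    return "below_baseline"


def specificity_ratio(
    ic10: float | None,
    ic10_baseline: float | None,
    ec: float | None,
) -> tuple[float, str]:
    """Specificity ratio with baseline fallback.

    Uses the experimental cytotoxicity IC10 when available
    (``source="cytotoxicity"``); otherwise falls back to the predicted
    baseline IC10 (``source="baseline"``).  A censored effect concentration
    means the endpoint is inactive and no SR exists.
    """
    ec_val = _require_positive("ec", ec)
    if ic10 is not None:
        return _require_positive("ic10", ic10) / ec_val, "cytotoxicity"
    if ic10_baseline is not None:
        return _require_positive("ic10_baseline", ic10_baseline) / ec_val, "baseline"
    raise ValueError("neither experimental nor baseline IC10 available")


def sr_score(sr: float) -> float:
    """Logistic transform of the specificity ratio, midpoint 5.

    SR = 5 maps to 0.5; SR = 1 to ~0.018 (effects at cytotoxic
    concentrations score ~0); SR >= 10 to ~1 (0.9933 at exactly 10 - the
    asymptote is not clipped)."""
    if sr <= 0:
        raise ValueError(f"SR must be positive, got {sr}")
    return 1.0 / (1.0 + math.exp(-(sr - SR_SCORE_MIDPOINT)))


def cumulative_sr_score(srs: list[float]) -> float:
    """Sum of SR-Scores over the active endpoints of the battery.

    Inactive endpoints (no effect concentration) are simply absent from
    ``srs`` and contribute nothing; an empty battery scores 0.  The maximum
    equals the number of assays in the battery.
    """
    return sum(sr_score(s) for s in srs)


def classify_substitute(
    sigma: float, sigma_reference: float, rep_ic10: float
) -> str:
    """Two-axis substitution call.

    ``regrettable`` when the candidate's Cumulative SR-Score is equal to or
    higher than the reference compound's AND its cytotoxicity REP exceeds 1
    (i.e. it is both as broadly specifically active and more cytotoxic);
    otherwise ``not_flagged``.
    """
    if sigma < 0 or sigma_reference < 0 or rep_ic10 < 0:
        raise ValueError("inputs must be non-negative")
    if sigma >= sigma_reference and rep_ic10 > 1.0:
        return "regrettable"
    return "not_flagged"


@dataclass
class EndpointScore:
    """Per-assay slice of a hazard profile."""

    assay_id: str
    benchmark: float | None = None
    censor_bound: float | None = None
    sr: float | None = None
    sr_source: str = "none"  # {cytotoxicity, baseline, none}
    sr_score: float | None = None
    rep: float | None = None

    @property
    def active(self) -> bool:
        return self.benchmark is not None


@dataclass
class HazardProfile:
    """Per-compound summary across the assay battery."""

    compound_id: str
    endpoints: dict[str, EndpointScore] = field(default_factory=dict)
    ic10_median: float | None = None
    ic10_baseline: float | None = None
    tr_median: float | None = None
    rep_ic10: float | None = None
    cumulative_sr_score: float = 0.0
    category: str = "not_flagged"
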