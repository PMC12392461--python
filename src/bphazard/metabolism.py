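"""Potency and concentration changes after simulated phase-I oxidation.

Compounds are oxidised in vitro with an abiotic cytochrome-P450-mimicking
porphyrin catalyst (aCYP) and re-tested; two ratios summarise the outcome:

* TK-Ratio = benchmark before oxidation / benchmark after oxidation.
  1 means the reaction mix is as potent as the parent, > 1 metabolic
  activation, < 1 detoxification.  Its SEM follows first-order error
  propagation of the ratio.
* C_parent-Ratio = parent concentration after / before oxidation.
  1 means no oxidation took place; < 1 partial degradation.

A mix that becomes clearly more cytotoxic (TK > 2) while the parent is not
degraded (C_parent-Ratio ~ 1) is internally inconsistent - either a very
potent metabolite formed from a small parent turnover, or the benchmark is
inaccurate - and is flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "OxidationExperiment",
    "tk_ratio",
    "tk_ratio_sem",
    "c_parent_ratio",
    "interpret_oxidation",
    "evaluate_experiments",
]

#: TK threshold above which the oxidised mix counts as clearly more toxic.
TK_ACTIVATION_THRESHOLD = 2.0
#: "Parent unchanged" tolerance for the inconsistency flag.
PARENT_UNCHANGED_MIN = 0.9


@dataclass(frozen=True)
class OxidationExperiment:
    """Paired before/after benchmarks and parent concentrations.

    Benchmarks are molar; parent concentrations may be in any unit as long
    as before and after agree.  SEs are linear-scale, as delivered by the
    curve-fitting stage (n = 2 replicate experiments in the assay design
    this mirrors, so they are crude; they are accepted as given).
    """

    compound_id: str
    endpoint: str  # {"cytotoxicity", "ERalpha"}
    x_before: float
    se_before: float
    x_after: float
    se_after: float
    c_parent_before: float | None = None
    c_parent_after: float | None = None

    def __post_init__(self) -> None:
        if self.x_before <= 0 or self.x_after <= 0:
            raise ValueError("benchmark concentrations must be positive")
        if self.se_before < 0 or self.se_after < 0:
            raise ValueError("standard errors must be non-negative")
        for c in (self.c_parent_before, self.c_parent_after):
            if c is not None and c < 0:
                raise ValueError("parent concentrations must be non-negative")


def tk_ratio(x_before: float | None, x_after: float | None) -> float:
    """Toxicokinetic ratio: benchmark before / after oxidation."""
    if x_before is None or x_after is None:
        raise ValueError("censored benchmark; TK-Ratio undefined")
    if x_before <= 0 or x_after <= 0:
        raise ValueError("benchmarks must be positive")
    return x_before / x_after


def tk_ratio_sem(
    x_before: float, se_before: float, x_after: float, se_after: float
) -> float:
    """First-order standard error of the TK-Ratio:

        sqrt( (se_before / x_after)**2 + (x_before * se_after / x_after**2)**2 )
    """
    if x_before <= 0 or x_after <= 0:
        raise ValueError("benchmarks must be positive")
    if se_before < 0 or se_after < 0:
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(
        (se_before / x_after) ** 2 + (x_before * se_after / x_after**2) ** 2
    )


def c_parent_ratio(c_after: float, c_before: float) -> float:
    """Remaining parent fraction: concentration after / before oxidation."""
    if c_before <= 0:
        raise ValueError("c_before must be positive")
    if c_after < 0:
        raise ValueError("c_after must be non-negative")
    return c_after / c_before


def interpret_oxidation(
    tk_cytotoxicity: float,
    c_parent: float | None,
    parent_unchanged_min: float = PARENT_UNCHANGED_MIN,
) -> tuple[str, bool]:
    """Label an oxidation outcome from the cytotoxicity TK-Ratio.

    Returns ``(label, inconsistent)`` where label is
    ``"more-toxic-mixture"`` (TK > 2) or ``"similar-or-detoxified"``
    (TK <= 2).  ``inconsistent`` is set when the mix became more toxic yet
    the parent compound was essentially unchanged
    (C_parent-Ratio >= ``parent_unchanged_min``).
    """
    if tk_cytotoxicity <= 0:
        raise ValueError("TK-Ratio must be positive")
    if tk_cytotoxicity > TK_ACTIVATION_THRESHOLD:
        inconsistent = c_parent is not None and c_parent >= parent_unchanged_min
        return "more-toxic-mixture", inconsistent
    return "similar-or-detoxified", False


def evaluate_experiments(experiments: list[OxidationExperiment]) -> pd.DataFrame:
    """Tabulate TK-Ratios, SEMs, parent ratios and labels for a batch.

    Cytotoxicity TK-Ratios drive the label; endpoints without parent
    concentrations get a label but no inconsistency assessment.
    """
    rows = []
    for e in experiments:
        tk = tk_ratio(e.x_before, e.x_after)
        sem = tk_ratio_sem(e.x_before, e.se_before, e.x_after, e.se_after)
        cp = (
            c_parent_ratio(e.c_parent_after, e.c_parent_before)
            if e.c_parent_before is not None and e.c_parent_after is not None
            else None
        )
        if e.endpoint == "cytotoxicity":
            label, inconsistent = interpret_oxidation(tk, cp)
        else:
            label, inconsistent = "", False
        rows.append(
            {
                "compound_id": e.compound_id,
                "endpoint": e.endpoint,
                "tk_ratio": tk,
                "tk_sem": sem,
                "c_parent_ratio": cp,
                "label": label,
                "inconsistent": inconsistent,
            }
        )
    return pd.DataFrame(rows)
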