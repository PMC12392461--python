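"""Speciation and baseline-toxicity prediction from partitioning descriptors.

Baseline (narcosis-type) cytotoxicity arises from nonspecific accumulation of
a chemical in cell membranes.  For cell-based bioassays it can be predicted
from the critical membrane burden of 0.026 mol per litre of membrane lipid,
which is uniform across chemicals and cell types, combined with the
liposome-water distribution ratio of the chemical and the lipid/protein
content of the exposure medium:

    IC10_baseline = 0.026 / D_lipw * (1 + D_BSAw * VF_protein + D_lipw * VF_lipid)

All distribution ratios here are on the linear scale; compound panels store
them as log10 values.  Ionisation matters because only a fraction of an
acidic compound is neutral at assay pH; that fraction follows standard
Henderson-Hasselbalch speciation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CRITICAL_MEMBRANE_BURDEN",
    "Compound",
    "MediumComposition",
    "LipwCoefficients",
    "fraction_neutral",
    "baseline_ic10",
    "lipw_from_kow",
    "read_panel",
    "write_panel",
]

#: Critical membrane concentration causing 10% cytotoxicity (mol / L membrane).
CRITICAL_MEMBRANE_BURDEN = 0.026

#: Physiological pH used for speciation unless a medium says otherwise.
DEFAULT_PH = 7.4


@dataclass(frozen=True)
class Compound:
    """One panel member with its partitioning descriptors.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"BPA"``; unique within a panel.
    log_kow : float, optional
        log10 octanol-water partition constant of the neutral species.
    log_dlipw : float, optional
        log10 ionisation-corrected liposome-water distribution ratio.
    log_dbsaw : float, optional
        log10 bovine-serum-albumin-water distribution ratio.
    pka_values : tuple of float
        Acid dissociation constants, sorted ascending.
    alpha_neutral : float, optional
        Fraction of the neutral species at assay pH, in [0, 1].
    smiles : str, optional
        Structure string for similarity analyses.
    """

    id: str
    log_kow: float | None = None
    log_dlipw: float | None = None
    log_dbsaw: float | None = None
    pka_values: tuple[float, ...] = field(default_factory=tuple)
    alpha_neutral: float | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.alpha_neutral is not None and not 0.0 <= self.alpha_neutral <= 1.0:
            raise ValueError(f"alpha_neutral must be in [0, 1], got {self.alpha_neutral}")
        if list(self.pka_values) != sorted(self.pka_values):
            raise ValueError("pka_values must be sorted ascending")

    @property
    def d_lipw(self) -> float:
        """Linear-scale liposome-water distribution ratio."""
        if self.log_dlipw is None:
            raise ValueError(f"{self.id}: log_dlipw not set")
        return 10.0 ** self.log_dlipw

    @property
    def d_bsaw(self) -> float:
        """Linear-scale BSA-water distribution ratio (0 when unknown)."""
        return 0.0 if self.log_dbsaw is None else 10.0 ** self.log_dbsaw


@dataclass(frozen=True)
class MediumComposition:
    """Protein and lipid content of an assay medium (volume fractions, L/L).

    Defaults describe the pure-membrane limit (no sorbing medium
    constituents), which is also the configuration used when medium
    compositions are not known for a particular assay.
    """

    vf_protein: float = 0.0
    vf_lipid: float = 0.0
    ph: float = DEFAULT_PH

    def __post_init__(self) -> None:
        if self.vf_protein < 0 or self.vf_lipid < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.vf_protein + self.vf_lipid >= 1:
            raise ValueError("volume fractions must sum to < 1")


def fraction_neutral(
    pka_values: tuple[float, ...] | list[float],
    n_acidic: int,
    ph: float = DEFAULT_PH,
) -> float:
    """Fraction of the neutral species of an acid at the given pH.

    Henderson-Hasselbalch speciation for mono- and diprotic acids:

        monoprotic:  alpha = 1 / (1 + 10**(pH - pKa1))
        diprotic:    alpha = 1 / (1 + 10**(pH - pKa1) + 10**(2 pH - pKa1 - pKa2))

    A compound with no acidic protons is fully neutral (returns 1.0).
    """
    if n_acidic not in (0, 1, 2):
        raise ValueError(f"n_acidic must be 0, 1 or 2, got {n_acidic}")
    if len(pka_values) < n_acidic:
        raise ValueError(
            f"{n_acidic} acidic proton(s) declared but only "
            f"{len(pka_values)} pKa value(s) given"
        )
    if n_acidic == 0:
        return 1.0
    if n_acidic == 1:
        return 1.0 / (1.0 + 10.0 ** (ph - pka_values[0]))
    pka1, pka2 = pka_values[0], pka_values[1]
    return 1.0 / (1.0 + 10.0 ** (ph - pka1) + 10.0 ** (2.0 * ph - pka1 - pka2))


def baseline_ic10(
    d_lipw: float,
    d_bsaw: float = 0.0,
    medium: MediumComposition | None = None,
) -> float:
    """Predicted baseline-toxicity IC10 in mol/L.

    Parameters are linear-scale distribution ratios.  With an empty medium
    (both volume fractions zero) this reduces to 0.026 / D_lipw.
    """
    if d_lipw <= 0:
        raise ValueError(f"d_lipw must be positive, got {d_lipw}")
    if d_bsaw < 0:
        raise ValueError(f"d_bsaw must be non-negative, got {d_bsaw}")
    if medium is None:
        medium = MediumComposition()
    return (
        CRITICAL_MEMBRANE_BURDEN
        / d_lipw
        * (1.0 + d_bsaw * medium.vf_protein + d_lipw * medium.vf_lipid)
    )


@dataclass(frozen=True)
class LipwCoefficients:
    """User-supplied linear map from log Kow to log Klipw of the neutral
    species, plus a log-unit discount applied to the charged species.

    There is deliberately no default model: published liposome-water
    regressions differ between chemical classes, so callers must state
    their coefficients explicitly.  ``slope=1, intercept=0,
    anion_discount_log=0`` is the identity configuration.
    """

    slope: float
    intercept: float
    anion_discount_log: float = 0.0


def lipw_from_kow(
    log_kow: float,
    alpha_neutral: float,
    coefficients: LipwCoefficients,
) -> float:
    """Ionisation-corrected log D_lipw from log Kow.

    The neutral-species log Klipw is ``slope * log_kow + intercept``; the
    charged species partitions ``anion_discount_log`` log units less.  The
    distribution ratio is the speciation-weighted sum on the linear scale:

        D_lipw = alpha * K_neutral + (1 - alpha) * K_neutral / 10**discount
    """
    if not 0.0 <= alpha_neutral <= 1.0:
        raise ValueError(f"alpha_neutral must be in [0, 1], got {alpha_neutral}")
    log_k_neutral = coefficients.slope * log_kow + coefficients.intercept
    k_neutral = 10.0 ** log_k_neutral
    k_anion = 10.0 ** (log_k_neutral - coefficients.anion_discount_log)
    return math.log10(alpha_neutral * k_neutral + (1.0 - alpha_neutral) * k_anion)


_PANEL_COLUMNS = [
    "id",
    "log_kow",
    "log_dlipw",
    "log_dbsaw",
    "pka1",
    "pka2",
    "alpha_neutral",
    "smiles",
]


def read_panel(path: str | Path) -> dict[str, Compound]:
    """Read a compound panel CSV (missing numeric values as empty cells)."""
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    panel: dict[str, Compound] = {}
    for _, row in df.iterrows():
        pkas = tuple(
            float(row[c]) for c in ("pka1", "pka2") if pd.notna(row[c])
        )
        cid = str(row["id"])
        if cid in panel:
            raise ValueError(f"duplicate compound id {cid!r} in panel")
        panel[cid] = Compound(
            id=cid,
            log_kow=None if pd.isna(row["log_kow"]) else float(row["log_kow"]),
            log_dlipw=None if pd.isna(row["log_dlipw"]) else float(row["log_dlipw"]),
            log_dbsaw=None if pd.isna(row["log_dbsaw"]) else float(row["log_dbsaw"]),
            pka_values=pkas,
            alpha_neutral=None
            if pd.isna(row["alpha_neutral"])
            else float(row["alpha_neutral"]),
            smiles=None if pd.isna(row["smiles"]) else str(row["smiles"]),
        )
    return panel


def write_panel(panel: dict[str, Compound], path: str | Path) -> None:
    """Write a compound panel as CSV, inverse of :func:`read_panel`."""
    rows = []
    for c in panel.values():
        rows.append(
            {
                "id": c.id,
                "log_kow": c.log_kow,
                "log_dlipw": c.log_dlipw,
                "log_dbsaw": c.log_dbsaw,
                "pka1": c.pka_values[0] if len(c.pka_values) > 0 else None,
                "pka2": c.pka_values[1] if len(c.pka_values) > 1 else None,
                "alpha_neutral": c.alpha_neutral,
                "smiles": c.smiles,
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, index=False)
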