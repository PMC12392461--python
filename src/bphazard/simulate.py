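"""Synthetic bioassay data with the statistical structure the analysis assumes.

Two generators and one packaged fixture:

* :func:`simulate_concentration_response` draws replicate responses from a
  log-logistic mean curve over a geometric concentration series with
  additive Gaussian noise on the normalised-% scale - the scatter pattern
  of reporter-gene replicates.
* :func:`simulate_oxidation` emulates paired before/after-oxidation
  benchmark measurements with lognormal multiplicative noise around a known
  true TK-Ratio.
* :func:`load_table1_fixture` returns the summary panel of BPA and its 26
  alternatives (physicochemical descriptors, per-assay benchmark
  concentrations, efficacies and cumulative scores) with censored cells
  represented explicitly as ``None``.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metabolism import OxidationExperiment
from .physchem import Compound
from .similarity import read_smiles_table

__all__ = [
    "ASSAYS",
    "GeneratorSpec",
    "ec50_from_benchmark",
    "simulate_concentration_response",
    "simulate_oxidation",
    "Table1Row",
    "Table1Fixture",
    "load_table1_fixture",
]

#: Assay battery endpoints and the fixture columns that hold their benchmarks.
ASSAYS = {
    "ERalpha": "ec10_eralpha",
    "PPARgamma": "ec10_pparg",
    "AhR": "ec10_ahr",
    "ARE": "ec_ir15_are",
    "MMP": "ec10_mmp",
    "NOI": "ec10_noi",
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and design for one compound x assay simulation.

    Defaults follow the plate design the analysis assumes: 12 two-fold
    dilutions, 3 replicates, additive Gaussian noise with SD 5% of the
    reference maximum.  ``c_max`` defaults to 100 x the true EC50 so the
    series brackets the transition region.
    """

    compound_id: str = "synthetic"
    assay_id: str = "ERalpha"
    true_top: float = 100.0
    true_ec50: float = 1e-6
    true_hill: float = 1.0
    cytotox_ic10: float | None = None
    n_concentrations: int = 12
    dilution: float = 2.0
    n_replicates: int = 3
    noise_sd: float = 5.0
    noise_model: str = "gaussian"  # or "lognormal"
    c_max: float | None = None
    response_scale: str = "percent_reference"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_top < 0 or self.true_ec50 <= 0 or self.true_hill <= 0:
            raise ValueError("curve parameters must be positive")
        if self.n_concentrations < 2 or self.dilution <= 1 or self.n_replicates < 1:
            raise ValueError("invalid series design")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def concentrations(self) -> np.ndarray:
        top_c = self.c_max if self.c_max is not None else 100.0 * self.true_ec50
        return top_c / self.dilution ** np.arange(self.n_concentrations)[::-1]


def ec50_from_benchmark(
    benchmark: float, top: float, hill: float = 1.0, threshold: float = 10.0
) -> float:
    """EC50 of the log-logistic curve whose response crosses ``threshold``
    at ``benchmark`` - the inverse of benchmark derivation, used to
    parameterise the generator from published benchmark concentrations."""
    if top <= threshold:
        raise ValueError(f"top={top} never reaches threshold {threshold}")
    return benchmark * (top / threshold - 1.0) ** (1.0 / hill)


def simulate_concentration_response(spec: GeneratorSpec) -> pd.DataFrame:
    """Tidy replicate concentration-response points for one spec.

    Columns match the fitting stage's input schema: ``compound_id,
    assay_id, concentration_M, response, response_scale, replicate``.
    """
    rng = np.random.default_rng(spec.seed)
    conc = spec.concentrations()
    mean = spec.true_top / (1.0 + (spec.true_ec50 / conc) ** spec.true_hill)
    rows = []
    for rep_i in range(1, spec.n_replicates + 1):
        if spec.noise_model == "gaussian":
            resp = mean + rng.normal(0.0, spec.noise_sd, size=len(conc))
        elif spec.noise_model == "lognormal":
            cv = spec.noise_sd / 100.0
            sigma = math.sqrt(math.log1p(cv**2))
            resp = mean * rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(conc))
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
        for c, r in zip(conc, resp):
            rows.append(
                {
                    "compound_id": spec.compound_id,
                    "assay_id": spec.assay_id,
                    "concentration_M": float(c),
                    "response": float(r),
                    "response_scale": spec.response_scale,
                    "replicate": rep_i,
                }
            )
    return pd.DataFrame(rows)


def simulate_oxidation(
    true_tk: float,
    cv: float,
    n_reps: int = 2,
    seed: int = 0,
    compound_id: str = "synthetic",
    endpoint: str = "cytotoxicity",
    x_before_true: float = 1e-5,
    true_c_parent_ratio: float = 1.0,
) -> OxidationExperiment:
    """Paired oxidation experiment with known ground-truth TK-Ratio.

    Replicate before/after benchmarks are the true values perturbed by
    mean-one lognormal noise of coefficient of variation ``cv``; the
    experiment carries their replicate means and standard errors.  ``cv=0``
    reproduces ``true_tk`` exactly.
    """
    if true_tk <= 0:
        raise ValueError("true_tk must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    mu = -(sigma**2) / 2.0  # mean-one lognormal

    def _measure(true_value: float) -> tuple[float, float]:
        draws = true_value * rng.lognormal(mu, sigma, size=n_reps)
        se = float(draws.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
        return float(draws.mean()), se

    x_after_true = x_before_true / true_tk
    xb, seb = _measure(x_before_true)
    xa, sea = _measure(x_after_true)
    cpb, _ = _measure(1.0)
    cpa, _ = _measure(true_c_parent_ratio)
    return OxidationExperiment(
        compound_id=compound_id,
        endpoint=endpoint,
        x_before=xb,
        se_before=seb,
        x_after=xa,
        se_after=sea,
        c_parent_before=cpb,
        c_parent_after=cpa,
    )


@dataclass(frozen=True)
class Table1Row:
    """One compound of the summary panel; ``None`` marks a censored /
    inactive cell (no effect below the highest tested concentration)."""

    id: str
    alpha_neutral_pct: float
    log_kow: float
    log_dlipw: float
    ic10_median: float | None
    ec10_eralpha: float | None
    ec10_pparg: float | None
    ec10_ahr: float | None
    ec_ir15_are: float | None
    ec10_mmp: float | None
    ec10_noi: float | None
    emax_eralpha: float | None
    emax_pparg: float | None
    sigma_sr_score: float

    def benchmark(self, assay: str) -> float | None:
        return getattr(self, ASSAYS[assay])


class Table1Fixture:
    """The packaged 27-compound summary panel with curated structures."""

    def __init__(self, rows: dict[str, Table1Row], smiles: dict[str, str]):
        self._rows = rows
        self._smiles = smiles

    def __getitem__(self, compound_id: str) -> Table1Row:
        return self._rows[compound_id]

    def __iter__(self):
        return iter(self._rows.values())

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def ids(self) -> list[str]:
        return list(self._rows)

    @property
    def smiles(self) -> dict[str, str]:
        return dict(self._smiles)

    def to_frame(self) -> pd.DataFrame:
        """The panel as the same tabular form it is shipped in."""
        return pd.DataFrame([vars(r) for r in self._rows.values()])

    def compounds(self) -> dict[str, Compound]:
        """Panel as physchem Compound records (alpha as a fraction)."""
        return {
            r.id: Compound(
                id=r.id,
                log_kow=r.log_kow,
                log_dlipw=r.log_dlipw,
                alpha_neutral=r.alpha_neutral_pct / 100.0,
                smiles=self._smiles.get(r.id),
            )
            for r in self._rows.values()
        }

    def benchmark_table(self, include_cytotoxicity: bool = False) -> pd.DataFrame:
        """Long-format benchmark table (compound_id, assay_id, benchmark).

        With ``include_cytotoxicity`` the median IC10 appears as extra rows
        under assay_id ``"cytotoxicity"`` - the schema the pipeline reads.
        """
        rows = []
        for r in self._rows.values():
            for assay in ASSAYS:
                rows.append(
                    {
                        "compound_id": r.id,
                        "assay_id": assay,
                        "benchmark": r.benchmark(assay),
                    }
                )
            if include_cytotoxicity:
                rows.append(
                    {
                        "compound_id": r.id,
                        "assay_id": "cytotoxicity",
                        "benchmark": r.ic10_median,
                    }
                )
        return pd.DataFrame(rows)


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged summary panel and curated SMILES."""
    data = resources.files("bphazard") / "data"
    with resources.as_file(data / "table1.csv") as p:
        df = pd.read_csv(p)
    with resources.as_file(data / "smiles.tsv") as p:
        smiles = read_smiles_table(p)
    rows: dict[str, Table1Row] = {}
    for _, r in df.iterrows():
        row = Table1Row(
            id=str(r["id"]),
            alpha_neutral_pct=float(r["alpha_neutral_pct"]),
            log_kow=float(r["log_kow"]),
            log_dlipw=float(r["log_dlipw"]),
            ic10_median=_opt(r["ic10_median"]),
            ec10_eralpha=_opt(r["ec10_eralpha"]),
            ec10_pparg=_opt(r["ec10_pparg"]),
            ec10_ahr=_opt(r["ec10_ahr"]),
            ec_ir15_are=_opt(r["ec_ir15_are"]),
            ec10_mmp=_opt(r["ec10_mmp"]),
            ec10_noi=_opt(r["ec10_noi"]),
            emax_eralpha=_opt(r["emax_eralpha"]),
            emax_pparg=_opt(r["emax_pparg"]),
            sigma_sr_score=float(r["sigma_sr_score"]),
        )
        rows[row.id] = row
    return Table1Fixture(rows, smiles)
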