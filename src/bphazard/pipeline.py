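"""End-to-end orchestration: benchmarks -> hazard profiles -> report tables.

The pipeline composes the library stages: it takes a per-compound x
per-assay benchmark table (either fitted from raw concentration-response
data or taken from a published summary panel), attaches baseline-toxicity
predictions, computes specificity ratios with the baseline fallback,
SR-Scores, cumulative scores, relative effect potencies against a
reference compound, and the substitution call, and renders the summary
artifacts (long-format scores, an SR-bin heatmap matrix, and the
REP-vs-cumulative-score scatter table).

Everything is deterministic given inputs and seed; every censoring or
fallback decision is recorded on the profile and surfaced in the outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dose_response import fit_curve, fits_to_frame, mask_cytotoxic, parse_benchmark
from .hazard import (
    EndpointScore,
    HazardProfile,
    classify_substitute,
    rep,
    specificity_ratio,
    sr_score,
    toxic_ratio,
)
from .physchem import Compound, MediumComposition, baseline_ic10
from .simulate import ASSAYS

__all__ = [
    "PipelineConfig",
    "score_panel",
    "run_pipeline",
    "render_summary",
    "sr_bin",
    "round_sig",
    "profiles_to_long",
    "profiles_to_summary",
]

logger = logging.getLogger("bphazard")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention for ratios)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Either ``curves_csv`` (raw tidy concentration-response points, fitted
    per compound x assay) or ``benchmarks_csv`` (pre-derived benchmarks;
    censored entries as ``">bound"`` strings or empty) must be given.
    """

    panel_csv: str | None = None
    curves_csv: str | None = None
    benchmarks_csv: str | None = None
    reference_compound: str = "BPA"
    assays: list[str] = field(default_factory=lambda: list(ASSAYS))
    ph: float = 7.4
    vf_protein: float = 0.0
    vf_lipid: float = 0.0
    ratio_sig_figs: int = 2
    score_decimals: int = 2
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def medium(self) -> MediumComposition:
        return MediumComposition(self.vf_protein, self.vf_lipid, self.ph)


def _benchmark_lookup(benchmarks: pd.DataFrame) -> dict[tuple[str, str], float | None]:
    """(compound, assay) -> molar benchmark or None for censored/absent."""
    out: dict[tuple[str, str], float | None] = {}
    for _, row in benchmarks.iterrows():
        value = row["benchmark"]
        if isinstance(value, str):
            value, _ = parse_benchmark(value)
        elif pd.isna(value):
            value = None
        out[(row["compound_id"], row["assay_id"])] = value
    return out


def score_panel(
    benchmarks: pd.DataFrame,
    panel: dict[str, Compound],
    ic10_median: dict[str, float | None],
    reference: str = "BPA",
    assays: list[str] | None = None,
    medium: MediumComposition | None = None,
) -> list[HazardProfile]:
    """Hazard profiles for every panel compound.

    Parameters
    ----------
    benchmarks : long DataFrame (compound_id, assay_id, benchmark)
        Molar effect benchmarks; NaN/None/">bound" entries are censored.
    panel : compound records (for baseline-toxicity prediction).
    ic10_median : experimental median cytotoxicity IC10 per compound
        (None when censored in every cell line).
    reference : compound id against which REPs are computed.
    """
    if reference not in panel:
        raise ValueError(f"reference compound {reference!r} not in panel")
    assays = list(ASSAYS) if assays is None else assays
    medium = medium or MediumComposition()
    lut = _benchmark_lookup(benchmarks)

    profiles: dict[str, HazardProfile] = {}
    for cid, compound in panel.items():
        prof = HazardProfile(compound_id=cid)
        prof.ic10_median = ic10_median.get(cid)
        if compound.log_dlipw is not None:
            prof.ic10_baseline = baseline_ic10(
                compound.d_lipw, compound.d_bsaw, medium
            )
        if prof.ic10_median is not None and prof.ic10_baseline is not None:
            prof.tr_median = toxic_ratio(prof.ic10_baseline, prof.ic10_median)
        for assay in assays:
            ep = EndpointScore(assay_id=assay)
            ec = lut.get((cid, assay))
            if ec is not None:
                ep.benchmark = ec
                sr, source = specificity_ratio(
                    prof.ic10_median, prof.ic10_baseline, ec
                )
                ep.sr, ep.sr_source = sr, source
                ep.sr_score = sr_score(sr)
                if source == "baseline":
                    logger.info("%s/%s: SR from baseline IC10 fallback", cid, assay)
            prof.endpoints[assay] = ep
        prof.cumulative_sr_score = sum(
            ep.sr_score for ep in prof.endpoints.values() if ep.sr_score is not None
        )
        profiles[cid] = prof

    ref = profiles[reference]
    for prof in profiles.values():
        if prof.ic10_median is not None and ref.ic10_median is not None:
            prof.rep_ic10 = rep(ref.ic10_median, prof.ic10_median)
        for assay, ep in prof.endpoints.items():
            ref_ec = ref.endpoints[assay].benchmark
            if ref_ec is not None and ep.benchmark is not None:
                ep.rep = rep(ref_ec, ep.benchmark)
        if prof.rep_ic10 is not None:
            prof.category = classify_substitute(
                prof.cumulative_sr_score, ref.cumulative_sr_score, prof.rep_ic10
            )
    return list(profiles.values())


def _fit_all(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every compound x assay group of a tidy points table.

    Cytotoxicity groups (assay_id ``"cytotoxicity"``, inhibition scale) are
    fitted first; their IC10 masks the effect assays of the same compound.
    """
    fits = []
    ic10_by_compound: dict[str, float | None] = {}
    grouped = curves.groupby(["compound_id", "assay_id"], sort=False)
    for (cid, assay), pts in grouped:
        if assay != "cytotoxicity":
            continue
        f = fit_curve(pts, benchmark_type="IC10", compound_id=cid, assay_id=assay)
        ic10_by_compound[cid] = f.benchmark
        fits.append(f)
    for (cid, assay), pts in grouped:
        if assay == "cytotoxicity":
            continue
        masked = mask_cytotoxic(pts, ic10_by_compound.get(cid))
        model = "linear_low_effect" if assay == "ARE" else "log_logistic"
        btype = "EC_IR1.5" if assay == "ARE" else "EC10"
        c_max = float(pts["concentration_M"].max())
        f = fit_curve(
            masked,
            model=model,
            benchmark_type=btype,
            c_max=c_max,
            compound_id=cid,
            assay_id=assay,
        )
        fits.append(f)
    return fits_to_frame(fits)


def run_pipeline(config: PipelineConfig):
    """Run the full scoring pipeline described by ``config``.

    Returns ``(profiles, outputs)`` where outputs maps artifact names to
    DataFrames; when ``config.out_dir`` is set they are also written as CSV
    with a JSON provenance sidecar capturing the configuration.
    """
    from .physchem import read_panel

    if config.panel_csv is None:
        raise ValueError("panel_csv is required")
    panel = read_panel(config.panel_csv)
    if config.reference_compound not in panel:
        raise ValueError(
            f"reference compound {config.reference_compound!r} absent from panel"
        )

    fit_table = None
    if config.curves_csv is not None:
        curves = pd.read_csv(config.curves_csv)
        required = {"compound_id", "assay_id", "concentration_M", "response"}
        missing = required - set(curves.columns)
        if missing:
            raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
        fit_table = _fit_all(curves)
        bm = fit_table[["compound_id", "assay_id", "benchmark"]]
    elif config.benchmarks_csv is not None:
        bm = pd.read_csv(config.benchmarks_csv)
    else:
        raise ValueError("either curves_csv or benchmarks_csv is required")

    lut = _benchmark_lookup(bm[bm.assay_id == "cytotoxicity"])
    ic10_median = {cid: lut.get((cid, "cytotoxicity")) for cid in panel}
    benchmarks = bm[bm.assay_id != "cytotoxicity"]

    profiles = score_panel(
        benchmarks,
        panel,
        ic10_median,
        reference=config.reference_compound,
        assays=config.assays,
        medium=config.medium(),
    )
    outputs = {
        "scores_long": profiles_to_long(profiles),
        "summary": profiles_to_summary(profiles, config),
    }
    heatmap, scatter = render_summary(profiles)
    outputs["sr_heatmap"] = heatmap
    outputs["rep_vs_sigma"] = scatter
    if fit_table is not None:
        outputs["curve_fits"] = fit_table

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps({"config": vars(config)}, indent=2, default=str)
        )
    return profiles, outputs


def profiles_to_long(profiles: list[HazardProfile]) -> pd.DataFrame:
    """Per compound x assay: benchmark, SR, SR source and SR-Score."""
    rows = []
    for p in profiles:
        for assay, ep in p.endpoints.items():
            rows.append(
                {
                    "compound_id": p.compound_id,
                    "assay_id": assay,
                    "benchmark": ep.benchmark,
                    "sr": ep.sr,
                    "sr_source": ep.sr_source,
                    "sr_score": ep.sr_score,
                    "rep": ep.rep,
                }
            )
    return pd.DataFrame(rows)


def profiles_to_summary(
    profiles: list[HazardProfile], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-compound summary: REPs, cumulative score and substitution call."""
    sig = config.ratio_sig_figs if config else 2
    dec = config.score_decimals if config else 2
    rows = []
    for p in profiles:
        rows.append(
            {
                "compound_id": p.compound_id,
                "ic10_median": p.ic10_median,
                "ic10_baseline": p.ic10_baseline,
                "tr_median": None
                if p.tr_median is None
                else round_sig(p.tr_median, sig),
                "rep_ic10": None
                if p.rep_ic10 is None
                else round_sig(p.rep_ic10, sig),
                "cumulative_sr_score": round(p.cumulative_sr_score, dec),
                "category": p.category,
            }
        )
    return pd.DataFrame(rows)


def sr_bin(sr: float | None) -> str:
    """Heatmap bin for a specificity ratio (``no effect`` when absent)."""
    if sr is None:
        return "no effect"
    if sr > 100:
        return "SR>100"
    if sr > 10:
        return "SR>10"
    if sr > 1:
        return "1<SR<10"
    return "SR<1"


def render_summary(profiles: list[HazardProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap matrix of SR bins (compound x assay) and the two-axis
    scatter table (cytotoxicity REP vs cumulative SR-Score)."""
    if not profiles:
        raise ValueError("need at least one profile")
    heat_rows = []
    for p in profiles:
        row: dict[str, object] = {"compound_id": p.compound_id}
        for assay, ep in p.endpoints.items():
            row[assay] = sr_bin(ep.sr)
        heat_rows.append(row)
    scatter = pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in profiles],
            "rep_ic10": [p.rep_ic10 for p in profiles],
            "cumulative_sr_score": [p.cumulative_sr_score for p in profiles],
            "category": [p.category for p in profiles],
        }
    )
    return pd.DataFrame(heat_rows), scatter
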