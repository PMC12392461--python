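"""Hazard scoring of the 27-compound panel against BPA.

Runs the scoring pipeline on the packaged summary panel: specificity
ratios from the median cytotoxicity IC10 (baseline-toxicity fallback where
censored), SR-Scores, cumulative SR-Scores, relative effect potencies
against BPA, and the two-axis substitution call.  Writes the long-format
scores, per-compound summary, SR-bin heatmap matrix and REP-vs-cumulative
scatter table under results/.

Note the SRs here are median-IC10-based; published per-cell-line SRs
differ in detail but the qualitative pattern (high ERalpha specificity for
Bz, BP-MIBK, BPAF) reproduces.
"""

from pathlib import Path

from bphazard.physchem import write_panel
from bphazard.pipeline import PipelineConfig, round_sig, run_pipeline
from bphazard.simulate import load_table1_fixture

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fixture = load_table1_fixture()
    panel_csv = OUT / "panel.csv"
    bm_csv = OUT / "benchmarks.csv"
    write_panel(fixture.compounds(), panel_csv)
    fixture.benchmark_table(include_cytotoxicity=True).to_csv(bm_csv, index=False)

    config = PipelineConfig(
        panel_csv=str(panel_csv),
        benchmarks_csv=str(bm_csv),
        reference_compound="BPA",
        out_dir=str(OUT / "hazard"),
    )
    profiles, outputs = run_pipeline(config)

    by_id = {p.compound_id: p for p in profiles}
    print("ERalpha relative effect potencies vs BPA (2 s.f.):")
    for cid in ("BP-MIBK", "BPAF", "BPZ", "BPB", "BPAP", "D8", "BPS-MAE", "2,4-BPS"):
        ep = by_id[cid].endpoints["ERalpha"]
        print(f"  {cid:10s} REP = {round_sig(ep.rep):g}")
    print("\nSubstitution calls (cumulative SR-Score >= BPA's and REP_IC10 > 1):")
    flagged = [p.compound_id for p in profiles if p.category == "regrettable"]
    print(" ", ", ".join(flagged) or "none")
    print("\nArtifacts written under", OUT / "hazard")


if __name__ == "__main__":
    main()
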