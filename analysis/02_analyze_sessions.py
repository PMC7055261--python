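#!/usr/bin/env python
"""Analyze the generated NWB session files: behavior and unit screening.

Reads only the NWB files under scratch/nwb/ (never the generator's in-memory
state), computes per-session confidence-ROC behavior (AUC, zROC slope,
high- vs low-confidence accuracy) and per-unit VS/MS selection with QC
metrics, and writes three tables under results/: behavior_summary.csv,
unit_selection.csv, population_summary.csv.
"""

from pathlib import Path

from newold.cli import analyze_nwb_dir

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = analyze_nwb_dir(
        ROOT / "scratch" / "nwb", ROOT / "results", n_boot=1000, seed=0
    )
    beh = tables["behavior"]
    pop = tables["population"].iloc[0]
    print(f"analyzed {len(beh)} sessions")
    print(
        f"mean AUC {beh.auc.mean():.3f} +/- {beh.auc.std(ddof=1):.3f}; "
        f"mean zROC slope {beh.zroc_slope.mean():.3f}"
    )
    print(
        f"accuracy high-confidence {beh.acc_high.mean():.3f} vs "
        f"low-confidence {beh.acc_low.mean():.3f}"
    )
    print(
        f"{int(pop.n_units)} units screened: {int(pop.n_vs)} VS "
        f"({pop.prop_vs:.1%}), {int(pop.n_ms)} MS ({pop.prop_ms:.1%}), "
        f"{int(pop.n_dual)} dual ({pop.prop_dual:.1%})"
    )
    print(f"tables written to {ROOT / 'results'}")


if __name__ == "__main__":
    main()
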