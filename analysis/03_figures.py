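#!/usr/bin/env python
"""Plot the study's comparison figures from results/study/results.csv.

Box plots of conventional vs optimized ROI fields and of electrode
displacement D by lesion class, plus scatter plots of D and improvement
against the initial FMA-UE score.  Run 02_run_study.py first.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results" / "study"
FIGS = RESULTS / "figures"


def main():
    df = pd.read_csv(RESULTS / "results.csv", comment="#")
    ok = df[df["status"] == "ok"]
    FIGS.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    ax.boxplot([ok["conv_field"], ok["opt_field"]],
               tick_labels=["conventional", "optimized"])
    for _, r in ok.iterrows():
        ax.plot([1, 2], [r["conv_field"], r["opt_field"]], "o-",
                color="0.6", lw=0.5, ms=3)
    ax.set_ylabel("ROI mean |E| (V/m)")
    ax.set_title("target field by montage")

    ax = axes[0, 1]
    cort = ok[ok["class"] == "cortical"]["d_total"]
    non = ok[ok["class"] != "cortical"]["d_total"]
    ax.boxplot([cort, non], tick_labels=["cortical", "non-cortical"])
    ax.set_ylabel("D (mm)")
    ax.set_title("electrode displacement by lesion class")

    ax = axes[1, 0]
    ax.scatter(ok["fma_ue"], ok["d_total"], c="tab:blue")
    ax.set_xlabel("initial FMA-UE")
    ax.set_ylabel("D (mm)")
    ax.set_title("displacement vs impairment")

    ax = axes[1, 1]
    ax.scatter(ok["fma_ue"], ok["improvement_pct"], c="tab:orange")
    ax.set_xlabel("initial FMA-UE")
    ax.set_ylabel("improvement (%)")
    ax.set_title("field improvement vs impairment")

    fig.tight_layout()
    out = FIGS / "study_overview.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
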