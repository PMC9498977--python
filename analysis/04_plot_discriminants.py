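"""Scatter of participants in the space of the two linear discriminants.

Reads results/stats/lda_scores.csv (trial-level LD scores), averages to
participant level, and draws the LD1/LD2 scatter with group colors, the
standard way the group separation of haptic-exploration profiles is shown.
The figure goes to scratch/figures/ (binary artifacts stay out of results/).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
COLORS = {"CB": "tab:red", "LB": "tab:green", "SI": "tab:blue"}


def main() -> None:
    scores_path = ROOT / "results" / "stats" / "lda_scores.csv"
    if not scores_path.exists():
        raise SystemExit(f"{scores_path} missing; run analysis/03_group_statistics.py first")
    scores = pd.read_csv(scores_path, index_col=0)

    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in scores.groupby("group"):
        ax.scatter(sub["LD1"], sub["LD2"], s=18, alpha=0.6, label=group,
                   color=COLORS.get(group, "gray"))
        ax.scatter(sub["LD1"].mean(), sub["LD2"].mean(), marker="X", s=120,
                   color=COLORS.get(group, "gray"), edgecolor="black", zorder=5)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2")
    ax.legend(title="group")
    ax.set_title("Haptic exploration profiles in discriminant space")
    outdir = ROOT / "scratch" / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "lda_scatter.png"
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
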