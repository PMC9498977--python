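"""Group-discrimination statistics over the cohort metrics.

Runs the full statistical stage on results/metrics.csv: a Bayes factor for
recognition accuracy (Box-Cox + BIC approximation), a one-way MANOVA
summarized by Roy's largest root over the twelve haptic variables, the
follow-up linear discriminant analysis, univariate ANOVAs with Welch
post-hocs (BH-FDR) on the three variables with the largest |LD1|
coefficients, and the directed correlations between the exploration-speed
indices and exploration duration. Group post-hocs are reported at the
participant-mean level (trials within a synthetic participant share that
participant's preset); the MANOVA/LDA run at trial level.

Writes tables under results/stats/. Run analysis/02_extract_metrics.py first.
"""

import json
from pathlib import Path

import pandas as pd

from hapticube.stats import analyze

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    metrics_path = results / "metrics.csv"
    if not metrics_path.exists():
        raise SystemExit(f"{metrics_path} missing; run analysis/02_extract_metrics.py first")
    metrics = pd.read_csv(metrics_path)
    accuracy = pd.read_csv(results / "accuracy.csv")

    trial_report = analyze(metrics, accuracy=accuracy, unit="trial")
    participant_report = analyze(metrics, accuracy=accuracy, unit="participant")

    outdir = results / "stats"
    outdir.mkdir(parents=True, exist_ok=True)

    manova = trial_report["manova"]
    lda = trial_report["lda"]
    summary = {
        "roy_largest_root": manova.roy,
        "roy_F": manova.f_value,
        "roy_df": [manova.df1, manova.df2],
        "roy_p": manova.p_value,
        "lda_separation_pct": [round(float(x), 2) for x in lda.proportion],
        "accuracy_BF01": trial_report["accuracy_bayes"]["BF01"]
        if trial_report["accuracy_bayes"]
        else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    lda.coefficients.to_csv(outdir / "lda_coefficients.csv", float_format="%.4f")
    lda.group_means.to_csv(outdir / "lda_group_means.csv", float_format="%.4f")
    lda.scores.to_csv(outdir / "lda_scores.csv", float_format="%.4f")

    rows = []
    for name, fu in participant_report["followups"].items():
        rows.append({"variable": name, "F": fu.anova_f, "df1": fu.anova_df[0],
                     "df2": fu.anova_df[1], "p": fu.anova_p})
        fu.posthoc.to_csv(outdir / f"posthoc_{name}.csv", index=False, float_format="%.6f")
    pd.DataFrame(rows).to_csv(outdir / "anova.csv", index=False, float_format="%.6f")
    trial_report["correlations"].to_csv(outdir / "correlations.csv", index=False,
                                        float_format="%.6f")

    print(f"MANOVA Roy = {manova.roy:.3f}, F({manova.df1}, {manova.df2}) = "
          f"{manova.f_value:.2f}, p = {manova.p_value:.2g}")
    print(f"LDA separation: LD1 {lda.proportion[0]:.1f}% / LD2 {lda.proportion[1]:.1f}%")
    print("LD1 group centroids (trial level):")
    print(lda.group_means["LD1"].round(2).to_string())
    if trial_report["accuracy_bayes"]:
        print(f"accuracy BF01 = {trial_report['accuracy_bayes']['BF01']:.2f} "
              "(> 1 favors no group effect)")
    print("participant-level Welch post-hocs written per variable")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
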