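"""Extract the per-trial haptic metrics from the simulated cohort.

Reads every session under scratch/cohort/, resamples each annotated trial to
the 0.2 s grid, applies the explorative-touch filter and computes the twelve
haptic dependent variables plus per-participant recognition accuracy.
Writes results/metrics.csv (one row per trial phase) and
results/accuracy.csv.

Run analysis/01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from hapticube.io import read_session
from hapticube.pipeline import accuracy_table, trial_metrics_table, write_metrics_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    sessions = sorted(cohort_dir.glob("*.jsonl"))
    if not sessions:
        raise SystemExit(f"no sessions in {cohort_dir}; run analysis/01_simulate_cohort.py first")

    tables = []
    annotations_all = []
    for path in sessions:
        samples, annotations = read_session(path)
        tables.append(trial_metrics_table(samples, annotations))
        annotations_all.extend(annotations)
    metrics = pd.concat(tables, ignore_index=True)
    accuracy = accuracy_table(annotations_all)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    write_metrics_csv(metrics, results / "metrics.csv")
    accuracy.to_csv(results / "accuracy.csv", index=False, float_format="%.6f")

    print(f"{len(metrics)} trial rows from {len(sessions)} sessions")
    summary = metrics.groupby("group")[
        ["mean_active_cells", "mean_smc", "amount_of_rotation", "exploration_duration"]
    ].mean()
    print(summary.round(3).to_string())
    print(f"wrote {results / 'metrics.csv'} and {results / 'accuracy.csv'}")


if __name__ == "__main__":
    main()
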