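"""Simulate the synthetic study cohort.

Generates the default cohort — 6 congenitally blind (CB), 10 late blind
(LB) and 16 sighted (SI) synthetic participants, three memorization+recall
trial pairs each, group presets carrying the published group-level targets —
and writes one session file per participant under scratch/cohort/ (raw
sessions are bulky; only the manifest goes to results/).

Usage: python analysis/01_simulate_cohort.py [--seed 42]
"""

import argparse
import csv
from pathlib import Path

from hapticube.io import write_session
from hapticube.synthetic import generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    outdir = ROOT / "scratch" / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(seed=args.seed)

    manifest = []
    for samples, annotations, script in cohort:
        path = outdir / f"{script.participant_id}.jsonl"
        write_session(samples, annotations, path)
        manifest.append(
            {
                "participant_id": script.participant_id,
                "group": script.group,
                "n_samples": len(samples),
                "n_trials": len(script.trials),
                "target_active_cells": f"{script.preset.target_active_cells:.4f}",
                "target_smc": f"{script.preset.target_smc:.4f}",
                "target_rotation_deg": f"{script.preset.total_rotation:.1f}",
            }
        )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with (results / "cohort_manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)

    print(f"wrote {len(cohort)} sessions to {outdir} (seed {args.seed})")
    print(f"manifest: {results / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
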