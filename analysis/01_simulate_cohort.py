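#!/usr/bin/env python
"""Simulate the study cohort: 18 graded patients (6 per response class).

Generates the default synthetic cohort — 6/6/6 patients across the three
pathological response grades, 16 replicate wells each, a 4-hour baseline
and 10 hours of post-treatment acquisition in ~40-minute bursts — and
writes the truth table plus a per-patient summary of raw spectral response.

The cohort is regenerated deterministically from COHORT_SEED by the later
scripts, so no bulky intensity data needs to live on disk.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bdiflow.spectral import burst_power_spectrum
from bdiflow.synthetic import CohortSpec, generate_cohort

COHORT_SEED = 20260927
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spec = CohortSpec(
        n_patients_per_grade=(6, 6, 6),
        wells_per_patient=16,
        arms=("cisplatin",),
        seed=COHORT_SEED,
    )
    cohort = generate_cohort(spec)
    RESULTS.mkdir(exist_ok=True)
    cohort.grades.to_csv(RESULTS / "grades.csv", index=False)

    fs = cohort.acquisition.frame_rate_hz
    nb = cohort.n_baseline_bursts
    rows = []
    for _, rec in cohort.grades.iterrows():
        wells = cohort.series[(rec["patient_id"], rec["arm"])]
        ratios = []
        for w in range(wells.shape[0]):
            base = np.mean(
                [burst_power_spectrum(wells[w, b], fs, 0).density.sum() for b in range(nb)]
            )
            post = np.mean(
                [
                    burst_power_spectrum(wells[w, b], fs, 0).density.sum()
                    for b in range(nb, wells.shape[1])
                ]
            )
            ratios.append(post / base)
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "grade": rec["grade"],
                "arm": rec["arm"],
                "median_post_over_baseline_power": round(float(np.median(ratios)), 4),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

    print(f"simulated {len(cohort.grades)} patients x {spec.wells_per_patient} wells")
    print("median post/baseline integrated-power ratio by grade:")
    print(summary.groupby("grade")["median_post_over_baseline_power"].median())
    print(f"wrote {RESULTS/'grades.csv'} and {RESULTS/'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
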