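#!/usr/bin/env python
"""Classify every patient under one-left-out cross-validation.

Reads the candidate table and truth grades from scripts 01/03, runs the
triplet-embedding + k-means classifier with in-fold selection and
standardization, and writes per-patient class likelihoods and predictions.
"""

from pathlib import Path

import pandas as pd

from bdiflow.classifier import NetworkConfig, olo_cross_validate
from bdiflow.io import read_outcomes

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    candidates = pd.read_csv(RESULTS / "features.csv", index_col="patient_id")
    truths = read_outcomes(RESULTS / "grades.csv").set_index("patient_id")["grade"]
    preds = olo_cross_validate(candidates, truths, NetworkConfig(seed=1))
    preds.to_csv(RESULTS / "predictions.csv", index=False, float_format="%.12g")

    acc = (preds["predicted"] == preds["actual"]).mean()
    print(f"OLO three-class accuracy: {acc:.3f} "
          f"({(preds['predicted'] == preds['actual']).sum()}/{len(preds)})")
    print(pd.crosstab(preds["predicted"], preds["actual"]))
    print(f"wrote {RESULTS/'predictions.csv'}")


if __name__ == "__main__":
    main()
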