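#!/usr/bin/env python
"""Internal validation of the candidate models and final selection.

Takes the eight candidates the full-sample ranking singles out (the M4
and M5 specifications of each family), runs fivefold cross-validation
and a 70/30 random-split validation on the synthetic cohort, combines
the ten resulting statistics into the final average-rank-value scores
and names the winner. Output: results/validation_report.json.

Run 01_simulate_cohort.py first (reads results/cohort.csv).
"""

import json
from pathlib import Path

import pandas as pd

from prefmap.validation import (
    ModelCandidate,
    combined_selection,
    cross_validate,
    holdout_validate,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20230817

CANDIDATES = [
    ModelCandidate("ols", "M4"),
    ModelCandidate("ols", "M5"),
    ModelCandidate("tobit", "M4"),
    ModelCandidate("tobit", "M5"),
    ModelCandidate("oprobit", "M4"),
    ModelCandidate("oprobit", "M5"),
    ModelCandidate("betamix", "M4", (("components", 1), ("n_starts", 8), ("label_suffix", "a"))),
    ModelCandidate("betamix", "M5", (("components", 1), ("n_starts", 8), ("label_suffix", "a"))),
]


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")

    print("validation I: fivefold cross-validation (pooled out-of-fold)")
    valI = cross_validate(CANDIDATES, cohort, k=5, seed=SEED)
    print(valI.round(4).to_string())

    print("validation II: random 70/30 split (test n = 315)")
    valII = holdout_validate(CANDIDATES, cohort, train_fraction=0.70, seed=SEED)
    print(valII.round(4).to_string())

    report = combined_selection(valI, valII)
    print("combined ARV over the 10 validation statistics:")
    print(report.combined_arv.round(2).sort_values().to_string())
    print(f"selected model: {report.winner}")

    payload = {
        "seed": SEED,
        "validation_cv": valI.round(6).to_dict(orient="index"),
        "validation_holdout": valII.round(6).to_dict(orient="index"),
        "combined_arv": report.combined_arv.round(3).to_dict(),
        "winner": report.winner,
    }
    with open(RESULTS / "validation_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)


if __name__ == "__main__":
    main()
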