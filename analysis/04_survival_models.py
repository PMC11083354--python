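#!/usr/bin/env python
"""Collinearity screen and the two multivariable Cox models.

Confirms that zone fraction and zone distance are collinear (hence the two
separate models), fits model A (fractions) and model B (distances) and
writes their hazard-ratio tables.
"""

from pathlib import Path

import pandas as pd

from nichecontact import fit_cox_model
from nichecontact.io_core import CohortTable
from nichecontact.survival_stats import check_model_separation

ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort_dir = ROOT / "results" / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    cohort = CohortTable(
        clinical=pd.read_csv(cohort_dir / "clinical.csv"),
        spatial=pd.read_csv(cohort_dir / "spatial_truth.csv"))

    flags = check_model_separation(cohort)["flags"]
    print("collinearity flags (|r| >= 0.7):")
    for a, b, r in flags:
        print(f"  {a} ~ {b}: r = {r:.2f}")

    for model in ("A", "B"):
        fit = fit_cox_model(cohort, model=model)
        out = ROOT / "results" / f"cox_model_{model}.csv"
        fit.summary.to_csv(out)
        print(f"\nmodel {model} (n={fit.n}, events={fit.n_events}) -> {out}")
        print(fit.summary.round(4).to_string())


if __name__ == "__main__":
    main()
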