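#!/usr/bin/env python
"""Cohort survival report: Kaplan-Meier by stratifier, multivariate Cox,
and the combined radiomic + molecular three-group stratification.

Requires scratch/radiomic_risk.csv (run 03 first). Writes
results/km_medians.csv and results/cox_table.csv.
"""
from pathlib import Path

import pandas as pd

from gliorad.survival import (
    combined_risk_groups,
    cox_multivariate,
    km_estimate,
    logrank_test,
)

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "prog", Path(__file__).with_name("03_prognostic_spca.py"))
_prog = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_prog)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    _, clin = _prog.load_tables()
    risk = pd.read_csv(ROOT / "scratch" / "radiomic_risk.csv").set_index("case_id")
    df = clin.join(risk["radiomic_risk"]).reset_index()
    df["combined_risk"] = combined_risk_groups(df["radiomic_risk"], df["pmgmt"])

    rows = []
    for strat in ("radiomic_risk", "pmgmt", "combined_risk"):
        chi2, p = logrank_test(df[strat], df["os_months"], df["event"])
        for level, sub in df.groupby(strat):
            km = km_estimate(sub["os_months"], sub["event"])
            rows.append({"stratifier": strat, "group": level, "n": len(sub),
                         "median_months": km.median_months, "logrank_p": p})
        print(f"{strat}: log-rank p = {p:.2g}")
    km_df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    km_df.to_csv(RESULTS / "km_medians.csv", index=False)
    print(km_df.to_string(index=False))

    fit = cox_multivariate(df)
    fit.table.to_csv(RESULTS / "cox_table.csv", index=False)
    print("\nmultivariate Cox (HR, 95 % CI, p):")
    for _, r in fit.table.iterrows():
        print(f"  {r['factor']:26s} {r['hr']:.2f} "
              f"({r['ci_low']:.2f}-{r['ci_high']:.2f})  p={r['p']:.3g}")
    print(f"  surgery global (2 df Wald)  p={fit.surgery_global_p:.3g}")


if __name__ == "__main__":
    main()
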