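#!/usr/bin/env python
"""Long-term-survivor prediction across overall-survival cutoffs.

For each cutoff from 10 to 17 months, labels cases long/short (censored
before the cutoff are excluded), runs nested-CV L1 logistic prediction,
and tabulates the accuracy profile. Writes results/survivor_sweep.csv.
"""
from pathlib import Path

from gliorad.lasso import survivor_sweep

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "prog", Path(__file__).with_name("03_prognostic_spca.py"))
_prog = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_prog)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    X, clin = _prog.load_tables()
    tbl, selected = survivor_sweep(
        X, clin["os_months"], clin["event"],
        cutoffs=[10, 11, 12, 13, 14, 15, 16, 17],
        outer_k=10, repeats=2, seed=2, n_lambda=30)
    RESULTS.mkdir(exist_ok=True)
    tbl.to_csv(RESULTS / "survivor_sweep.csv", index=False)
    cols = ["cutoff_months", "modelable", "n_labeled", "accuracy"]
    print(tbl[[c for c in cols if c in tbl.columns]].to_string(index=False))
    best = tbl[tbl["modelable"] == True]  # noqa: E712
    if len(best):
        b = best.loc[best["accuracy"].idxmax()]
        print(f"best accuracy {100 * b['accuracy']:.1f} % at "
              f"{b['cutoff_months']:.0f} months "
              f"({len(selected[float(b['cutoff_months'])])} features selected)")


if __name__ == "__main__":
    main()
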