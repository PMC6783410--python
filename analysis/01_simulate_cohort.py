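#!/usr/bin/env python
"""Simulate the phantom GBM cohort used by every downstream analysis.

Writes 100 cases (three MR-like volumes + two lesion masks each, NIfTI)
and the clinical/truth tables to scratch/cohort/, then prints the cohort's
basic survival characteristics.
"""
from pathlib import Path

import numpy as np

from gliorad.survival import km_estimate
from gliorad.synthetic import CohortConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
CONFIG = CohortConfig(n_cases=100, grid_shape=(48, 48, 48), seed=0)


def main():
    cases, clinical = generate_cohort(CONFIG)
    manifest = write_cohort(cases, clinical, OUT)
    km = km_estimate(clinical["os_months"], clinical["event"])
    print(f"wrote {len(manifest)} artifacts to {OUT}")
    print(f"n = {len(clinical)}, events = {clinical['event'].sum()} "
          f"({100 * clinical['event'].mean():.0f} %)")
    print(f"median OS = {km.median_months:.1f} months")
    print(f"methylated fraction = {clinical['pmgmt'].mean():.2f}")
    het = [c.truth.heterogeneity for c in cases]
    print(f"planted heterogeneity range: {min(het):.1f} - {max(het):.1f}")


if __name__ == "__main__":
    main()
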