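#!/usr/bin/env python
"""Radiomic risk stratification with the supervised-PC survival model.

Tunes the screening threshold by 10-fold cross-validation, fits the
model, classifies every case as radiomic high/low risk, and summarizes
the resulting Kaplan-Meier separation. Writes results/spca_summary.csv,
results/spca_importance.csv and scratch/radiomic_risk.csv.

Requires scratch/features.csv (run 02 first); the clinical table is
regenerated deterministically from the cohort config.
"""
from pathlib import Path

import pandas as pd

from gliorad.spca import (
    spca_classify,
    spca_cross_validate_threshold,
    spca_fit,
    spca_importance,
)
from gliorad.survival import km_estimate, logrank_test
from gliorad.synthetic import generate_clinical, sample_truth

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "sim", Path(__file__).with_name("01_simulate_cohort.py"))
_sim = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sim)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def load_tables():
    feats = pd.read_csv(ROOT / "scratch" / "features.csv").set_index("case_id")
    truths = [sample_truth(_sim.CONFIG, i) for i in range(_sim.CONFIG.n_cases)]
    clin = generate_clinical(_sim.CONFIG, truths).set_index("case_id")
    clin = clin.loc[feats.index]
    X = feats[[c for c in feats.columns if not c.startswith("loc_")]]
    return X, clin


def main():
    X, clin = load_tables()
    t = clin["os_months"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    cv = spca_cross_validate_threshold(X, t, e, k=10, seed=0)
    model = spca_fit(X, t, e, cv.best_threshold, cv_seed=0)
    score, labels = spca_classify(model, X)
    print(f"tuned threshold = {cv.best_threshold:.3f}; "
          f"{len(model.retained)} features retained")

    hi, lo = labels == "high", labels == "low"
    km_hi = km_estimate(t[hi], e[hi])
    km_lo = km_estimate(t[lo], e[lo])
    chi2, p = logrank_test(labels, t, e)
    print(f"median OS: high-risk {km_hi.median_months:.1f} mo "
          f"(n={hi.sum()}), low-risk {km_lo.median_months:.1f} mo "
          f"(n={lo.sum()}); log-rank p = {p:.2g}")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame([
        {"group": "high", "n": int(hi.sum()),
         "median_os_months": km_hi.median_months},
        {"group": "low", "n": int(lo.sum()),
         "median_os_months": km_lo.median_months},
        {"group": "logrank", "n": len(t), "median_os_months": p},
    ]).to_csv(RESULTS / "spca_summary.csv", index=False)
    imp = spca_importance(model, X)
    (pd.Series(imp, name="importance").rename_axis("feature")
       .sort_values(key=abs, ascending=False)
       .to_csv(RESULTS / "spca_importance.csv"))
    model.to_json(RESULTS / "spca_model.json")
    pd.DataFrame({"case_id": X.index, "score": score,
                  "radiomic_risk": labels}).to_csv(
        ROOT / "scratch" / "radiomic_risk.csv", index=False)
    top = max(imp, key=lambda k: abs(imp[k]))
    print(f"most important retained feature: {top} ({imp[top]:+.2f})")


if __name__ == "__main__":
    main()
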