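"""Kaplan-Meier, log-rank, multivariate Cox, and combined risk grouping.

The estimation itself is delegated to lifelines; this module fixes the
cohort-report conventions: median survival is the first time the
product-limit curve reaches 0.5 or below (undefined, not interpolated,
when it never does), the 3-level surgery factor is reported as the three
pairwise contrasts plus a global Wald test, and the combined
radiomic + molecular grouping follows the fixed three-class rule
(high = radiomic high AND unmethylated; low = radiomic low AND
methylated; everything else intermediate).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


@dataclass
class KMCurve:
    times: np.ndarray               # ordered observed event times
    survival: np.ndarray            # S(t) just after each event time
    at_risk: np.ndarray
    median_months: float            # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no observations")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    s = kmf.survival_function_.loc[t, kmf.survival_function_.columns[0]].to_numpy()
    at_risk = ev["at_risk"].to_numpy()
    below = np.flatnonzero(s <= 0.5)
    median = float(t[below[0]]) if len(below) else float("nan")
    return KMCurve(t, s, at_risk, median)


def logrank_test(groups, times, events) -> tuple:
    """Log-rank test across >= 2 groups; returns (chi-square, p)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups,
                                    np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


SURGERY_LEVELS = ("total", "partial", "biopsy")


@dataclass
class CoxFit:
    table: pd.DataFrame             # hr, ci_low, ci_high, p per reported row
    surgery_global_p: float | None
    encoding: dict


def cox_multivariate(clinical: pd.DataFrame, time_col: str = "os_months",
                     event_col: str = "event") -> CoxFit:
    """Multivariate Cox model of the cohort's prognostic factors.

    Expects columns age, kps, surgery (total/partial/biopsy), pmgmt
    (1 = methylated) and radiomic_risk ("high"/"low" or 1 = high).
    Continuous covariates enter untransformed (HR per unit). Surgery is
    dummy-coded against total removal; all three pairwise contrasts are
    reported (the biopsy-vs-partial contrast and its Wald CI come from
    the coefficient difference and covariance), plus a global 2-df Wald
    p-value for the factor.
    """
    df = clinical.copy()
    needed = {"age", "kps", "surgery", "pmgmt", "radiomic_risk", time_col, event_col}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    rr = df["radiomic_risk"]
    df["radiomic_high"] = (rr == "high").astype(int) if rr.dtype == object else rr.astype(int)
    df["pmgmt_unmet"] = 1 - df["pmgmt"].astype(int)
    df["surg_partial"] = (df["surgery"] == "partial").astype(int)
    df["surg_biopsy"] = (df["surgery"] == "biopsy").astype(int)

    covs = ["age", "kps", "surg_partial", "surg_biopsy", "pmgmt_unmet", "radiomic_high"]
    for c in covs:
        if df[c].nunique() < 2 and c not in ("surg_partial", "surg_biopsy"):
            raise ValueError(f"covariate {c} has zero variance")
    n_params = len(covs)
    if len(df) < 10 * n_params:
        import warnings
        warnings.warn(
            f"only {len(df)} complete cases for {n_params} parameters; "
            "estimates may be unstable"
        )
    cph = CoxPHFitter()
    cph.fit(df[[time_col, event_col] + covs], duration_col=time_col,
            event_col=event_col)
    summ = cph.summary
    V = cph.variance_matrix_

    def row(label, cov):
        r = summ.loc[cov]
        return {"factor": label, "hr": float(np.exp(r["coef"])),
                "ci_low": float(np.exp(r["coef lower 95%"])),
                "ci_high": float(np.exp(r["coef upper 95%"])),
                "p": float(r["p"])}

    rows = [row("Age", "age"), row("Pretreatment KPS", "kps"),
            row("Partial to Total removal", "surg_partial")]
    # biopsy vs partial: coefficient difference with covariance-based SE
    b_b = summ.loc["surg_biopsy", "coef"]
    b_p = summ.loc["surg_partial", "coef"]
    var = (V.loc["surg_biopsy", "surg_biopsy"] + V.loc["surg_partial", "surg_partial"]
           - 2 * V.loc["surg_biopsy", "surg_partial"])
    se = float(np.sqrt(var))
    diff = float(b_b - b_p)
    z = diff / se if se > 0 else 0.0
    rows.append({"factor": "Biopsy to Partial removal", "hr": float(np.exp(diff)),
                 "ci_low": float(np.exp(diff - 1.96 * se)),
                 "ci_high": float(np.exp(diff + 1.96 * se)),
                 "p": float(2 * sps.norm.sf(abs(z)))})
    rows.append(row("Biopsy to Total removal", "surg_biopsy"))
    rows.append(row("pMGMT unmethylated", "pmgmt_unmet"))
    rows.append(row("Radiomic high-risk", "radiomic_high"))

    # global 2-df Wald test for the surgery factor
    surgery_global_p = None
    if df["surg_partial"].nunique() > 1 and df["surg_biopsy"].nunique() > 1:
        b = summ.loc[["surg_partial", "surg_biopsy"], "coef"].to_numpy()
        Vs = V.loc[["surg_partial", "surg_biopsy"],
                   ["surg_partial", "surg_biopsy"]].to_numpy()
        w = float(b @ np.linalg.solve(Vs, b))
        surgery_global_p = float(sps.chi2.sf(w, df=2))
    return CoxFit(pd.DataFrame(rows), surgery_global_p,
                  {"surgery_reference": "total", "pmgmt": "1=methylated"})


def combined_risk_groups(radiomic_labels, pmgmt_labels) -> np.ndarray:
    """Three-class combined risk from radiomic risk and methylation status.

    high = radiomic high AND unmethylated; low = radiomic low AND
    methylated; all other complete combinations intermediate; cases with
    a missing label are marked "unclassifiable".
    """
    rad = pd.Series(radiomic_labels)
    mgmt = pd.Series(pmgmt_labels)
    if len(rad) != len(mgmt):
        raise ValueError("label vectors differ in length")
    out = np.full(len(rad), "intermediate", dtype=object)
    rad_high = rad == "high" if rad.dtype == object else rad.astype(float) == 1
    rad_low = rad == "low" if rad.dtype == object else rad.astype(float) == 0
    met = mgmt.astype(float) == 1
    unmet = mgmt.astype(float) == 0
    out[np.asarray(rad_high & unmet)] = "high"
    out[np.asarray(rad_low & met)] = "low"
    bad = rad.isna() | mgmt.isna()
    out[np.asarray(bad)] = "unclassifiable"
    return out
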