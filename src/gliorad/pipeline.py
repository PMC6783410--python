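"""End-to-end orchestration: simulate -> preprocess -> extract -> model -> report.

A single YAML config drives every stage; every artifact lands in the
configured work directory and is listed in ``manifest.json`` together
with per-stage config hashes and all seeds, so a rerun with an unchanged
config skips completed stages and a changed model seed rebuilds only the
modeling stages while reusing the image-derived feature table.

Real-data mode: when ``features_csv``/``clinical_csv`` are given, the
image stages are bypassed and the modeling stages run directly on the
supplied feature table (one row per case, catalog feature columns).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import CATALOG, catalog_manifest
from .features import TextureConfig, extract_case_features
from .lasso import nested_cv_metrics, lasso_cv_fit, survivor_sweep
from .preproc import (
    AffineTransform,
    compute_gdzscore,
    compute_t2edge,
    normalize_t1_like,
    normalize_t2,
)
from .spca import spca_classify, spca_cross_validate_threshold, spca_fit
from .survival import combined_risk_groups, cox_multivariate, km_estimate, logrank_test
from .synthetic import CohortConfig, generate_cohort, write_cohort
from .voi import VOI, build_voi_core, build_voi_edema, location_features, map_voi_to_atlas

log = logging.getLogger("gliorad")

CLINICAL_COLUMNS = ("case_id", "age", "sex", "kps", "surgery", "pmgmt",
                    "os_months", "event")


@dataclass
class PipelineConfig:
    workdir: str = "gliorad_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    spca_threshold: float | str = "auto"   # "auto" = CV-tuned
    spca_k: int = 10
    spca_seed: int = 0
    lasso_outer_k: int = 10
    lasso_repeats: int = 5
    lasso_seed: int = 0
    lasso_n_lambda: int = 50
    survivor_cutoffs: tuple = (10, 11, 12, 13, 14, 15, 16, 17)
    features_csv: str | None = None        # real-data mode inputs
    clinical_csv: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        d["texture"] = asdict(self.texture)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        raw.pop("texture_directions", None)
        tex_raw = raw.pop("texture", {})
        if "directions" in tex_raw:
            tex_raw["directions"] = tuple(map(tuple, tex_raw["directions"]))
        texture = TextureConfig(**tex_raw)
        if "survivor_cutoffs" in raw:
            raw["survivor_cutoffs"] = tuple(raw["survivor_cutoffs"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(cohort=cohort, texture=texture, **raw)


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> list:
    """Machine-readable pre-flight issues (missing files, schema problems)."""
    issues = []
    for attr in ("features_csv", "clinical_csv"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            issues.append({"kind": "missing_file", "path": str(p), "field": attr})
    if config.clinical_csv and Path(config.clinical_csv).exists():
        df = pd.read_csv(config.clinical_csv)
        missing = set(CLINICAL_COLUMNS) - set(df.columns)
        for col in sorted(missing):
            issues.append({"kind": "schema", "table": "clinical",
                           "missing_column": col})
        if "pmgmt" in df.columns and df["pmgmt"].isna().any():
            issues.append({"kind": "incomplete_labels", "column": "pmgmt",
                           "n_missing": int(df["pmgmt"].isna().sum())})
    if config.features_csv and Path(config.features_csv).exists():
        cols = pd.read_csv(config.features_csv, nrows=1).columns
        if "case_id" not in cols:
            issues.append({"kind": "schema", "table": "features",
                           "missing_column": "case_id"})
    return issues


# ---------------------------------------------------------------------------
# Per-case preprocessing + extraction


def preprocess_case(case, brain_mask=None, xfm_t1: AffineTransform | None = None,
                    xfm_t2: AffineTransform | None = None) -> dict:
    """Normalize one case's three series, build the two derived series and
    the two VOIs, all on the Gd-T1 grid.

    ``xfm_t1``/``xfm_t2`` are world-to-world affines taking the T1/T2
    grids onto the Gd-T1 grid (e.g. externally estimated registrations);
    omitted, the volumes are assumed pre-aligned. The T2 lesion mask rides
    the T2 transform with nearest-neighbour resampling.
    """
    from .preproc import GridSpec, resample_affine, resample_mask

    t1, t2, t2_lesion = case.t1, case.t2, case.t2_mask
    target = GridSpec(case.t1gd.shape, case.t1gd.grid_to_world)
    if xfm_t1 is not None:
        t1 = resample_affine(t1, xfm_t1, target)
    if xfm_t2 is not None:
        t2 = resample_affine(t2, xfm_t2, target)
        t2_lesion = resample_mask(t2_lesion, case.t2.grid_to_world, xfm_t2, target)
    if brain_mask is None:
        brain_mask = case.t1gd.voxels != 0
    n_t1 = normalize_t1_like(t1, brain_mask)
    n_t1gd = normalize_t1_like(case.t1gd, brain_mask)
    n_t2 = normalize_t2(t2, brain_mask)
    series = {
        "T1": n_t1,
        "T2": n_t2,
        "T1Gd": n_t1gd,
        "T2Edge": compute_t2edge(n_t2),
        "Gdzscore": compute_gdzscore(n_t1, n_t1gd, brain_mask),
    }
    core = build_voi_core(case.core_mask, case.t1gd.spacing_mm,
                          case.t1gd.grid_to_world)
    edema = build_voi_edema(t2_lesion, core)
    return {"series": series, "core": core, "edema": edema}


def case_location_row(core: VOI, edema: VOI) -> dict:
    """Location features of both VOIs on the atlas grid (identity subject
    -> atlas world transform for pre-aligned synthetic data)."""
    xfm = AffineTransform.identity("subject", "atlas")
    out = {}
    for name, voi in (("core", core), ("edema", edema)):
        if voi.is_empty:
            out.update({f"loc_{name}_{k}": np.nan for k in
                        ("x", "y", "z", "volume_mm3", "left_fraction", "right_fraction")})
            continue
        at = map_voi_to_atlas(voi, xfm)
        lf = location_features(at)
        out[f"loc_{name}_x"], out[f"loc_{name}_y"], out[f"loc_{name}_z"] = lf.centroid_atlas_mm
        out[f"loc_{name}_volume_mm3"] = lf.volume_atlas_mm3
        out[f"loc_{name}_left_fraction"] = lf.left_fraction
        out[f"loc_{name}_right_fraction"] = lf.right_fraction
    return out


def extract_cohort_features(cases, texture: TextureConfig | None = None,
                            with_location: bool = True) -> pd.DataFrame:
    """Feature table: 489 texture columns (+ location columns) per case."""
    texture = texture or TextureConfig()
    rows = []
    for case in cases:
        pp = preprocess_case(case)
        vec = extract_case_features(pp["series"], pp["core"], pp["edema"], texture)
        row = vec.to_dict()
        if with_location:
            row.update(case_location_row(pp["core"], pp["edema"]))
        row["case_id"] = case.truth.case_id
        rows.append(row)
    df = pd.DataFrame(rows).set_index("case_id")
    return df


# ---------------------------------------------------------------------------
# Stage runner


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the artifact manifest.

    Stages are skipped when their outputs exist and the relevant part of
    the config is unchanged (per-stage hash recorded in the manifest).
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest_path = workdir / "manifest.json"
    manifest = {"config_hash": config_hash(config.to_dict()), "stages": {}}
    old = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh).get("stages", {})

    def stage_done(name, stage_hash, outputs):
        return (
            old.get(name, {}).get("hash") == stage_hash
            and all(Path(p).exists() for p in outputs)
        )

    def record(name, stage_hash, outputs, t0, skipped=False):
        manifest["stages"][name] = {
            "hash": stage_hash,
            "outputs": [str(p) for p in outputs],
            "seconds": round(_time.time() - t0, 2),
            "skipped": skipped,
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    features_path = workdir / "features.csv"
    clinical_path = workdir / "clinical.csv"

    if config.features_csv:
        # real-data mode: copy through the supplied tables
        feats = pd.read_csv(config.features_csv).set_index("case_id")
        clin = pd.read_csv(config.clinical_csv)
        feats.to_csv(features_path)
        clin.to_csv(clinical_path, index=False)
        record("ingest", config_hash([config.features_csv, config.clinical_csv]),
               [features_path, clinical_path], _time.time())
    else:
        sim_hash = config_hash(asdict(config.cohort))
        ext_hash = config_hash([asdict(config.cohort), asdict(config.texture)])
        t0 = _time.time()
        if stage_done("extract", ext_hash, [features_path, clinical_path]):
            log.info("extract: outputs up to date, skipping")
            record("simulate", sim_hash, old.get("simulate", {}).get("outputs", []),
                   t0, skipped=True)
            record("extract", ext_hash, [features_path, clinical_path], t0,
                   skipped=True)
        else:
            try:
                cases, clin = generate_cohort(config.cohort)
            except Exception as exc:
                raise PipelineError(f"stage simulate failed: {exc}") from exc
            cohort_manifest = write_cohort(cases, clin, workdir / "cohort")
            record("simulate", sim_hash, list(cohort_manifest.values()), t0)
            t0 = _time.time()
            try:
                feats = extract_cohort_features(cases, config.texture)
            except Exception as exc:
                raise PipelineError(f"stage extract failed: {exc}") from exc
            feats.to_csv(features_path)
            clin.to_csv(clinical_path, index=False)
            with open(workdir / "feature_catalog.json", "w") as fh:
                json.dump(catalog_manifest(), fh, indent=2)
            record("extract", ext_hash,
                   [features_path, clinical_path, workdir / "feature_catalog.json"], t0)

    feats = pd.read_csv(features_path).set_index("case_id")
    clin = pd.read_csv(clinical_path)
    texture_cols = [c for c in feats.columns if c in set(CATALOG)]
    X = feats[texture_cols]
    clin = clin.set_index("case_id").loc[feats.index].reset_index()
    time_v = clin["os_months"].to_numpy(float)
    event_v = clin["event"].to_numpy(int)

    # ---- prognostication (supervised PCA) ----
    spca_hash = config_hash([manifest["stages"].get("extract", {}).get("hash"),
                             str(config.spca_threshold), config.spca_k,
                             config.spca_seed])
    model_path = workdir / "spca_model.json"
    risk_path = workdir / "radiomic_risk.csv"
    t0 = _time.time()
    if stage_done("prognosticate", spca_hash, [model_path, risk_path]):
        record("prognosticate", spca_hash, [model_path, risk_path], t0, skipped=True)
        risk = pd.read_csv(risk_path)
    else:
        if config.spca_threshold == "auto":
            cv = spca_cross_validate_threshold(X, time_v, event_v,
                                               k=config.spca_k, seed=config.spca_seed)
            theta = cv.best_threshold
        else:
            theta = float(config.spca_threshold)
        model = spca_fit(X, time_v, event_v, theta, cv_seed=config.spca_seed)
        model.to_json(model_path)
        score, labels = spca_classify(model, X)
        risk = pd.DataFrame({"case_id": feats.index, "score": score,
                             "radiomic_risk": labels})
        risk.to_csv(risk_path, index=False)
        record("prognosticate", spca_hash, [model_path, risk_path], t0)

    # ---- pMGMT prediction (LASSO nested CV) ----
    lasso_hash = config_hash([manifest["stages"].get("extract", {}).get("hash"),
                              config.lasso_outer_k, config.lasso_repeats,
                              config.lasso_seed])
    mgmt_path = workdir / "mgmt_metrics.csv"
    mgmt_feat_path = workdir / "mgmt_selected_features.json"
    t0 = _time.time()
    if stage_done("predict_mgmt", lasso_hash, [mgmt_path, mgmt_feat_path]):
        record("predict_mgmt", lasso_hash, [mgmt_path, mgmt_feat_path], t0,
               skipped=True)
    else:
        y = clin["pmgmt"].to_numpy(int)
        try:
            m = nested_cv_metrics(X, y, outer_k=config.lasso_outer_k,
                                  repeats=config.lasso_repeats,
                                  seed=config.lasso_seed,
                                  n_lambda=config.lasso_n_lambda)
            pd.DataFrame([m.as_dict()]).to_csv(mgmt_path, index=False)
            fit = lasso_cv_fit(X, y, k=config.lasso_outer_k,
                               seed=config.lasso_seed,
                               n_lambda=config.lasso_n_lambda)
            with open(mgmt_feat_path, "w") as fh:
                json.dump({"lambda_min": fit.lambda_min,
                           "selected": fit.selected}, fh, indent=2)
        except ValueError as exc:  # cohort too small / single class
            log.warning("predict_mgmt not modelable: %s", exc)
            pd.DataFrame([{"modelable": False, "reason": str(exc)}]).to_csv(
                mgmt_path, index=False)
            with open(mgmt_feat_path, "w") as fh:
                json.dump({"modelable": False, "reason": str(exc)}, fh)
        record("predict_mgmt", lasso_hash, [mgmt_path, mgmt_feat_path], t0)

    # ---- long-term survivor sweep ----
    sweep_hash = config_hash([lasso_hash, list(config.survivor_cutoffs)])
    sweep_path = workdir / "survivor_sweep.csv"
    t0 = _time.time()
    if stage_done("survivor_sweep", sweep_hash, [sweep_path]):
        record("survivor_sweep", sweep_hash, [sweep_path], t0, skipped=True)
    else:
        tbl, sel = survivor_sweep(X, time_v, event_v, config.survivor_cutoffs,
                                  outer_k=config.lasso_outer_k,
                                  repeats=config.lasso_repeats,
                                  seed=config.lasso_seed,
                                  n_lambda=config.lasso_n_lambda)
        tbl.to_csv(sweep_path, index=False)
        with open(workdir / "survivor_selected_features.json", "w") as fh:
            json.dump({str(k): v for k, v in sel.items()}, fh, indent=2)
        record("survivor_sweep", sweep_hash,
               [sweep_path, workdir / "survivor_selected_features.json"], t0)

    # ---- survival report ----
    report_hash = config_hash([spca_hash, lasso_hash])
    report_dir = workdir / "report"
    report_dir.mkdir(exist_ok=True)
    t0 = _time.time()
    clin2 = clin.merge(risk, on="case_id")
    km_rows = []
    for group_col, value in (("radiomic_risk", None), ("pmgmt", None)):
        for level, sub in clin2.groupby(group_col):
            curve = km_estimate(sub["os_months"], sub["event"])
            km_rows.append({"stratifier": group_col, "group": level,
                            "n": len(sub), "median_months": curve.median_months})
    clin2["combined_risk"] = combined_risk_groups(
        clin2["radiomic_risk"].to_numpy(), clin2["pmgmt"].to_numpy())
    for level, sub in clin2.groupby("combined_risk"):
        curve = km_estimate(sub["os_months"], sub["event"])
        km_rows.append({"stratifier": "combined_risk", "group": level,
                        "n": len(sub), "median_months": curve.median_months})
    km_df = pd.DataFrame(km_rows)
    km_df.to_csv(report_dir / "km_medians.csv", index=False)

    tests = {}
    for col in ("radiomic_risk", "pmgmt", "combined_risk"):
        if clin2[col].nunique() > 1:
            chi2, p = logrank_test(clin2[col].to_numpy(), clin2["os_months"],
                                   clin2["event"])
            tests[col] = {"chi2": chi2, "p": p}
    with open(report_dir / "logrank_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)

    cox_outputs = [report_dir / "km_medians.csv", report_dir / "logrank_tests.json"]
    try:
        cox = cox_multivariate(clin2)
        cox.table.to_csv(report_dir / "cox_table.csv", index=False)
        cox_outputs.append(report_dir / "cox_table.csv")
    except Exception as exc:  # tiny cohorts may not support a 6-parameter fit
        log.warning("multivariate Cox fit not produced: %s", exc)
    clin2.to_csv(report_dir / "cohort_with_risk.csv", index=False)
    cox_outputs.append(report_dir / "cohort_with_risk.csv")
    record("report", report_hash, cox_outputs, t0)
    return manifest
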