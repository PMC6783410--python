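"""The 489-name radiomic feature catalog.

Per (image series, VOI) combination the extractor reports 48 texture
features — 14 histogram first-order statistics, 11 GLCM statistics
aggregated as mean and SD over the 13 unique 3-D directions (22), and 6
GLRLM statistics aggregated the same way (12). With 5 series (T1, T2,
T1Gd, T2Edge, Gdzscore) and 2 VOIs (core, edema) that is 480, plus 9
VOI shape features: 489 in total.

The catalog decomposition (14 / 11x2 / 6x2 per combination plus 9 shape)
is this package's construction of the printed feature count; the exact
per-family split of the original catalog is not published in full.

Name grammar: ``{Series}_{voi}_{Family}{Stat}[_{Agg}]`` with Agg in
{Mean, SD} for the direction-aggregated families, e.g.
``T1Gd_core_GLRLMLrge_SD``.
"""
from __future__ import annotations

SERIES_ORDER = ("T1", "T2", "T1Gd", "T2Edge", "Gdzscore")
VOI_ORDER = ("core", "edema")

FIRST_ORDER_STATS = (
    "Mean", "Median", "Min", "Max", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "Entropy", "P10", "P90", "IQR", "RMS",
)

GLCM_STATS = (
    "Contrast", "Correlation", "Energy", "Entropy", "Homogeneity",
    "Dissimilarity", "Autocorrelation", "ClusterShade",
    "ClusterProminence", "SumAverage", "MaxProbability",
)

# Lrge = long-run emphasis, the abbreviation used in reported feature names
GLRLM_STATS = (
    "ShortRun", "Lrge", "GrayNonUnif", "RunNonUnif", "RunPct", "LowGrayRun",
)

SHAPE_FEATURES = (
    "Shape_core_Volume",
    "Shape_core_SurfaceArea",
    "Shape_core_Sphericity",
    "Shape_core_MaxDiameter",
    "Shape_edema_Volume",
    "Shape_edema_SurfaceArea",
    "Shape_edema_Sphericity",
    "Shape_edema_MaxDiameter",
    "Shape_edema_CoreVolumeRatio",
)

AGGREGATES = ("Mean", "SD")


def combo_feature_names(series: str, voi: str) -> list:
    names = [f"{series}_{voi}_Hist{s}" for s in FIRST_ORDER_STATS]
    for s in GLCM_STATS:
        names += [f"{series}_{voi}_GLCM{s}_{a}" for a in AGGREGATES]
    for s in GLRLM_STATS:
        names += [f"{series}_{voi}_GLRLM{s}_{a}" for a in AGGREGATES]
    return names


def feature_catalog() -> list:
    """The full ordered catalog: 489 unique feature names."""
    names = []
    for series in SERIES_ORDER:
        for voi in VOI_ORDER:
            names += combo_feature_names(series, voi)
    names += list(SHAPE_FEATURES)
    return names


def catalog_manifest() -> list:
    """Catalog with family/series/VOI tags, for JSON export."""
    out = []
    for name in feature_catalog():
        if name.startswith("Shape_"):
            _, voi, stat = name.split("_", 2)
            out.append({"name": name, "series": None, "voi": voi,
                        "family": "Shape", "stat": stat})
        else:
            series, voi, rest = name.split("_", 2)
            if rest.startswith("Hist"):
                fam, stat, agg = "Hist", rest[4:], None
            else:
                fam = rest[:5] if rest.startswith("GLRLM") else rest[:4]
                tail = rest[len(fam):]
                stat, agg = tail.rsplit("_", 1)
            out.append({"name": name, "series": series, "voi": voi,
                        "family": fam, "stat": stat, "agg": agg})
    return out


CATALOG = feature_catalog()
assert len(CATALOG) == 489 and len(set(CATALOG)) == 489
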