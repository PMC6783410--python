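"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates voxels, pairs, runs or risk sets directly in
plain Python, without reusing any of the package's vectorized code paths.
Only usable on tiny inputs.
"""
from __future__ import annotations

import math

import numpy as np


def brute_first_order(values):
    """First-order statistics from the raw voxel list."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    sd = math.sqrt(var)
    if sd > 0:
        skew = sum((x - mean) ** 3 for x in v) / n / sd**3
        kurt = sum((x - mean) ** 4 for x in v) / n / var**2 - 3.0
    else:
        skew = kurt = 0.0
    counts = {}
    for x in v:
        counts[x] = counts.get(x, 0) + 1
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())

    def pct(q):
        # numpy 'linear' convention
        pos = q / 100 * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return {
        "Mean": mean,
        "Median": pct(50),
        "Min": v[0],
        "Max": v[-1],
        "Range": v[-1] - v[0],
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": sum(x * x for x in v) / n,
        "Entropy": entropy,
        "P10": pct(10),
        "P90": pct(90),
        "IQR": pct(75) - pct(25),
        "RMS": math.sqrt(sum(x * x for x in v) / n),
    }


def brute_glcm(labels, offset):
    """Symmetric normalized co-occurrence matrix by direct pair enumeration."""
    labels = np.asarray(labels)
    nb = int(labels.max())
    mat = np.zeros((nb, nb))
    dx, dy, dz = offset
    nx, ny, nz = labels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] == 0:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                if labels[x2, y2, z2] == 0:
                    continue
                a, b = labels[x, y, z] - 1, labels[x2, y2, z2] - 1
                mat[a, b] += 1
                mat[b, a] += 1
    s = mat.sum()
    return mat / s if s > 0 else None


def brute_glcm_stats(p):
    n = p.shape[0]
    stats = {k: 0.0 for k in
             ("Contrast", "Energy", "Entropy", "Homogeneity", "Dissimilarity",
              "Autocorrelation", "ClusterShade", "ClusterProminence",
              "SumAverage")}
    mu = 0.0
    for i in range(n):
        for j in range(n):
            mu += (i + 1) * p[i, j]
    sigma2 = 0.0
    for i in range(n):
        for j in range(n):
            sigma2 += ((i + 1) - mu) ** 2 * p[i, j]
    for i in range(n):
        for j in range(n):
            q = p[i, j]
            if q == 0:
                continue
            gi, gj = i + 1, j + 1
            stats["Contrast"] += (gi - gj) ** 2 * q
            stats["Energy"] += q * q
            stats["Entropy"] -= q * math.log2(q)
            stats["Homogeneity"] += q / (1 + (gi - gj) ** 2)
            stats["Dissimilarity"] += abs(gi - gj) * q
            stats["Autocorrelation"] += gi * gj * q
            stats["ClusterShade"] += (gi + gj - 2 * mu) ** 3 * q
            stats["ClusterProminence"] += (gi + gj - 2 * mu) ** 4 * q
            stats["SumAverage"] += (gi + gj) * q
    stats["MaxProbability"] = float(p.max())
    stats["Correlation"] = (
        (stats["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 1e-12 else 1.0
    )
    return stats


def brute_runs(labels, offset):
    """All maximal same-bin runs along one direction, by walking each line."""
    labels = np.asarray(labels)
    nx, ny, nz = labels.shape
    d = np.asarray(offset)
    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                p = np.array([x, y, z])
                prev = p - d
                # start of a line segment through the volume?
                if (0 <= prev[0] < nx and 0 <= prev[1] < ny and 0 <= prev[2] < nz):
                    continue
                seq = []
                q = p.copy()
                while 0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz:
                    seq.append(int(labels[tuple(q)]))
                    q = q + d
                i = 0
                while i < len(seq):
                    if seq[i] == 0:
                        i += 1
                        continue
                    j = i
                    while j < len(seq) and seq[j] == seq[i]:
                        j += 1
                    runs.append((seq[i], j - i))
                    i = j
    return runs


def brute_glrlm_stats(runs, n_voxels):
    r = len(runs)
    from collections import Counter
    by_gray = Counter(g for g, _ in runs)
    by_len = Counter(l for _, l in runs)
    return {
        "ShortRun": sum(1.0 / l**2 for _, l in runs) / r,
        "Lrge": sum(float(l**2) for _, l in runs) / r,
        "GrayNonUnif": sum(c**2 for c in by_gray.values()) / r,
        "RunNonUnif": sum(c**2 for c in by_len.values()) / r,
        "RunPct": r / n_voxels,
        "LowGrayRun": sum(1.0 / g**2 for g, _ in runs) / r,
    }


def product_limit(times, events):
    """Hand-rolled Kaplan-Meier: returns [(t, S(t))] at event times."""
    data = sorted(zip(times, events))
    n = len(data)
    s = 1.0
    out = []
    i = 0
    while i < n:
        t = data[i][0]
        d = sum(1 for tt, ee in data if tt == t and ee == 1)
        at_risk = sum(1 for tt, _ in data if tt >= t)
        j = i
        while j < n and data[j][0] == t:
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            out.append((t, s))
        i = j
    return out
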