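"""Independent brute-force oracles used to verify feature implementations.

Everything here is written as a direct transcription of the defining sums —
explicit python loops over pixels, pairs, runs, zones and neighborhoods —
and deliberately shares no code with the package implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def oracle_glcm(levels, mask, direction):
    """Co-occurrence features by explicit pair enumeration (one direction)."""
    levels = np.atleast_3d(levels)
    mask = np.atleast_3d(mask).astype(bool)
    ng = int(levels[mask].max())
    C = np.zeros((ng, ng))
    for v in zip(*np.nonzero(mask)):
        w = tuple(v[i] + direction[i] for i in range(3))
        if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w]:
            C[levels[v] - 1, levels[w] - 1] += 1
    C = C + C.T
    P = C / C.sum()
    inv_var = 0.0
    contrast = 0.0
    for i in range(ng):
        for j in range(ng):
            contrast += P[i, j] * (i - j) ** 2
            if i != j:
                inv_var += P[i, j] / (i - j) ** 2
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    hxy = -sum(P[i, j] * math.log2(P[i, j]) for i in range(ng) for j in range(ng) if P[i, j] > 0)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    return {"InverseVariance": inv_var, "Imc1": imc1, "Contrast": contrast}


def oracle_glrlm(levels, mask, direction):
    """Run-length features by walking every maximal run (one direction)."""
    levels = np.atleast_3d(levels)
    mask = np.atleast_3d(mask).astype(bool)
    runs = []
    for v in zip(*np.nonzero(mask)):
        prev = tuple(v[i] - direction[i] for i in range(3))
        if (
            all(0 <= prev[i] < mask.shape[i] for i in range(3))
            and mask[prev]
            and levels[prev] == levels[v]
        ):
            continue  # not a run start
        length = 0
        cur = v
        while (
            all(0 <= cur[i] < mask.shape[i] for i in range(3))
            and mask[cur]
            and levels[cur] == levels[v]
        ):
            length += 1
            cur = tuple(cur[i] + direction[i] for i in range(3))
        runs.append((int(levels[v]), length))
    nr = len(runs)
    return {
        "LongRunEmphasis": sum(j**2 for _, j in runs) / nr,
        "ShortRunEmphasis": sum(1.0 / j**2 for _, j in runs) / nr,
        "LongRunLowGrayLevelEmphasis": sum(j**2 / i**2 for i, j in runs) / nr,
    }


def oracle_glszm(levels, mask, connectivity_3d=True):
    """Size-zone features by flood fill over equal-level zones."""
    levels = np.atleast_3d(levels)
    mask = np.atleast_3d(mask).astype(bool)
    if connectivity_3d:
        neigh = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    else:
        neigh = [
            (a, b, 0) for a, b in itertools.product((-1, 0, 1), repeat=2) if (a, b) != (0, 0)
        ]
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for v in zip(*np.nonzero(mask)):
        if seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in neigh:
                w = tuple(cur[i] + d[i] for i in range(3))
                if (
                    all(0 <= w[i] < mask.shape[i] for i in range(3))
                    and mask[w]
                    and not seen[w]
                    and levels[w] == g
                ):
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), size))
    nz = len(zones)
    mu = sum(g for g, _ in zones) / nz
    return {
        "SmallAreaHighGrayLevelEmphasis": sum(g**2 / s**2 for g, s in zones) / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(g**2 * s**2 for g, s in zones) / nz,
        "GrayLevelVariance": sum((g - mu) ** 2 for g, _ in zones) / nz,
    }


def oracle_ngtdm(levels, mask, use_3d=True):
    """NGTDM features by explicit per-voxel neighborhood averaging."""
    levels = np.atleast_3d(levels)
    mask = np.atleast_3d(mask).astype(bool)
    if use_3d:
        neigh = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    else:
        neigh = [
            (a, b, 0) for a, b in itertools.product((-1, 0, 1), repeat=2) if (a, b) != (0, 0)
        ]
    ng = int(levels[mask].max())
    s = np.zeros(ng + 1)
    n = np.zeros(ng + 1)
    for v in zip(*np.nonzero(mask)):
        vals = []
        for d in neigh:
            w = tuple(v[i] + d[i] for i in range(3))
            if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w]:
                vals.append(levels[w])
        if not vals:
            continue
        g = int(levels[v])
        s[g] += abs(g - sum(vals) / len(vals))
        n[g] += 1
    N = n.sum()
    p = n / N
    occ = [i for i in range(1, ng + 1) if p[i] > 0]
    ngp = len(occ)
    if ngp < 2:
        contrast = 0.0
    else:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1))
            * (s.sum() / N)
        )
    denom = sum(abs(i * p[i] - j * p[j]) for i in occ for j in occ)
    busyness = sum(p[i] * s[i] for i in occ) / denom if denom > 0 else 0.0
    return {"Contrast": contrast, "Busyness": busyness}


def oracle_ch(points, labels):
    """Calinski-Harabasz by explicit double loops."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    n, k = len(points), len(uniq)
    grand = points.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        member = points[labels == u]
        m = member.mean(axis=0)
        B += len(member) * sum((m[d] - grand[d]) ** 2 for d in range(points.shape[1]))
        for x in member:
            W += sum((x[d] - m[d]) ** 2 for d in range(points.shape[1]))
    if W == 0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def oracle_auc(scores, labels):
    """AUC by explicit pairwise concordance counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_mwu_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by rank-sum enumeration.

    Independent of the package implementation: works on the rank sum R1
    rather than U, enumerating all assignments of pooled midranks.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mean_r1 = n1 * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean_r1)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(combo)].sum()
        if abs(r1 - mean_r1) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total
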