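"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-pixel / per-pair enumeration with
Python loops, deliberately avoiding the vectorized implementation paths it
is used to check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Texture matrices by exhaustive enumeration
# ---------------------------------------------------------------------------

def oracle_glcm_counts(levels, ng, offsets):
    h, w = levels.shape
    counts = [[0] * ng for _ in range(ng)]
    for r in range(h):
        for c in range(w):
            if levels[r][c] == 0:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and levels[r2][c2] != 0:
                    a, b = levels[r][c] - 1, levels[r2][c2] - 1
                    counts[a][b] += 1
                    counts[b][a] += 1
    return np.array(counts, dtype=float)


def oracle_glcm_features(levels, ng, offsets):
    counts = oracle_glcm_counts(levels, ng, offsets)
    total = counts.sum()
    p = counts / total
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    corr = 0.0
    if var_i > 0 and var_j > 0:
        corr = sum((i + 1 - mu_i) * (j + 1 - mu_j) * p[i][j]
                   for i in range(ng) for j in range(ng)) / math.sqrt(var_i * var_j)
    out = {
        "Energy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "Homogeneity": sum(p[i][j] / (1 + (i - j) ** 2)
                           for i in range(ng) for j in range(ng)),
        "Entropy": -sum(p[i][j] * math.log2(p[i][j])
                        for i in range(ng) for j in range(ng) if p[i][j] > 0),
        "Variance": var_i,
        "SumAverage": sum((i + j + 2) * p[i][j] for i in range(ng) for j in range(ng)),
        "Dissimilarity": sum(abs(i - j) * p[i][j]
                             for i in range(ng) for j in range(ng)),
        "MaxProbability": p.max(),
    }
    return out


def oracle_runs(levels, direction):
    """All maximal same-level in-mask runs along one direction."""
    h, w = levels.shape
    dr, dc = direction
    runs = []
    for r in range(h):
        for c in range(w):
            v = levels[r][c]
            if v == 0:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w and levels[pr][pc] == v:
                continue  # not a run start
            length = 0
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w and levels[rr][cc] == v:
                length += 1
                rr += dr
                cc += dc
            runs.append((v, length))
    return runs


def oracle_glrlm_features(levels, ng, directions, n_pixels):
    runs = []
    for d in directions:
        runs.extend(oracle_runs(levels, d))
    nr = len(runs)
    rmax = max(l for _, l in runs)
    n = [[0.0] * rmax for _ in range(ng)]
    for v, l in runs:
        n[v - 1][l - 1] += 1
    p = [[n[i][j] / nr for j in range(rmax)] for i in range(ng)]
    p_i = [sum(p[i]) for i in range(ng)]
    p_j = [sum(p[i][j] for i in range(ng)) for j in range(rmax)]
    mu_i = sum((i + 1) * p_i[i] for i in range(ng))
    mu_j = sum((j + 1) * p_j[j] for j in range(rmax))
    s = lambda f: sum(f(i + 1, j + 1) * p[i][j]
                      for i in range(ng) for j in range(rmax))
    return {
        "SRE": s(lambda i, j: 1 / j**2),
        "LRE": s(lambda i, j: j**2),
        "GLN": nr * sum(x**2 for x in p_i),
        "RLN": nr * sum(x**2 for x in p_j),
        "RP": nr / (n_pixels * len(directions)),
        "LGRE": s(lambda i, j: 1 / i**2),
        "HGRE": s(lambda i, j: i**2),
        "SRLGE": s(lambda i, j: 1 / (i**2 * j**2)),
        "SRHGE": s(lambda i, j: i**2 / j**2),
        "LRLGE": s(lambda i, j: j**2 / i**2),
        "LRHGE": s(lambda i, j: i**2 * j**2),
        "GLV": sum((i + 1 - mu_i) ** 2 * p_i[i] for i in range(ng)),
        "RLV": sum((j + 1 - mu_j) ** 2 * p_j[j] for j in range(rmax)),
    }


def oracle_zones(levels):
    """8-connected same-level zones by flood fill: list of (level, size)."""
    h, w = levels.shape
    seen = [[False] * w for _ in range(h)]
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r][c] == 0 or seen[r][c]:
                continue
            v = levels[r][c]
            stack = [(r, c)]
            seen[r][c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w and not seen[r2][c2]
                                and levels[r2][c2] == v):
                            seen[r2][c2] = True
                            stack.append((r2, c2))
            zones.append((v, size))
    return zones


def oracle_glszm_features(levels, ng, n_pixels):
    zones = oracle_zones(levels)
    nz = len(zones)
    zmax = max(s for _, s in zones)
    n = [[0.0] * zmax for _ in range(ng)]
    for v, s_ in zones:
        n[v - 1][s_ - 1] += 1
    p = [[n[i][j] / nz for j in range(zmax)] for i in range(ng)]
    p_i = [sum(p[i]) for i in range(ng)]
    p_z = [sum(p[i][j] for i in range(ng)) for j in range(zmax)]
    mu_i = sum((i + 1) * p_i[i] for i in range(ng))
    mu_z = sum((j + 1) * p_z[j] for j in range(zmax))
    s = lambda f: sum(f(i + 1, j + 1) * p[i][j]
                      for i in range(ng) for j in range(zmax))
    return {
        "SZE": s(lambda i, z: 1 / z**2),
        "LZE": s(lambda i, z: z**2),
        "GLN": nz * sum(x**2 for x in p_i),
        "ZSN": nz * sum(x**2 for x in p_z),
        "ZP": nz / n_pixels,
        "LGZE": s(lambda i, z: 1 / i**2),
        "HGZE": s(lambda i, z: i**2),
        "SZLGE": s(lambda i, z: 1 / (i**2 * z**2)),
        "SZHGE": s(lambda i, z: i**2 / z**2),
        "LZLGE": s(lambda i, z: z**2 / i**2),
        "LZHGE": s(lambda i, z: z**2 * i**2),
        "GLV": sum((i + 1 - mu_i) ** 2 * p_i[i] for i in range(ng)),
        "ZSV": sum((j + 1 - mu_z) ** 2 * p_z[j] for j in range(zmax)),
    }


def oracle_ngtdm_features(levels, ng, mask, cap=1.0e6):
    h, w = levels.shape
    n = [0.0] * ng
    s = [0.0] * ng
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r][c]:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2][c2]:
                        neigh.append(levels[r2][c2])
            if not neigh:
                continue
            n_valid += 1
            i = levels[r][c]
            n[i - 1] += 1
            s[i - 1] += abs(i - sum(neigh) / len(neigh))
    p = [x / n_valid for x in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(ng))
    s_sum = sum(s)
    coarse = 1.0 / ps if ps > 0 else cap
    contrast = 0.0
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (ngp * (ngp - 1))) * (s_sum / n_valid)
    denom_b = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                  for i in present for j in present)
    busy = ps / denom_b if denom_b > 0 else 0.0
    cplx = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (n_valid * (p[i] + p[j]))
               for i in present for j in present)
    strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                / s_sum) if s_sum > 0 else 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy,
            "Complexity": cplx, "Strength": strength}


# ---------------------------------------------------------------------------
# Greedy stepwise-selection oracle
# ---------------------------------------------------------------------------

def oracle_select(table, labels, drop_ratio=0.5, max_features=20,
                  redundancy_sign="minus"):
    """Exhaustive greedy re-selection recomputing correlations each step."""
    cols = list(table.columns)
    y = (np.asarray(labels) == np.unique(labels)[1]).astype(float)

    def absr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))

    rel = {c: absr(table[c].to_numpy(dtype=float), y) for c in cols}
    selected = [min(cols, key=lambda c: (-rel[c], c))]
    scores = [rel[selected[0]]]
    termination = "exhausted"
    while True:
        remaining = [c for c in cols if c not in selected]
        if not remaining:
            termination = "exhausted"
            break
        if len(selected) >= max_features:
            termination = "max_features"
            break
        red = {c: float(np.mean([absr(table[c].to_numpy(dtype=float),
                                      table[s].to_numpy(dtype=float))
                                 for s in selected])) for c in remaining}
        sign = -1.0 if redundancy_sign == "minus" else 1.0
        crit = {c: rel[c] + sign * red[c] for c in remaining}
        best = min(remaining, key=lambda c: (-crit[c], c))
        score = red[best] + rel[best]
        if score < drop_ratio * scores[-1]:
            termination = "score_drop"
            break
        selected.append(best)
        scores.append(score)
    return selected, scores, termination


# ---------------------------------------------------------------------------
# AUC by exhaustive pair counting
# ---------------------------------------------------------------------------

def oracle_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
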