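"""Independent brute-force oracles.

Every texture family and filter metric is re-implemented here with naive
loops, straight from the definitions, sharing no code with the package.
These exist solely to cross-check the vectorized implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# histogram

def hist_oracle(pixels):
    x = [float(v) for row in np.asarray(pixels) for v in row]
    n = len(x)
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    ps = [c / n for c in counts.values()]
    energy = sum(p * p for p in ps)
    entropy = -sum(p * math.log2(p) for p in ps if p > 0)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2 - 3.0
    else:
        skew = kurt = 0.0
    return [energy, entropy, kurt, mean, skew, sd, var]


# ---------------------------------------------------------------------------
# co-occurrence

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix_oracle(pixels, levels, distance, angle):
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[pixels[r, c], pixels[r2, c2]] += 1
                mat[pixels[r2, c2], pixels[r, c]] += 1
    return mat / mat.sum()


def glcm_oracle_single(P):
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    if sd_x > 0 and sd_y > 0:
        corr = (
            sum(i * j * P[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        corr = 0.0
    d_avg = sum(k * p_diff[k] for k in range(L))
    s_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    ent = lambda ps: -sum(p * math.log2(p) for p in ps if p > 0)
    return [
        corr,
        ent(p_diff),
        sum((k - d_avg) ** 2 * p_diff[k] for k in range(L)),
        s_avg,
        ent(p_sum),
        sum((i - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        sum((k - s_avg) ** 2 * p_sum[k] for k in range(2 * L - 1)),
        sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
        ent(P.ravel()),
        sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
        sum((i + j - mu_x - mu_y) ** 3 * P[i, j] for i in range(L) for j in range(L)),
        sum((i + j - mu_x - mu_y) ** 4 * P[i, j] for i in range(L) for j in range(L)),
    ]


def glcm_oracle(pixels, levels, distance=1, angles=(0, 45, 90, 135)):
    per = [
        glcm_oracle_single(glcm_matrix_oracle(pixels, levels, distance, a))
        for a in angles
    ]
    return [sum(v[k] for v in per) / len(per) for k in range(13)]


# ---------------------------------------------------------------------------
# statistical feature matrix

def sfm_oracle(pixels, displacements=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    pixels = np.asarray(pixels, float)
    h, w = pixels.shape
    means = []
    for dr, dc in displacements:
        diffs = []
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    diffs.append(abs(pixels[r, c] - pixels[r2, c2]))
        means.append(sum(diffs) / len(diffs))
    return sum(means) / len(means)


# ---------------------------------------------------------------------------
# run lengths

def _lines_oracle(pixels, angle):
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    step = _OFFSETS[angle]
    starts = []
    # a line start is any in-bounds pixel whose backward neighbour is out
    for r in range(h):
        for c in range(w):
            pr, pc = r - step[0], c - step[1]
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    lines = []
    for r, c in starts:
        line = []
        while 0 <= r < h and 0 <= c < w:
            line.append(pixels[r, c])
            r, c = r + step[0], c + step[1]
        lines.append(line)
    return lines


def glrlm_oracle(pixels, levels, directions=(0, 45, 90, 135)):
    pixels = np.asarray(pixels)
    n_pix = pixels.size
    out = []
    for angle in directions:
        runs = []  # (level, length)
        for line in _lines_oracle(pixels, angle):
            i = 0
            while i < len(line):
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                runs.append((line[i], j - i))
                i = j
        n_runs = len(runs)
        sre = sum(1.0 / l**2 for _, l in runs) / n_runs
        lre = sum(float(l**2) for _, l in runs) / n_runs
        per_level = {}
        per_len = {}
        for g, l in runs:
            per_level[g] = per_level.get(g, 0) + 1
            per_len[l] = per_len.get(l, 0) + 1
        glu = sum(v**2 for v in per_level.values()) / n_runs
        rlu = sum(v**2 for v in per_len.values()) / n_runs
        out.append([sre, lre, glu, rlu, n_runs / n_pix])
    return [sum(v[k] for v in out) / len(out) for k in range(5)]


# ---------------------------------------------------------------------------
# Laws masks

def laws_oracle(pixels, vectors):
    pixels = np.asarray(pixels, float)
    l5, e5, s5 = vectors
    named = {"L": l5, "E": e5, "S": s5}
    h, w = pixels.shape
    means, variances = [], []
    for name in ("LE", "EL", "SL", "EE", "LS"):
        mask = [[named[name[0]][i] * named[name[1]][j] for j in range(5)] for i in range(5)]
        resp = []
        for r in range(h - 4):
            for c in range(w - 4):
                # full 2-D convolution: kernel flipped in both axes
                acc = 0.0
                for i in range(5):
                    for j in range(5):
                        acc += mask[4 - i][4 - j] * pixels[r + i, c + j]
                resp.append(abs(acc))
        m = sum(resp) / len(resp)
        means.append(m)
        variances.append(sum((v - m) ** 2 for v in resp) / len(resp))
    return means + variances


# ---------------------------------------------------------------------------
# NGLDM

def ngldm_oracle(pixels, levels, distance=1, tolerance=0):
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    d = distance
    n_neigh = (2 * d + 1) ** 2 - 1
    Q = np.zeros((levels, n_neigh + 1))
    for r in range(d, h - d):
        for c in range(d, w - d):
            k = 0
            for dr in range(-d, d + 1):
                for dc in range(-d, d + 1):
                    if (dr, dc) != (0, 0) and abs(
                        int(pixels[r + dr, c + dc]) - int(pixels[r, c])
                    ) <= tolerance:
                        k += 1
            Q[pixels[r, c], k] += 1
    S = Q.sum()
    sne = sum(
        Q[g, k] / k**2 for g in range(levels) for k in range(1, n_neigh + 1)
    ) / S
    lne = sum(Q[g, k] * k**2 for g in range(levels) for k in range(n_neigh + 1)) / S
    nnu = sum(Q[:, k].sum() ** 2 for k in range(n_neigh + 1)) / S
    sm = sum((Q[g, k] / S) ** 2 for g in range(levels) for k in range(n_neigh + 1))
    ent = -sum(
        (q / S) * math.log2(q / S) for q in Q.ravel() if q > 0
    )
    return [sne, lne, nnu, sm, ent]


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_oracle(pixels, levels, distance=1, epsilon=1e-6):
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    d = distance
    s = [0.0] * levels
    n_g = [0] * levels
    N = 0
    for r in range(d, h - d):
        for c in range(d, w - d):
            neigh = [
                float(pixels[r + dr, c + dc])
                for dr in range(-d, d + 1)
                for dc in range(-d, d + 1)
                if (dr, dc) != (0, 0)
            ]
            g = int(pixels[r, c])
            s[g] += abs(g - sum(neigh) / len(neigh))
            n_g[g] += 1
            N += 1
    present = [g for g in range(levels) if n_g[g] > 0]
    p = {g: n_g[g] / N for g in present}
    Ng = len(present)
    coars = 1.0 / (epsilon + sum(p[g] * s[g] for g in present))
    if Ng > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (Ng * (Ng - 1))
        ) * (sum(s[g] for g in present) / N)
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busy = (
            sum(p[g] * s[g] for g in present) / (busy_den + epsilon)
            if busy_den > 0
            else 0.0
        )
        compl_ = sum(
            abs(i - j) / (N * (p[i] + p[j])) * (p[i] * s[i] + p[j] * s[j])
            for i in present
            for j in present
        )
    else:
        contrast = busy = compl_ = 0.0
    strength = sum(
        (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
    ) / (epsilon + sum(s[g] for g in present))
    return [busy, coars, compl_, contrast, strength]


# ---------------------------------------------------------------------------
# wavelet LL (orthonormal Haar, symmetric boundary)

def haar_ll_oracle(pixels):
    x = np.asarray(pixels, float)
    if x.shape[0] % 2:
        x = np.vstack([x, x[-1:]])
    if x.shape[1] % 2:
        x = np.hstack([x, x[:, -1:]])
    return (x[0::2, 0::2] + x[0::2, 1::2] + x[1::2, 0::2] + x[1::2, 1::2]) / 2.0


# ---------------------------------------------------------------------------
# local Fourier ring

_RING = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def local_fourier_oracle(pixels):
    pixels = np.asarray(pixels, float)
    h, w = pixels.shape
    mags = [[] for _ in range(8)]
    phases = [[] for _ in range(8)]
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            ring = [pixels[r + dr, c + dc] for dr, dc in _RING]
            for u in range(8):
                re = sum(ring[n] * math.cos(-2 * math.pi * u * n / 8) for n in range(8))
                im = sum(ring[n] * math.sin(-2 * math.pi * u * n / 8) for n in range(8))
                mag = math.hypot(re, im)
                tol = 1e-9 * (1.0 + mag)
                if abs(re) <= tol:
                    re = 0.0
                if abs(im) <= tol:
                    im = 0.0
                mags[u].append(mag)
                phases[u].append(math.atan2(im, re) if mag > 1e-9 else 0.0)
    def mean(v):
        return sum(v) / len(v)
    def sd(v):
        m = mean(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))
    return (
        [mean(m) for m in mags]
        + [mean(p) for p in phases]
        + [sd(m) for m in mags]
        + [sd(p) for p in phases]
    )


# ---------------------------------------------------------------------------
# filter metrics (literal second-path implementations)

def dice_oracle(groups):
    """groups: list of 1-D arrays, one per setting."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    num = sum((g.mean() - grand) ** 2 for g in groups)
    den = sum(
        sum((v - g.mean()) ** 2 for v in g) / (len(g) - 1) for g in groups
    )
    return num / den


def ttest_setting_oracle(pos, neg):
    mp, mn = np.mean(pos), np.mean(neg)
    vp = sum((v - mp) ** 2 for v in pos) / (len(pos) - 1)
    vn = sum((v - mn) ** 2 for v in neg) / (len(neg) - 1)
    return abs(mp - mn) / math.sqrt(vp / len(pos) + vn / len(neg))


def aggregate_oracle(per_setting):
    s = len(per_setting)
    m = sum(per_setting) / s
    sd = math.sqrt(sum((v - m) ** 2 for v in per_setting) / (s - 1))
    return sum(per_setting) / (s * sd)


def pearson_oracle(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def fitness_oracle(accs):
    return sum(accs) - sum((a - b) ** 2 for a, b in combinations(accs, 2))
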