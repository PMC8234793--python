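"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain scalar loops, deliberately sharing no
code path with the package, so agreement between the two is meaningful.
"""

import math

import numpy as np


def window_eval(window, lambda_g=3.0):
    """Scalar-loop reliability statistics and filter response of a 5x5 window.

    Returns (reference, deviation, reliable_flags_rowmajor, response).
    """
    vals = [float(v) for row in np.asarray(window) for v in row]
    assert len(vals) == 25
    xc = sorted(vals)[12]
    xbar = sum(vals) / 25.0
    xo = (xc + xbar) / 2.0
    sigma = math.sqrt(sum((v - xo) ** 2 for v in vals) / 25.0)
    rel = [abs(v - xo) <= sigma for v in vals]
    nr = sum(rel)
    sg2 = sum((v - xo) ** 2 for v, r in zip(vals, rel) if r) / nr
    num = den = 0.0
    for idx, (v, r) in enumerate(zip(vals, rel)):
        if not r:
            continue
        dr, dc = divmod(idx, 5)
        d = math.hypot(dr - 2, dc - 2)
        cs = math.exp(-d)
        cg = 1.0 if sg2 <= 1e-6 else math.exp(-((xo - v) ** 2) / (lambda_g * sg2))
        num += cs * cg * v
        den += cs * cg
    return xo, sigma, rel, num / den


def filter_image(img, lambda_g=3.0):
    """Naive double-loop version of the adaptive local window filter."""
    arr = np.asarray(img, dtype=float)
    padded = np.pad(arr, 2, mode="reflect")
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = window_eval(padded[i : i + 5, j : j + 5], lambda_g)[3]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def confusion(seg, truth):
    """Pixel-loop confusion counts: (n_image, n_seg, n_truth, n_inter, n_union)."""
    s = np.asarray(seg, bool)
    t = np.asarray(truth, bool)
    n_image = n_seg = n_truth = n_inter = n_union = 0
    for a, b in zip(s.ravel(), t.ravel()):
        n_image += 1
        n_seg += bool(a)
        n_truth += bool(b)
        n_inter += bool(a and b)
        n_union += bool(a or b)
    return n_image, n_seg, n_truth, n_inter, n_union


def histogram(img):
    """Counting-loop gray histogram."""
    counts = [0] * 256
    for v in np.asarray(img).ravel():
        counts[int(v)] += 1
    return counts


def objective(levels, gamma, weights, memberships, centers, m):
    """Triple-loop histogram-FCM objective."""
    total = 0.0
    for i, v in enumerate(centers):
        for j, xi in enumerate(levels):
            total += gamma[j] * weights[j] * memberships[i][j] ** m * (xi - v) ** 2
    return total


def memberships(levels, centers, m):
    """Loop evaluation of the fuzzy membership update (uniform prior)."""
    C, L = len(centers), len(levels)
    u = [[0.0] * L for _ in range(C)]
    for j, xi in enumerate(levels):
        hits = [i for i, v in enumerate(centers) if abs(xi - v) <= 1e-12]
        if hits:
            u[hits[0]][j] = 1.0
            continue
        inv = [abs(xi - v) ** (-2.0 / (m - 1.0)) for v in centers]
        s = sum(inv)
        for i in range(C):
            u[i][j] = inv[i] / s
    return u


def center_update(levels, gamma, weights, u, m):
    """Loop evaluation of the weighted histogram center update."""
    out = []
    for row in u:
        num = den = 0.0
        for j, xi in enumerate(levels):
            w = gamma[j] * weights[j] * row[j] ** m
            num += w * xi
            den += w
        out.append(num / den)
    return out


def pixel_fcm(x, n_clusters, m=2.0, tol=1e-4, max_iter=300):
    """Minimal per-pixel FCM loop (spread init), returns sorted centers."""
    x = [float(v) for v in np.asarray(x).ravel()]
    lo, hi = min(x), max(x)
    centers = [lo + (hi - lo) * k / (n_clusters - 1) for k in range(n_clusters)]
    j_prev = None
    for _ in range(max_iter):
        u = memberships(x, centers, m)
        gamma = [1.0] * len(x)
        ones = [1.0] * len(x)
        centers = center_update(x, gamma, ones, u, m)
        j = objective(x, gamma, ones, u, centers, m)
        if j_prev is not None and abs(j - j_prev) <= tol:
            break
        j_prev = j
    return sorted(centers)
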