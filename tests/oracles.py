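"""Independent reference implementations used only as test oracles.

Everything here is written as plainly as possible — explicit double loops,
dynamic programming tables, dense searches — and deliberately shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_pr(coords, z, dr):
    """O(n^2) pair histogram: weight 2*Zi*Zj into the bin containing r_ij."""
    coords = np.asarray(coords, float)
    z = np.asarray(z, float)
    n = len(coords)
    contributions = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = math.dist(coords[i], coords[j])
            k = int(math.floor(r / dr))
            contributions[k] = contributions.get(k, 0.0) + 2.0 * z[i] * z[j]
    nb = max(contributions) + 1
    hist = np.zeros(nb)
    for k, w in contributions.items():
        hist[k] = w
    centers = (np.arange(nb) + 0.5) * dr
    return centers, hist


def brute_force_debye(coords, z, q_grid):
    """Double loop over ordered atom pairs, sinc evaluated term by term."""
    coords = np.asarray(coords, float)
    z = np.asarray(z, float)
    n = len(coords)
    out = []
    for q in np.asarray(q_grid, float):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    total += z[i] * z[j]
                    continue
                r = math.dist(coords[i], coords[j])
                x = q * r
                total += z[i] * z[j] * (1.0 if x == 0 else math.sin(x) / x)
        out.append(total)
    return np.array(out)


def brute_force_rg(coords, weights):
    """Weighted RMS distance from the weighted centroid, written longhand."""
    coords = np.asarray(coords, float)
    w = np.asarray(weights, float)
    cx = sum(wi * c[0] for wi, c in zip(w, coords)) / w.sum()
    cy = sum(wi * c[1] for wi, c in zip(w, coords)) / w.sum()
    cz = sum(wi * c[2] for wi, c in zip(w, coords)) / w.sum()
    acc = 0.0
    for wi, c in zip(w, coords):
        acc += wi * ((c[0] - cx) ** 2 + (c[1] - cy) ** 2 + (c[2] - cz) ** 2)
    return math.sqrt(acc / w.sum())


def reference_interp(x_new, x_src, y_src):
    """Piecewise-linear interpolation with zero outside the source range."""
    out = []
    for x in x_new:
        if x < x_src[0] or x > x_src[-1]:
            out.append(0.0)
            continue
        for k in range(len(x_src) - 1):
            if x_src[k] <= x <= x_src[k + 1]:
                t = (x - x_src[k]) / (x_src[k + 1] - x_src[k])
                out.append((1 - t) * y_src[k] + t * y_src[k + 1])
                break
    return np.array(out)


def needleman_wunsch_identities(a: str, b: str,
                                match=1.0, mismatch=0.0, gap=-1.0) -> set[float]:
    """Textbook global alignment DP.

    Returns the set of percent identities (identical columns / alignment
    length * 100) over ALL score-optimal alignments — co-optimal alignments
    can legitimately differ in identity, so a correct implementation must
    land somewhere in this set.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i][j] = max(diag, score[i - 1][j] + gap, score[i][j - 1] + gap)

    results: set[float] = set()

    def walk(i, j, ident, length):
        if i == 0 and j == 0:
            results.add(round(100.0 * ident / length, 9))
            return
        here = score[i][j]
        if i > 0 and j > 0:
            step = match if a[i - 1] == b[j - 1] else mismatch
            if np.isclose(here, score[i - 1][j - 1] + step):
                walk(i - 1, j - 1, ident + (a[i - 1] == b[j - 1]), length + 1)
        if i > 0 and np.isclose(here, score[i - 1][j] + gap):
            walk(i - 1, j, ident, length + 1)
        if j > 0 and np.isclose(here, score[i][j - 1] + gap):
            walk(i, j - 1, ident, length + 1)

    walk(n, m, 0, 0)
    return results


def _quat_to_matrix(quat):
    w, x, y, z = quat / np.linalg.norm(quat)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rotation_search_rmsd(a, b, n_samples=50_000, seed=0):
    """Search over proper rotations (with optimal translation): dense random
    sampling of unit quaternions followed by derivative-free local polish."""
    from scipy.optimize import minimize

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_of(quat):
        diff = ac @ _quat_to_matrix(quat).T - bc
        return math.sqrt((diff ** 2).sum() / len(a))

    rng = np.random.default_rng(seed)
    best_q, best = None, math.inf
    for _ in range(n_samples):
        quat = rng.standard_normal(4)
        val = rmsd_of(quat)
        if val < best:
            best, best_q = val, quat
    res = minimize(rmsd_of, best_q / np.linalg.norm(best_q),
                   method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12,
                                                  "maxiter": 5000})
    return min(best, float(res.fun))


def grid_search_scale(i_model, i_exp, sigma, lo, hi, n=200_001):
    """Dense 1-D search for the scale minimizing the chi-square."""
    grid = np.linspace(lo, hi, n)
    chis = [(((i_exp - c * i_model) / sigma) ** 2).mean() for c in grid]
    k = int(np.argmin(chis))
    return grid[k], chis[k]


def simulate_early_stopping(losses, patience, tol=1e-6):
    """Replay the patience rule on a loss sequence.

    Returns (number of iterations consumed, best index, stopped_early).
    """
    best = math.inf
    best_idx = -1
    streak = 0
    for i, loss in enumerate(losses):
        if loss < best - tol:
            best = loss
            best_idx = i
            streak = 0
        else:
            streak += 1
        if streak >= patience:
            return i + 1, best_idx, True
    return len(losses), best_idx, False


def pearson_by_hand(x, y):
    """Covariance formula written out explicitly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den
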