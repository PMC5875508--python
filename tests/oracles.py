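"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, with plain
loops or exhaustive search, and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_distance_to_set(shape, spacing, targets) -> np.ndarray:
    """Exact Euclidean distance (mm) from every voxel to the nearest target
    voxel, by scanning all pairs."""
    targets = np.asarray(targets, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    out = np.empty(shape)
    for idx in np.ndindex(*shape):
        d = (np.asarray(idx, dtype=float) - targets) * sp
        out[idx] = np.sqrt((d * d).sum(axis=1)).min()
    return out


def brute_force_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance, negative inside, via two all-pairs scans."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    d_to_fg = brute_force_distance_to_set(mask.shape, spacing, fg)
    d_to_bg = brute_force_distance_to_set(mask.shape, spacing, bg)
    return np.where(mask, -d_to_bg, d_to_fg)


def brute_force_dilate(mask: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    fg = np.argwhere(mask)
    d = brute_force_distance_to_set(mask.shape, spacing, fg)
    return d <= margin_mm * (1 + 1e-12)


# ---------------------------------------------------------------------------
# STAPLE EM (straightforwardly coded from the model definition)
# ---------------------------------------------------------------------------


def staple_em_reference(decisions: np.ndarray, n_iter: int = 20, tol: float = 1e-6,
                        init_p: float = 0.9, init_q: float = 0.9,
                        prior: float | None = None):
    """Reference binary STAPLE: ``decisions`` is (raters, voxels) in {0,1}.

    Plain-python E/M loops; returns (w, p, q, iterations).
    """
    D = np.asarray(decisions, dtype=float)
    J, N = D.shape
    pi = float(D.mean()) if prior is None else prior
    p = [init_p] * J
    q = [init_q] * J
    w = np.full(N, pi)
    it = 0
    for it in range(1, n_iter + 1):
        w_new = np.empty(N)
        for i in range(N):
            a = pi
            b = 1.0 - pi
            for j in range(J):
                if D[j, i] == 1:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            w_new[i] = a / (a + b)
        delta = np.abs(w_new - w).max()
        w = w_new
        sw = w.sum()
        swc = (1.0 - w).sum()
        for j in range(J):
            if sw > 0:
                p[j] = float(np.clip((w * D[j]).sum() / sw, 1e-6, 1 - 1e-6))
            if swc > 0:
                q[j] = float(np.clip(((1 - w) * (1 - D[j])).sum() / swc, 1e-6, 1 - 1e-6))
        if delta < tol:
            break
    return w, np.array(p), np.array(q), it


# ---------------------------------------------------------------------------
# exhaustive multi-level Otsu
# ---------------------------------------------------------------------------


def exhaustive_multiotsu_bins(counts: np.ndarray, centers: np.ndarray, classes: int = 4):
    """Globally optimal thresholds by evaluating every bin-boundary
    combination, maximizing between-class variance sum(w_k * mu_k^2).

    All C(n-1, classes-1) cuts are scored; for 4 classes the score table is
    evaluated with one broadcast per leading cut so the full search stays
    fast.  Returns the class-boundary bin indices (class k = bins
    [b_{k-1}, b_k) with b_0 = 0, b_classes = nbins) and the best score.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    n = len(counts)
    total = counts.sum()
    cw = np.concatenate([[0.0], np.cumsum(counts)]) / total
    cm = np.concatenate([[0.0], np.cumsum(counts * centers)]) / total

    def seg(a, b):
        """w*mu^2 contribution of bins [a, b) for array-valued a, b."""
        w = cw[b] - cw[a]
        m = cm[b] - cm[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(w > 0, m * m / np.maximum(w, 1e-300), 0.0)
        return v

    if classes == 2:
        cuts = np.arange(1, n)
        vals = seg(np.zeros_like(cuts), cuts) + seg(cuts, np.full_like(cuts, n))
        k = int(np.argmax(vals))
        return (int(cuts[k]),), float(vals[k])

    if classes != 4:
        from itertools import combinations

        best_val, best = -np.inf, None
        for cut in combinations(range(1, n), classes - 1):
            bounds = (0,) + cut + (n,)
            val = sum(seg(np.array([a]), np.array([b]))[0] for a, b in zip(bounds[:-1], bounds[1:]))
            if val > best_val:
                best_val, best = val, cut
        return best, best_val

    # classes == 4: enumerate (t1, t2, t3) with t2, t3 broadcast per t1
    idx = np.arange(n + 1)
    pair = seg(idx[:, None].repeat(n + 1, 1), idx[None, :].repeat(n + 1, 0).copy())
    best_val, best = -np.inf, None
    for t1 in range(1, n - 1):
        # score(t2, t3) = seg(0,t1) + seg(t1,t2) + seg(t2,t3) + seg(t3,n)
        t2 = np.arange(t1 + 1, n - 0)
        t3 = np.arange(1, n)
        grid = pair[t1, t2][:, None] + pair[np.ix_(t2, t3)] + pair[t3, n][None, :]
        valid = t3[None, :] > t2[:, None]
        grid = np.where(valid, grid, -np.inf)
        k = np.unravel_index(np.argmax(grid), grid.shape)
        val = seg(np.array([0]), np.array([t1]))[0] + grid[k]
        if val > best_val:
            best_val = val
            best = (t1, int(t2[k[0]]), int(t3[k[1]]))
    return best, float(best_val)


# ---------------------------------------------------------------------------
# surface distances (all pairs between boundary voxel sets)
# ---------------------------------------------------------------------------


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    fg = np.argwhere(mask)
    out = []
    for idx in fg:
        for ax in range(3):
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if (n < 0).any() or (n >= np.array(mask.shape)).any() or not mask[tuple(n)]:
                    out.append(idx)
                    break
            else:
                continue
            break
    return np.array(out) if out else np.empty((0, 3), dtype=int)


def brute_force_surface_distances(a: np.ndarray, b: np.ndarray, spacing):
    """(mean_sym, hausdorff) from all-pairs boundary distances."""
    sp = np.asarray(spacing, dtype=float)
    ba = _boundary_voxels(a) * sp
    bb = _boundary_voxels(b) * sp
    d = np.sqrt(((ba[:, None, :] - bb[None, :, :]) ** 2).sum(axis=2))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    mean_sym = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return mean_sym, hd


# ---------------------------------------------------------------------------
# dense joint-histogram mutual information
# ---------------------------------------------------------------------------


def dense_mi_reference(fixed_vals: np.ndarray, moving_vals: np.ndarray, bins: int) -> float:
    """MI (nats) from a dense joint histogram with the same window scheme as
    the package metric: hard binning on fixed, cubic B-spline spreading on
    moving — written from the formula with plain loops over bin offsets."""
    f = np.asarray(fixed_vals, dtype=float).ravel()
    m = np.asarray(moving_vals, dtype=float).ravel()
    fmin, fmax = f.min(), f.max()
    mmin, mmax = m.min(), m.max()
    fw = (fmax - fmin) / bins or 1.0
    mw = (mmax - mmin) / bins or 1.0
    fi = np.minimum(((f - fmin) / fw).astype(int), bins - 1)
    mc = (m - mmin) / mw - 0.5

    def beta3(u):
        au = abs(u)
        if au < 1:
            return (4 - 6 * au**2 + 3 * au**3) / 6
        if au < 2:
            return (2 - au) ** 3 / 6
        return 0.0

    joint = np.zeros((bins, bins))
    for k in range(len(f)):
        base = int(np.floor(mc[k]))
        for off in (-1, 0, 1, 2):
            b = base + off
            w = beta3(mc[k] - b)
            if w > 0:
                joint[fi[k], min(max(b, 0), bins - 1)] += w
    joint /= joint.sum()
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log(joint[i, j] / (pf[i] * pm[j]))
    return mi


def binned_entropy(vals: np.ndarray, bins: int) -> float:
    h, _ = np.histogram(np.asarray(vals).ravel(), bins=bins)
    p = h[h > 0] / h.sum()
    return float(-(p * np.log(p)).sum())
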