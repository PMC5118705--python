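"""Independent straight-line reference implementations used as oracles.

Everything here is deliberately naive: explicit Python loops per pixel,
per window, per offset, with no shared code with the package beyond numpy
and LAPACK primitives.  Definitions (in words):

* gradient: central difference per axis, out-of-range samples by
  replicate/reflect padding;
* orientation at a location: first right singular vector of the matrix of
  window gradient vectors (raster order), sign-fixed to have nonnegative
  dot with the window's summed gradient (ties: x>=0, then y>=0, then
  z>=0); theta = atan2(psi_y, psi_x); phi = atan2(psi_z, hypot(psi_x,
  psi_y)); orientations are defined on the grid extended by the window
  radius (gradient field extended by 2r);
* binning: floor((theta+pi)/(2pi/B)) clamped to B-1; phi analogously over
  [-pi/2, pi/2];
* co-occurrence at an ROI location: symmetric counts of bin pairs at the
  offset displacements within its window; entropy in bits of the
  normalized count matrix (row-major accumulation over nonzero cells).
"""

import math

import numpy as np


def pad_array(arr, width, policy):
    return np.pad(arr, width, mode="edge" if policy == "replicate" else "reflect")


def naive_gradients(img, policy="replicate"):
    """Central differences by explicit per-sample loops."""
    img = np.asarray(img, dtype=np.float64)
    comps = []
    for ax in range(img.ndim):
        p = pad_array(img, [(1, 1) if a == ax else (0, 0) for a in range(img.ndim)], policy)
        out = np.empty(img.shape)
        for idx in np.ndindex(img.shape):
            lo = list(idx)
            hi = list(idx)
            lo[ax] += 0
            hi[ax] += 2
            out[idx] = (p[tuple(hi)] - p[tuple(lo)]) / 2.0
        comps.append(out)
    return comps


def sign_fixed_psi(G):
    """First right singular vector of G, deterministic sign."""
    _, _, vh = np.linalg.svd(G[None], full_matrices=False)
    psi = vh[0, 0, :].copy()
    colsum = G.sum(axis=0)
    dot = float(np.einsum("d,d->", psi, colsum))
    flip = dot < 0
    if dot == 0:
        if psi[0] < 0:
            flip = True
        elif psi[0] == 0:
            if psi[1] < 0:
                flip = True
            elif len(psi) == 3 and psi[1] == 0 and psi[2] < 0:
                flip = True
    if flip:
        psi = -psi
    if not np.any(G != 0):
        psi[:] = 0.0
    return psi + 0.0  # clear negative zeros so atan2(0, 0) == 0


def naive_binned_fields(img, r, B, policy="replicate"):
    """Binned theta (and phi in 3D) on the grid extended by r, by loops."""
    d = img.ndim
    grads = naive_gradients(img, policy)
    gp = [pad_array(g, 2 * r, policy) for g in grads]
    ext_shape = tuple(n + 2 * r for n in img.shape)
    w = 2 * r + 1
    theta_bins = np.empty(ext_shape, dtype=np.int64)
    phi_bins = np.empty(ext_shape, dtype=np.int64) if d == 3 else None
    omega = 2.0 * math.pi / B
    for idx in np.ndindex(ext_shape):
        rows = []
        for delta in np.ndindex((w,) * d):
            loc = tuple(i + dd for i, dd in zip(idx, delta))
            rows.append([g[loc] for g in gp])
        G = np.array(rows, dtype=np.float64)
        psi = sign_fixed_psi(G)
        degenerate = not np.any(G != 0)
        theta = 0.0 if degenerate else math.atan2(psi[1], psi[0])
        tb = int(math.floor((theta + math.pi) / omega))
        theta_bins[idx] = min(max(tb, 0), B - 1)
        if d == 3:
            phi = 0.0 if degenerate else math.atan2(
                psi[2], math.hypot(psi[0], psi[1])
            )
            pb = int(math.floor((phi + math.pi / 2) / (math.pi / B)))
            phi_bins[idx] = min(max(pb, 0), B - 1)
    return (theta_bins,) if d == 2 else (theta_bins, phi_bins)


def window_cooc_counts(binned_ext, corner, w, offsets, B):
    """B x B symmetric pair counts of the window with the given corner."""
    d = binned_ext.ndim
    window = binned_ext[tuple(slice(c, c + w) for c in corner)]
    M = np.zeros((B, B), dtype=np.int64)
    for pos in np.ndindex(window.shape):
        for off in offsets:
            nb = tuple(p + o for p, o in zip(pos, off))
            if all(0 <= n < w for n in nb):
                p, q = int(window[pos]), int(window[nb])
                M[p, q] += 1
                M[q, p] += 1
    return M


def entropy_of_counts(M):
    """Shannon entropy in bits of a count matrix, row-major accumulation."""
    total = M.sum()
    flat = M.ravel()
    nz = flat[flat > 0]
    probs = nz / total
    return float(-(probs * np.log2(probs)).sum())


def naive_entropy_maps(img, mask, r, B, offsets, policy="replicate"):
    """Per-ROI-location entropy maps (one for 2D, two for 3D), by loops."""
    fields = naive_binned_fields(img, r, B, policy)
    w = 2 * r + 1
    out = []
    for binned in fields:
        values = np.full(img.shape, np.nan)
        for idx in np.argwhere(mask):
            M = window_cooc_counts(binned, tuple(idx), w, offsets, B)
            values[tuple(idx)] = entropy_of_counts(M)
        out.append(values)
    return out


def grid_search_orientation_2d(G, step=1e-3):
    """Axis maximizing sum of squared projections, by brute grid search."""
    alphas = np.arange(0.0, math.pi, step)
    u = np.stack([np.cos(alphas), np.sin(alphas)], axis=1)
    energy = ((G @ u.T) ** 2).sum(axis=0)
    best = u[int(np.argmax(energy))]
    return apply_sign_rule(best, G)


def grid_search_orientation_3d(G, coarse=0.01, fine=5e-4):
    """Hemisphere grid search (coarse then refined) for the top axis."""
    M = G.T @ G

    def best_on(az_vals, el_vals):
        az, el = np.meshgrid(az_vals, el_vals, indexing="ij")
        u = np.stack(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)],
            axis=-1,
        ).reshape(-1, 3)
        energy = np.einsum("nd,de,ne->n", u, M, u)
        k = int(np.argmax(energy))
        return u[k], az.ravel()[k], el.ravel()[k]

    _, a0, e0 = best_on(
        np.arange(0.0, math.pi, coarse),
        np.arange(-math.pi / 2, math.pi / 2 + coarse, coarse),
    )
    u, _, _ = best_on(
        np.arange(a0 - 2 * coarse, a0 + 2 * coarse, fine),
        np.arange(e0 - 2 * coarse, e0 + 2 * coarse, fine),
    )
    return apply_sign_rule(u, G)


def apply_sign_rule(u, G):
    u = np.asarray(u, dtype=np.float64)
    dot = float(u @ G.sum(axis=0))
    if dot < 0:
        return -u
    if dot == 0:
        if u[0] < 0:
            return -u
        if u[0] == 0 and u[1] < 0:
            return -u
        if len(u) == 3 and u[0] == 0 and u[1] == 0 and u[2] < 0:
            return -u
    return u


def pairwise_auc(scores, labels, positive):
    """AUC by the all-pairs count, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exact_ranksum_pvalue(a, b):
    """Two-sided rank-sum p by exhaustive enumeration (tie-free data)."""
    from itertools import combinations

    import scipy.stats as st

    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == n + m, "oracle requires tie-free data"
    ranks = st.rankdata(pooled)
    w_obs = ranks[:n].sum()
    all_ranks = range(1, n + m + 1)
    ws = [sum(c) for c in combinations(all_ranks, n)]
    total = len(ws)
    le = sum(1 for w in ws if w <= w_obs)
    ge = sum(1 for w in ws if w >= w_obs)
    return min(1.0, 2.0 * min(le, ge) / total)
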