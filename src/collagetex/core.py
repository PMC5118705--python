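"""Co-occurrence of local anisotropic gradient orientations (CoLlAGe).

The descriptor assigns every ROI location an entropy value measuring how
disordered the *dominant gradient orientations* are in its neighborhood:

1. Per-pixel intensity gradients (central differences).
2. For every location, stack the gradient vectors of its ``(2r+1)``-wide
   window into a matrix ``G`` and take the first right singular vector
   ``psi`` of ``G`` — the direction maximizing the summed squared
   projections of the window's gradients.  In 2D this yields one angle
   ``theta = atan2(psi_y, psi_x)``; in 3D an azimuth ``theta`` and an
   elevation ``phi = atan2(psi_z, hypot(psi_x, psi_y))``.
3. Discretize the angles into ``B`` equal bins, build a ``B x B``
   co-occurrence matrix of binned orientations over each location's window
   (symmetric counts over unit-displacement neighbor pairs), and record its
   Shannon entropy in bits as the CoLlAGe value of that location.

Aggressive, architecturally disordered tissue yields windows whose dominant
orientations vary, spreading co-occurrence mass over many cells and driving
the entropy up; coherent texture concentrates mass and drives it toward 0.

Angle conventions
-----------------
``theta`` lives on the full signed range ``(-pi, pi]`` — folding to
``[0, pi)`` would make the descriptor blind to intensity inversion (a patch
and its complement would collapse).  ``phi`` lives on ``[-pi/2, pi/2]``.
The SVD sign ambiguity is resolved by orienting ``psi`` to have nonnegative
dot product with the window's summed gradient (ties: ``psi_x >= 0``, then
``psi_y >= 0``, then ``psi_z >= 0``).

Boundary handling
-----------------
Gradients use replicate (or reflect) padding; orientations are computed on
the grid extended by the window radius so that co-occurrence windows around
ROI-boundary pixels use real image context where it exists and padded
context only at image borders.  Only ROI locations receive an entropy value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    ConfigError,
    DegenerateInputError,
    EmptyROIError,
    NoPairsError,
    NumericalInputError,
)
from .io_roi import ImageScene, ROIMask

__all__ = [
    "CollageConfig",
    "GradientField",
    "PrincipalOrientation",
    "CooccurrenceMatrix",
    "EntropyMap",
    "OFFSETS_2D",
    "OFFSETS_3D",
    "compute_gradient_field",
    "assemble_gradient_matrix",
    "dominant_orientation_2d",
    "dominant_orientation_3d",
    "discretize_orientation",
    "discretize_elevation",
    "orientation_cooccurrence",
    "cooccurrence_entropy",
    "collage_entropy_map_2d",
    "collage_entropy_maps_3d",
]

#: Unique unit-displacement directions (0/45/90/135 degrees) in 2D.
OFFSETS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

#: The 13 unique unit-displacement directions in 3D (half of the 26
#: neighbors; the other half are the negations and are covered by
#: symmetric counting).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)  # lexicographic canonical half of the 26
)


@dataclass(frozen=True)
class CollageConfig:
    """Tunable parameters of the descriptor.

    Parameters
    ----------
    window_radius
        Half-width ``r`` of the local window; the window spans ``2r+1``
        locations per axis.  Default 2 (a 5x5 neighborhood).
    orientation_bins
        Number ``B`` of equal angular bins for discretizing orientations.
        Default 64 (bin width < 6 degrees for theta).
    hist_bins
        Number ``v`` of bins of the entropy histogram that forms the
        feature vector.  Default 10.
    boundary_policy
        ``"replicate"`` (edge values repeated) or ``"reflect"``.
    cooc_offsets
        Displacement directions defining co-occurring pairs inside a
        window.  ``None`` selects the unit-displacement defaults
        (:data:`OFFSETS_2D` / :data:`OFFSETS_3D`).
    rescale_roi
        If True, intensities are min-max rescaled over the ROI before
        gradient computation.  Default off.
    """

    window_radius: int = 2
    orientation_bins: int = 64
    hist_bins: int = 10
    boundary_policy: str = "replicate"
    cooc_offsets: tuple[tuple[int, ...], ...] | None = None
    rescale_roi: bool = False

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ConfigError("window_radius must be >= 1")
        if self.orientation_bins < 2:
            raise ConfigError("orientation_bins must be >= 2")
        if self.hist_bins < 2:
            raise ConfigError("hist_bins must be >= 2")
        if self.boundary_policy not in ("replicate", "reflect"):
            raise ConfigError(
                f"unknown boundary_policy {self.boundary_policy!r}"
            )
        if self.cooc_offsets is not None and len(self.cooc_offsets) == 0:
            raise ConfigError("cooc_offsets must be nonempty")

    @property
    def window_size(self) -> int:
        """Window width ``2r+1`` per axis (always odd)."""
        return 2 * self.window_radius + 1

    @property
    def omega(self) -> float:
        """Angular discretization factor for theta: ``2*pi / B``."""
        return 2.0 * math.pi / self.orientation_bins

    @property
    def entropy_upper_bound(self) -> float:
        """``log2(B^2)``, the maximum co-occurrence entropy in bits."""
        return 2.0 * math.log2(self.orientation_bins)

    @property
    def entropy_hist_range(self) -> tuple[float, float]:
        """Fixed histogram range shared by all lesions: [0, log2(B^2)]."""
        return (0.0, self.entropy_upper_bound)

    def offsets_for(self, dims: int) -> tuple[tuple[int, ...], ...]:
        if self.cooc_offsets is not None:
            offs = tuple(tuple(int(x) for x in o) for o in self.cooc_offsets)
            for o in offs:
                if len(o) != dims:
                    raise ConfigError(
                        f"offset {o} has {len(o)} components for a "
                        f"{dims}D scene"
                    )
            return offs
        return OFFSETS_2D if dims == 2 else OFFSETS_3D


@dataclass
class GradientField:
    """Per-location intensity gradient components (grid units)."""

    components: tuple[np.ndarray, ...]  # (d/drow, d/dcol[, d/dslice])

    @property
    def dims(self) -> int:
        return len(self.components)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.components[0].shape


@dataclass
class PrincipalOrientation:
    """Dominant orientation of a window's gradient field."""

    psi: np.ndarray  # unit vector (or zeros when degenerate)
    theta: float
    phi: float | None = None
    degenerate: bool = False


@dataclass
class CooccurrenceMatrix:
    """Symmetric B x B counts of co-occurring orientation-bin pairs."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise NoPairsError("co-occurrence matrix is empty")
        return self.counts / total


@dataclass
class EntropyMap:
    """Per-location co-occurrence entropy over an ROI (bits).

    ``values`` is a full-grid array holding NaN outside the ROI;
    ``values[mask]`` are the defined entropies.
    """

    values: np.ndarray
    mask: np.ndarray
    orientation_bins: int
    angle: str = "theta"  # "theta" (azimuth) or "phi" (elevation)

    @property
    def roi_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def upper_bound(self) -> float:
        return 2.0 * math.log2(self.orientation_bins)


# ---------------------------------------------------------------------------
# gradients and windows


def _pad(arr: np.ndarray, width: int, policy: str) -> np.ndarray:
    mode = "edge" if policy == "replicate" else "reflect"
    return np.pad(arr, width, mode=mode)


def compute_gradient_field(
    scene: ImageScene, boundary_policy: str = "replicate"
) -> GradientField:
    """Central-difference gradient per axis, boundaries by padding.

    ``df[i] = (f[i+1] - f[i-1]) / 2`` with the out-of-range samples supplied
    by replicate or reflect padding, so the field is defined on the full
    grid.  Exact on linear ramps at interior points.
    """
    arr = scene.intensities
    if boundary_policy == "reflect" and min(arr.shape) < 3:
        raise DegenerateInputError(
            "reflect boundary policy needs >= 3 samples per axis"
        )
    comps = []
    for axis in range(arr.ndim):
        width = [(0, 0)] * arr.ndim
        width[axis] = (1, 1)
        mode = "edge" if boundary_policy == "replicate" else "reflect"
        p = np.pad(arr, width, mode=mode)
        lo = [slice(None)] * arr.ndim
        hi = [slice(None)] * arr.ndim
        lo[axis] = slice(0, arr.shape[axis])
        hi[axis] = slice(2, arr.shape[axis] + 2)
        comps.append((p[tuple(hi)] - p[tuple(lo)]) / 2.0)
    return GradientField(tuple(comps))


def assemble_gradient_matrix(
    field: GradientField, center: tuple[int, ...], config: CollageConfig
) -> np.ndarray:
    """Stack the window's gradient vectors into an ``(n, d)`` matrix.

    Rows enumerate window locations in raster (C) order; row ``k`` holds the
    gradient vector at the k-th window location.  Windows extending past the
    grid are resolved by the boundary policy.
    """
    r = config.window_radius
    d = field.dims
    if len(center) != d:
        raise ConfigError(f"center {center} does not match field dims {d}")
    padded = [_pad(c, r, config.boundary_policy) for c in field.components]
    sl = tuple(slice(c, c + 2 * r + 1) for c in center)  # padded coords
    cols = [p[sl].ravel() for p in padded]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# dominant orientations


def _sign_fix(psi: np.ndarray, colsum: np.ndarray) -> np.ndarray:
    """Resolve the SVD sign ambiguity deterministically (batched).

    Orient each vector to have nonnegative dot product with the window's
    summed gradient; on exact ties require ``psi_x >= 0``, then
    ``psi_y >= 0``, then ``psi_z >= 0``.
    """
    dot = np.einsum("nd,nd->n", psi, colsum)
    flip = dot < 0
    tie = dot == 0
    flip |= tie & (psi[:, 0] < 0)
    tie &= psi[:, 0] == 0
    flip |= tie & (psi[:, 1] < 0)
    if psi.shape[1] == 3:
        tie &= psi[:, 1] == 0
        flip |= tie & (psi[:, 2] < 0)
    out = psi.copy()
    out[flip] *= -1.0
    return out + 0.0  # clear negative zeros so atan2(0, 0) == 0


def _principal_axes(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First right singular vector per stacked gradient matrix.

    Parameters
    ----------
    stack
        Array ``(N, n, d)`` of N gradient matrices.

    Returns
    -------
    psi : (N, d) sign-fixed unit vectors (zeros where degenerate)
    degenerate : (N,) bool, True where the matrix is all-zero
    """
    if not np.all(np.isfinite(stack)):
        raise NumericalInputError("gradient matrix contains non-finite values")
    degenerate = ~np.any(stack != 0, axis=(1, 2))
    _, _, vh = np.linalg.svd(stack, full_matrices=False)
    psi = vh[:, 0, :]
    psi = _sign_fix(psi, stack.sum(axis=1))
    psi[degenerate] = 0.0
    return psi, degenerate


def dominant_orientation_2d(G: np.ndarray) -> PrincipalOrientation:
    """Dominant gradient orientation of a 2-column gradient matrix.

    ``psi`` is the first right singular vector of ``G`` — the unit direction
    ``u`` maximizing ``sum_k (g_k . u)^2`` — sign-fixed as in
    :func:`_sign_fix`; ``theta = atan2(psi_y, psi_x)`` in ``(-pi, pi]``.
    An all-zero ``G`` is degenerate: ``theta = 0``.
    """
    G = np.asarray(G, dtype=np.float64)
    if G.ndim != 2 or G.shape[1] != 2:
        raise ConfigError(f"expected an (n, 2) matrix, got {G.shape}")
    psi, degen = _principal_axes(G[None])
    psi, degen = psi[0], bool(degen[0])
    theta = 0.0 if degen else float(np.arctan2(psi[1], psi[0]))
    return PrincipalOrientation(psi=psi, theta=theta, degenerate=degen)


def dominant_orientation_3d(G: np.ndarray) -> PrincipalOrientation:
    """Dominant orientation of a 3-column gradient matrix.

    Azimuth ``theta = atan2(psi_y, psi_x)`` in ``(-pi, pi]`` and elevation
    ``phi = atan2(psi_z, hypot(psi_x, psi_y))`` in ``[-pi/2, pi/2]``.  When
    the in-plane part vanishes, ``theta = 0`` by the degenerate-azimuth
    convention of ``atan2(0, 0)``.
    """
    G = np.asarray(G, dtype=np.float64)
    if G.ndim != 2 or G.shape[1] != 3:
        raise ConfigError(f"expected an (n, 3) matrix, got {G.shape}")
    psi, degen = _principal_axes(G[None])
    psi, degen = psi[0], bool(degen[0])
    if degen:
        theta = phi = 0.0
    else:
        theta = float(np.arctan2(psi[1], psi[0]))
        phi = float(np.arctan2(psi[2], np.hypot(psi[0], psi[1])))
    return PrincipalOrientation(psi=psi, theta=theta, phi=phi, degenerate=degen)


# ---------------------------------------------------------------------------
# discretization


def discretize_orientation(theta, config: CollageConfig):
    """Map angles in ``(-pi, pi]`` to bin indices ``0..B-1``.

    ``index = floor((theta + pi) / omega)`` with half-open bins
    ``[left, right)`` and the single point ``theta = pi`` clamped into the
    last bin.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if np.any(theta <= -math.pi - 1e-12) or np.any(theta > math.pi + 1e-12):
        raise ConfigError("theta outside (-pi, pi]")
    B = config.orientation_bins
    idx = np.floor((theta + math.pi) / config.omega).astype(np.int64)
    idx = np.clip(idx, 0, B - 1)
    return idx if idx.ndim else int(idx)


def discretize_elevation(phi, config: CollageConfig):
    """Map elevation angles in ``[-pi/2, pi/2]`` to bin indices ``0..B-1``
    over B equal bins of width ``pi / B`` (top endpoint clamped)."""
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(phi < -math.pi / 2 - 1e-12) or np.any(phi > math.pi / 2 + 1e-12):
        raise ConfigError("phi outside [-pi/2, pi/2]")
    B = config.orientation_bins
    idx = np.floor((phi + math.pi / 2) / (math.pi / B)).astype(np.int64)
    idx = np.clip(idx, 0, B - 1)
    return idx if idx.ndim else int(idx)


# ---------------------------------------------------------------------------
# co-occurrence and entropy


def _pair_codes(window: np.ndarray, offsets, B: int) -> np.ndarray:
    """Flat codes ``p*B + q`` for all symmetric in-window neighbor pairs."""
    codes = []
    nd = window.ndim
    for off in offsets:
        src = []
        dst = []
        ok = True
        for ax in range(nd):
            d = off[ax]
            n = window.shape[ax]
            a, b = max(0, -d), n - max(0, d)
            if a >= b:
                ok = False
                break
            src.append(slice(a, b))
            dst.append(slice(a + d, b + d))
        if not ok:
            continue
        p = window[tuple(src)].ravel()
        q = window[tuple(dst)].ravel()
        codes.append(p.astype(np.int64) * B + q)
        codes.append(q.astype(np.int64) * B + p)
    if not codes:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(codes)


def orientation_cooccurrence(
    binned_window: np.ndarray, config: CollageConfig
) -> CooccurrenceMatrix:
    """B x B co-occurrence counts of binned orientations within a window.

    Every in-window location pair at a displacement in ``cooc_offsets``
    increments both ``counts[p, q]`` and ``counts[q, p]``, so the matrix is
    symmetric by construction and its total equals twice the number of
    unordered neighbor pairs.
    """
    w = np.asarray(binned_window)
    B = config.orientation_bins
    if w.size < 2:
        raise NoPairsError("window spans fewer than 2 locations")
    if w.min() < 0 or w.max() >= B:
        raise ConfigError("bin indices outside [0, B-1]")
    codes = _pair_codes(w, config.offsets_for(w.ndim), B)
    if codes.size == 0:
        raise NoPairsError("no location pairs at the configured offsets")
    counts = np.bincount(codes, minlength=B * B).reshape(B, B)
    return CooccurrenceMatrix(counts)


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Shannon entropy (bits) of the empirical pair-code distribution."""
    _, counts = np.unique(codes, return_counts=True)
    probs = counts / codes.size
    return float(-(probs * np.log2(probs)).sum())


def cooccurrence_entropy(M: CooccurrenceMatrix) -> float:
    """Shannon entropy in bits of a normalized co-occurrence matrix:
    ``-sum m log2 m`` over nonzero cells (``0 log 0 := 0``)."""
    total = M.total
    if total == 0:
        raise NoPairsError("co-occurrence matrix is empty")
    flat = M.counts.ravel()
    nz = flat[flat > 0]
    probs = nz / total
    return float(-(probs * np.log2(probs)).sum())


# ---------------------------------------------------------------------------
# entropy maps


def _binned_orientation_fields(
    scene: ImageScene, config: CollageConfig
) -> list[np.ndarray]:
    """Discretized dominant-orientation fields on the grid extended by the
    window radius.

    Returns one binned field (theta) for 2D scenes, two (theta, phi) for 3D.
    The fields live on ``shape + 2r`` grids: orientation is computed at every
    location within ``r`` of the image so that co-occurrence windows around
    ROI-boundary pixels are fully populated; the gradient field is extended
    by ``2r`` with the boundary policy to feed those windows.
    """
    r = config.window_radius
    w = config.window_size
    grads = compute_gradient_field(scene, config.boundary_policy)
    padded = [_pad(c, 2 * r, config.boundary_policy) for c in grads.components]
    d = scene.dims
    win_shape = (w,) * d
    views = [sliding_window_view(p, win_shape) for p in padded]
    out_shape = views[0].shape[:d]
    n = int(np.prod(out_shape))
    stack = np.stack(
        [v.reshape(n, w**d) for v in views], axis=2
    )  # (n, window, d)
    psi, degen = _principal_axes(stack)
    theta = np.arctan2(psi[:, 1], psi[:, 0])
    theta[degen] = 0.0
    fields = [discretize_orientation(theta, config).reshape(out_shape)]
    if d == 3:
        phi = np.arctan2(psi[:, 2], np.hypot(psi[:, 0], psi[:, 1]))
        phi[degen] = 0.0
        fields.append(discretize_elevation(phi, config).reshape(out_shape))
    return fields


def _maybe_rescale(scene: ImageScene, mask: ROIMask, config: CollageConfig) -> ImageScene:
    if not config.rescale_roi:
        return scene
    vals = scene.intensities[mask.membership]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return scene
    return ImageScene(
        (scene.intensities - lo) / (hi - lo),
        spacing=scene.spacing,
        identifier=scene.identifier,
    )


def _entropy_maps(
    scene: ImageScene, mask: ROIMask, config: CollageConfig
) -> list[EntropyMap]:
    mask.check_aligned(scene)
    scene = _maybe_rescale(scene, mask, config)
    r = config.window_radius
    B = config.orientation_bins
    offsets = config.offsets_for(scene.dims)
    fields = _binned_orientation_fields(scene, config)
    names = ["theta", "phi"]
    maps = []
    coords = np.argwhere(mask.membership)
    for fi, binned in enumerate(fields):
        values = np.full(scene.shape, np.nan)
        for c in coords:
            sl = tuple(slice(ci, ci + 2 * r + 1) for ci in c)
            codes = _pair_codes(binned[sl], offsets, B)
            values[tuple(c)] = _entropy_from_codes(codes)
        maps.append(
            EntropyMap(values, mask.membership.copy(), B, angle=names[fi])
        )
    return maps


def collage_entropy_map_2d(
    scene: ImageScene, mask: ROIMask, config: CollageConfig | None = None
) -> EntropyMap:
    """Per-pixel CoLlAGe entropy map of a 2D scene over an ROI.

    For every ROI pixel: dominant orientations of all pixels in its window
    are discretized into ``B`` bins, their co-occurrence matrix over the
    window is built, and its entropy in bits becomes the pixel's value.
    """
    config = config or CollageConfig()
    if scene.dims != 2:
        raise ConfigError("collage_entropy_map_2d requires a 2D scene")
    if not mask.membership.any():
        raise EmptyROIError("empty ROI")
    return _entropy_maps(scene, mask, config)[0]


def collage_entropy_maps_3d(
    scene: ImageScene, mask: ROIMask, config: CollageConfig | None = None
) -> tuple[EntropyMap, EntropyMap]:
    """Per-voxel CoLlAGe entropy maps of a 3D volume over an ROI.

    Returns two maps from separate co-occurrence matrices: one of the
    discretized azimuth ``theta`` (disorder within the X-Y plane) and one
    of the elevation ``phi`` (disorder out of plane).
    """
    config = config or CollageConfig()
    if scene.dims != 3:
        raise ConfigError("collage_entropy_maps_3d requires a 3D scene")
    if not mask.membership.any():
        raise EmptyROIError("empty ROI")
    m = _entropy_maps(scene, mask, config)
    return m[0], m[1]
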