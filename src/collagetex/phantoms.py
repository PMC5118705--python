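"""Seeded synthetic phantoms with controllable orientation disorder.

The generator emulates the two situations the descriptor is built for:

* checkerboard patch pairs where one patch is the intensity complement of
  the other — gray-level co-occurrence statistics cannot tell them apart,
  signed gradient orientations can;
* lesion-like oriented textures whose *local gradient-orientation
  disorder* differs between classes: a sinusoidal carrier whose
  orientation is jittered per local patch (at the window scale the
  descriptor probes), plus additive noise.  Larger jitter sigma means more
  disordered dominant orientations, hence higher co-occurrence entropy —
  the synthetic analogue of an aggressive, architecturally heterogeneous
  lesion versus a coherent benign one.

Cohorts carry one unique group id per phantom "patient" (with optional
multiple slices per patient) so grouped cross-validation is exercised.
Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .io_roi import ImageScene, ROIMask

__all__ = [
    "PhantomSpec",
    "PhantomCohort",
    "make_checkerboard_pair",
    "make_oriented_texture",
    "make_3d_phantom",
    "elliptical_mask",
    "make_phantom_cohort",
]

MAX_INTENSITY = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one oriented-texture phantom.

    Parameters
    ----------
    shape
        Grid shape, >= 8 per axis; 2 axes for images, 3 for volumes.
    base_orientation_deg
        Carrier orientation (degrees, in-plane).
    jitter_deg
        Standard deviation of the zero-mean per-patch orientation
        perturbation (degrees).  0 gives a coherent texture; 45 a highly
        disordered one.
    elevation_deg, elevation_jitter_deg
        3D only: carrier elevation out of the (row, col) plane and its
        per-patch jitter.
    wavelength
        Carrier wavelength in pixels.
    patch
        Side of the square/cubic patches that share one jittered
        orientation; disorder lives at this scale.
    noise
        Additive Gaussian noise std, in intensity units (0..255 scale).
    seed
        Seed of the phantom's private random generator.
    """

    shape: tuple[int, ...] = (48, 48)
    base_orientation_deg: float = 30.0
    jitter_deg: float = 0.0
    elevation_deg: float = 0.0
    elevation_jitter_deg: float = 0.0
    wavelength: float = 8.0
    patch: int = 6
    noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ConfigError("shape must have 2 or 3 axes")
        if min(self.shape) < 8:
            raise ConfigError("phantom axes must be >= 8")
        if self.jitter_deg < 0 or self.elevation_jitter_deg < 0:
            raise ConfigError("jitter must be >= 0")
        if self.wavelength <= 0 or self.patch < 1:
            raise ConfigError("wavelength and patch must be positive")


def make_checkerboard_pair(
    cell_size: int, shape: tuple[int, int]
) -> tuple[ImageScene, ImageScene]:
    """A checkerboard image and its intensity complement.

    ``P2 = MAX_INTENSITY - P1`` at every pixel, so ``P1 + P2`` is constant.
    ``shape`` must be a multiple of ``cell_size`` per axis.
    """
    if any(s % cell_size for s in shape):
        raise ConfigError("shape must be a multiple of cell_size")
    r, c = np.indices(shape)
    parity = (r // cell_size + c // cell_size) % 2
    p1 = parity.astype(np.float64) * MAX_INTENSITY
    return (
        ImageScene(p1, identifier="checkerboard"),
        ImageScene(MAX_INTENSITY - p1, identifier="checkerboard_complement"),
    )


def _patch_field(shape, patch: int, values: np.ndarray) -> np.ndarray:
    """Upsample a per-patch value grid to the full grid (nearest)."""
    idx = tuple(
        np.minimum(np.arange(n) // patch, values.shape[ax] - 1)
        for ax, n in enumerate(shape)
    )
    return values[np.ix_(*idx)]


def make_oriented_texture(spec: PhantomSpec) -> ImageScene:
    """Sinusoidal carrier with per-patch orientation jitter and noise (2D).

    Intensity at pixel ``(r, c)`` is
    ``A/2 * (1 + sin(2*pi/lambda * (r*sin(alpha) + c*cos(alpha))))`` with
    ``alpha = base + N(0, sigma)`` drawn once per ``patch x patch`` block,
    plus additive Gaussian noise; A = 255.
    """
    if len(spec.shape) != 2:
        raise ConfigError("make_oriented_texture expects a 2D shape")
    rng = np.random.default_rng(spec.seed)
    n_pr = -(-spec.shape[0] // spec.patch)
    n_pc = -(-spec.shape[1] // spec.patch)
    jit = rng.normal(0.0, spec.jitter_deg, size=(n_pr, n_pc))
    alpha = np.deg2rad(spec.base_orientation_deg + _patch_field(spec.shape, spec.patch, jit))
    r, c = np.indices(spec.shape)
    phase = 2.0 * math.pi / spec.wavelength * (
        r * np.sin(alpha) + c * np.cos(alpha)
    )
    img = MAX_INTENSITY / 2.0 * (1.0 + np.sin(phase))
    img += rng.normal(0.0, spec.noise, size=spec.shape)
    return ImageScene(img, identifier=f"oriented_s{spec.seed}")


def make_3d_phantom(spec: PhantomSpec) -> ImageScene:
    """Oriented 3D carrier with per-patch azimuth and elevation jitter.

    The carrier normal has azimuth ``base_orientation + jitter`` in the
    (row, col) plane and elevation ``elevation + elevation_jitter`` toward
    the slice axis; both jitters are drawn once per cubic patch.
    """
    if len(spec.shape) != 3:
        raise ConfigError("make_3d_phantom expects a 3D shape")
    rng = np.random.default_rng(spec.seed)
    n_patches = tuple(-(-n // spec.patch) for n in spec.shape)
    az = np.deg2rad(
        spec.base_orientation_deg
        + _patch_field(
            spec.shape, spec.patch, rng.normal(0.0, spec.jitter_deg, n_patches)
        )
    )
    el = np.deg2rad(
        spec.elevation_deg
        + _patch_field(
            spec.shape,
            spec.patch,
            rng.normal(0.0, spec.elevation_jitter_deg, n_patches),
        )
    )
    r, c, z = np.indices(spec.shape)
    nr = np.cos(el) * np.sin(az)
    nc = np.cos(el) * np.cos(az)
    nz = np.sin(el)
    phase = 2.0 * math.pi / spec.wavelength * (r * nr + c * nc + z * nz)
    img = MAX_INTENSITY / 2.0 * (1.0 + np.sin(phase))
    img += rng.normal(0.0, spec.noise, size=spec.shape)
    return ImageScene(img, identifier=f"oriented3d_s{spec.seed}")


def elliptical_mask(
    shape: tuple[int, ...], group_id: str = "roi", fraction: float = 0.7
) -> ROIMask:
    """Centered elliptical (2D) or ellipsoidal (3D) ROI strictly inside the
    frame; semi-axes are ``fraction/2`` of each axis length."""
    centers = [(n - 1) / 2.0 for n in shape]
    semi = [max(1.0, fraction * n / 2.0) for n in shape]
    grids = np.indices(shape)
    q = sum(
        ((g - c) / s) ** 2 for g, c, s in zip(grids, centers, semi)
    )
    return ROIMask(q <= 1.0, group_id=group_id)


@dataclass
class PhantomCohort:
    """A labeled, grouped collection of phantom scenes.

    ``samples`` is a list of ``(scene, mask, label)`` with label +1 for
    class A (first spec) and -1 for class B; masks carry unique group ids
    per phantom patient.
    """

    samples: list[tuple[ImageScene, ROIMask, int]]
    class_specs: tuple[PhantomSpec, PhantomSpec]
    master_seed: int

    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.samples])


def make_phantom_cohort(
    n_per_class: int,
    class_specs: tuple[PhantomSpec, PhantomSpec],
    master_seed: int = 0,
    slices_per_patient: int = 1,
) -> PhantomCohort:
    """Balanced two-class cohort of oriented-texture phantoms.

    Each of the ``2 * n_per_class`` phantom patients gets a unique group id
    and ``slices_per_patient`` independent scenes drawn from its class
    spec with per-scene seeds spawned from the master seed; masks are
    centered ellipses.  Labels are +1 (first spec) and -1 (second).
    """
    if n_per_class < 2:
        raise ConfigError("n_per_class must be >= 2")
    if len(class_specs) != 2:
        raise ConfigError("exactly two class specs are required")
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(2 * n_per_class * slices_per_patient)
    samples = []
    si = 0
    for ci, (spec, label) in enumerate(zip(class_specs, (+1, -1))):
        for p in range(n_per_class):
            gid = f"patient_{ci}_{p:03d}"
            for s in range(slices_per_patient):
                sc_spec = replace(spec, seed=int(seeds[si] % (2**31)))
                si += 1
                scene = (
                    make_oriented_texture(sc_spec)
                    if len(spec.shape) == 2
                    else make_3d_phantom(sc_spec)
                )
                scene.identifier = f"{gid}_slice{s}"
                mask = elliptical_mask(spec.shape, group_id=gid)
                samples.append((scene, mask, label))
    return PhantomCohort(samples, tuple(class_specs), master_seed)
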