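"""Image/volume and ROI-mask I/O, plus entropy heat-map export.

A scene is a 2D image (PNG/TIFF) or a 3D volume (NIfTI-1) of scalar
intensities on a regular grid; a region of interest (ROI) is a congruent
boolean mask, typically an expert-delineated lesion.  Coordinates are
0-based with axis order (row, column[, slice]) throughout the package.
Multi-channel and multi-frame inputs are rejected rather than silently
reduced: the descriptor operates on single-channel anatomic images.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    EmptyROIError,
    InputError,
    UnsupportedFormatError,
)

__all__ = [
    "ImageScene",
    "ROIMask",
    "load_scene",
    "load_mask",
    "save_scene",
    "save_mask",
    "export_entropy_heatmap",
]

_2D_EXTS = {".png", ".tif", ".tiff"}
_3D_EXTS = {".nii", ".nii.gz"}


@dataclass
class ImageScene:
    """A 2D or 3D grid of scalar intensities with optional physical spacing.

    Parameters
    ----------
    intensities
        Array of finite real intensities, shape ``(rows, cols)`` or
        ``(rows, cols, slices)``.
    spacing
        Physical size of one grid step per axis, in mm.  Defaults to 1.0
        per axis.  Recorded as metadata; gradients are computed in grid
        units (anisotropy is not corrected).
    identifier
        Free-form name used in feature tables.
    """

    intensities: np.ndarray
    spacing: tuple[float, ...] | None = None
    identifier: str = "scene"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim not in (2, 3):
            raise UnsupportedFormatError(
                f"scene must have 2 or 3 spatial axes, got {arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise InputError("scene intensities must all be finite")
        self.intensities = arr
        if self.spacing is None:
            self.spacing = (1.0,) * arr.ndim
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != arr.ndim:
                raise AlignmentError(
                    f"spacing has {len(self.spacing)} entries for a "
                    f"{arr.ndim}D scene"
                )

    @property
    def dims(self) -> int:
        return self.intensities.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class ROIMask:
    """Boolean region-of-interest mask congruent with an :class:`ImageScene`.

    ``group_id`` identifies the phantom/patient the ROI belongs to and drives
    grouped cross-validation (all ROIs sharing a group fall in one fold).
    """

    membership: np.ndarray
    group_id: str = "group"

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.dtype != np.bool_:
            m = m != 0
        if m.ndim not in (2, 3):
            raise UnsupportedFormatError(
                f"mask must have 2 or 3 axes, got {m.ndim}"
            )
        if not m.any():
            raise EmptyROIError("ROI mask has no member locations")
        self.membership = m

    @property
    def shape(self) -> tuple[int, ...]:
        return self.membership.shape

    @property
    def n_members(self) -> int:
        return int(self.membership.sum())

    def check_aligned(self, scene: ImageScene) -> None:
        if self.shape != scene.shape:
            raise AlignmentError(
                f"mask shape {self.shape} does not match scene shape "
                f"{scene.shape}"
            )


def _ext_of(path: str) -> str:
    low = path.lower()
    if low.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(low)[1]


def _read_2d(path: str) -> np.ndarray:
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:  # unreadable / truncated
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        raise UnsupportedFormatError(
            f"{path!r} is multi-channel/multi-frame; provide a single-channel "
            "grayscale image"
        )
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path!r} has {arr.ndim} axes; expected a 2D grayscale image"
        )
    return np.asarray(arr, dtype=np.float64)


def _read_nifti(path: str) -> tuple[np.ndarray, tuple[float, ...]]:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise InputError(f"cannot read NIfTI {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim > 3:
        raise UnsupportedFormatError(
            f"{path!r} has {data.ndim} non-trivial axes; >3 spatial axes "
            "are unsupported"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return np.asarray(data, dtype=np.float64), zooms


def load_scene(path: str, format_hint: str | None = None) -> ImageScene:
    """Read a 2D image (PNG/TIFF) or 3D volume (NIfTI-1) as an ImageScene.

    Intensities are converted to float64 without rescaling.  NIfTI voxel
    spacing is preserved in ``scene.spacing``.

    Parameters
    ----------
    path
        Input file.
    format_hint
        Optional override: ``"png"``, ``"tiff"`` or ``"nifti"``.  By default
        the extension decides.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path!r}")
    ext = _ext_of(path)
    hint = (format_hint or "").lower()
    is_nifti = hint in {"nifti", "nii"} or (not hint and ext in _3D_EXTS)
    identifier = os.path.basename(path)
    for e in (".nii.gz", ".nii", ".png", ".tif", ".tiff"):
        if identifier.lower().endswith(e):
            identifier = identifier[: -len(e)]
            break
    if is_nifti:
        data, zooms = _read_nifti(path)
        return ImageScene(data, spacing=zooms, identifier=identifier)
    if hint in {"png", "tif", "tiff"} or ext in _2D_EXTS:
        return ImageScene(_read_2d(path), identifier=identifier)
    raise UnsupportedFormatError(
        f"unrecognized scene format for {path!r} (expected PNG/TIFF/NIfTI)"
    )


def load_mask(path: str, scene: ImageScene, group_id: str | None = None) -> ROIMask:
    """Read an ROI mask congruent with ``scene``.

    Nonzero locations become members.  ``group_id`` defaults to the value in
    a JSON sidecar (``<path stem>.json`` with key ``"group_id"``) if present,
    otherwise the filename stem.
    """
    raw = load_scene(path)
    if raw.shape != scene.shape:
        raise AlignmentError(
            f"mask shape {raw.shape} does not match scene shape {scene.shape}"
        )
    if group_id is None:
        stem = os.path.splitext(path)[0]
        if stem.lower().endswith(".nii"):
            stem = stem[:-4]
        sidecar = stem + ".json"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                group_id = json.load(fh).get("group_id")
        if group_id is None:
            group_id = os.path.basename(stem)
    return ROIMask(raw.intensities != 0, group_id=group_id)


def save_scene(scene: ImageScene, path: str) -> None:
    """Write a scene to PNG/TIFF (2D) or NIfTI-1 (3D).

    PNG output is clipped/rounded to uint8 if intensities fit [0, 255] and
    are integer-valued; TIFF and NIfTI keep float values exactly.
    """
    ext = _ext_of(path)
    if scene.dims == 2 and ext in _2D_EXTS:
        import imageio.v3 as iio

        arr = scene.intensities
        if ext == ".png":
            rounded = np.rint(arr)
            if not (
                np.allclose(arr, rounded)
                and rounded.min() >= 0
                and rounded.max() <= 255
            ):
                raise UnsupportedFormatError(
                    "PNG output requires integer intensities in [0, 255]; "
                    "use TIFF for float data"
                )
            iio.imwrite(path, rounded.astype(np.uint8))
        else:
            iio.imwrite(path, arr.astype(np.float32))
    elif scene.dims == 3 and ext in _3D_EXTS:
        import nibabel as nib

        affine = np.diag(list(scene.spacing) + [1.0])
        img = nib.Nifti1Image(scene.intensities.astype(np.float32), affine)
        img.header.set_zooms(scene.spacing)
        nib.save(img, path)
    else:
        raise UnsupportedFormatError(
            f"cannot write a {scene.dims}D scene to {path!r}"
        )


def save_mask(mask: ROIMask, path: str, spacing: tuple[float, ...] | None = None) -> None:
    """Write a mask as a 0/1 image or volume, plus a group-id JSON sidecar."""
    scene = ImageScene(
        mask.membership.astype(np.float64),
        spacing=spacing,
        identifier=mask.group_id,
    )
    save_scene(scene, path)
    stem = os.path.splitext(path)[0]
    if stem.lower().endswith(".nii"):
        stem = stem[:-4]
    with open(stem + ".json", "w") as fh:
        json.dump({"group_id": mask.group_id}, fh)


def _bwr_rgb(t: np.ndarray) -> np.ndarray:
    """Blue→white→red colormap sampled continuously; red−blue is 2t−1,
    strictly monotone in t, which makes color ordering testable."""
    t = np.clip(t, 0.0, 1.0)
    r = np.minimum(1.0, 2.0 * t)
    b = np.minimum(1.0, 2.0 * (1.0 - t))
    g = np.minimum(r, b)
    return np.stack([r, g, b], axis=-1)


def export_entropy_heatmap(entropy_map, scene: ImageScene, path: str) -> None:
    """Render an entropy map over its scene and write it as an RGB image.

    Inside the ROI, color scales monotonically from blue (minimum entropy in
    the ROI) to red (maximum); outside, the underlying intensity is shown in
    grayscale.  A degenerate range (all entropies equal) renders the middle
    of the colormap.  For 3D maps the slice with the most ROI voxels is
    rendered.

    Parameters
    ----------
    entropy_map
        An :class:`~collagetex.core.EntropyMap` aligned with ``scene``.
    scene
        The underlying image.
    path
        Output PNG/TIFF path.
    """
    import imageio.v3 as iio

    if entropy_map.values.shape != scene.shape:
        raise AlignmentError(
            f"entropy map shape {entropy_map.values.shape} does not match "
            f"scene shape {scene.shape}"
        )
    vals = entropy_map.values
    roi = entropy_map.mask
    img = scene.intensities
    if scene.dims == 3:
        counts = roi.sum(axis=(0, 1))
        k = int(np.argmax(counts))
        vals, roi, img = vals[:, :, k], roi[:, :, k], img[:, :, k]

    lo, hi = img.min(), img.max()
    gray = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)

    if roi.any():
        eps = vals[roi]
        emin, emax = float(np.min(eps)), float(np.max(eps))
        if emax == emin:
            t = np.full(eps.shape, 0.5)
        else:
            t = (eps - emin) / (emax - emin)
        rgb[roi] = _bwr_rgb(t)

    iio.imwrite(path, np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8))
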