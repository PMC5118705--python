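"""Aggregation of entropy maps into CoLlAGe feature vectors.

The per-ROI feature vector is the histogram of the entropy map: ``v``
equal-width bins over the *fixed* range ``[0, log2(B^2)]`` (not the
per-image min/max, which would destroy comparability across lesions), with
the rightmost bin closed.  Values are frequencies (sum to 1), making the
vector invariant to lesion size.  In 3D the feature is the flattened
``v x v`` joint histogram of the azimuth and elevation entropy maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CollageConfig,
    EntropyMap,
    collage_entropy_map_2d,
    collage_entropy_maps_3d,
)
from .errors import AlignmentError, ConfigError, EmptyROIError
from .io_roi import ImageScene, ROIMask

__all__ = [
    "CollageFeatureVector",
    "entropy_histogram",
    "joint_entropy_histogram",
    "extract_collage_feature_vector",
    "feature_table",
]


@dataclass
class CollageFeatureVector:
    """Entropy-histogram feature vector (classifier input).

    ``values`` has length ``v`` for a 2D map or ``v*v`` (row-major flattened
    joint histogram) for a 3D map pair; when ``normalized`` the entries are
    frequencies summing to 1.
    """

    values: np.ndarray
    bin_edges: np.ndarray
    normalized: bool = True
    joint: bool = False

    def __len__(self) -> int:
        return len(self.values)


def entropy_histogram(
    emap: EntropyMap, config: CollageConfig
) -> CollageFeatureVector:
    """Histogram of an entropy map over the fixed range ``[0, log2(B^2)]``.

    Bins are half-open ``[left, right)`` with the last bin closed (numpy
    convention); frequencies are normalized by the ROI size.
    """
    if config.hist_bins < 2:
        raise ConfigError("hist_bins must be >= 2")
    eps = emap.roi_values
    if eps.size == 0:
        raise EmptyROIError("entropy map has no ROI values")
    counts, edges = np.histogram(
        eps, bins=config.hist_bins, range=emap_range(emap)
    )
    return CollageFeatureVector(counts / eps.size, edges)


def emap_range(emap: EntropyMap) -> tuple[float, float]:
    """The fixed histogram range shared by all lesions at a given B."""
    return (0.0, emap.upper_bound)


def joint_entropy_histogram(
    emap_theta: EntropyMap, emap_phi: EntropyMap, config: CollageConfig
) -> CollageFeatureVector:
    """Flattened ``v x v`` joint histogram of two aligned entropy maps.

    Row-major flattening: bin ``(i, j)`` (theta-bin i, phi-bin j) lands at
    index ``i * v + j``.  Marginalizing over the phi axis recovers
    ``entropy_histogram(emap_theta)``.
    """
    if emap_theta.values.shape != emap_phi.values.shape or not np.array_equal(
        emap_theta.mask, emap_phi.mask
    ):
        raise AlignmentError("entropy maps are not aligned on the same ROI")
    if config.hist_bins < 2:
        raise ConfigError("hist_bins must be >= 2")
    et = emap_theta.roi_values
    ep = emap_phi.roi_values
    counts, xe, _ = np.histogram2d(
        et,
        ep,
        bins=config.hist_bins,
        range=[emap_range(emap_theta), emap_range(emap_phi)],
    )
    return CollageFeatureVector(
        counts.ravel() / et.size, xe, joint=True
    )


def extract_collage_feature_vector(
    scene: ImageScene, mask: ROIMask, config: CollageConfig | None = None
) -> CollageFeatureVector:
    """End-to-end CoLlAGe feature vector of a scene/ROI pair.

    Composes gradients -> dominant orientations -> co-occurrence -> entropy
    map -> histogram.  2D scenes yield the ``v``-bin entropy histogram;
    3D scenes the ``v x v`` joint histogram of the azimuth and elevation
    entropy maps.
    """
    config = config or CollageConfig()
    if scene.dims == 2:
        emap = collage_entropy_map_2d(scene, mask, config)
        return entropy_histogram(emap, config)
    et, ep = collage_entropy_maps_3d(scene, mask, config)
    return joint_entropy_histogram(et, ep, config)


def feature_table(
    samples,
    config: CollageConfig | None = None,
    descriptor: str = "collage",
) -> pd.DataFrame:
    """Feature table with one row per lesion.

    Parameters
    ----------
    samples
        Iterable of ``(scene, mask)`` or ``(scene, mask, label)`` tuples.
    config
        Descriptor configuration.

    Returns
    -------
    DataFrame with columns ``identifier``, ``group_id``, ``descriptor``,
    ``collage_bin_0 .. collage_bin_{n-1}`` and, when labels are supplied,
    ``label``.
    """
    config = config or CollageConfig()
    rows = []
    for item in samples:
        scene, mask, label = (*item, None)[:3]
        fv = extract_collage_feature_vector(scene, mask, config)
        row = {
            "identifier": scene.identifier,
            "group_id": mask.group_id,
            "descriptor": descriptor,
        }
        if label is not None:
            row["label"] = label
        for i, val in enumerate(fv.values):
            row[f"collage_bin_{i}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
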