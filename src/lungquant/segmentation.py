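"""HU-threshold lung segmentation and 3D-filter pneumothorax detection.

The total-lung mask is a rule-based surrogate (threshold + border-connected
air removal + closing + hole filling + largest-component retention); an
externally produced total-lung mask can be supplied instead and is used
verbatim.  Normal lung is the HU window [-950, -450] (inclusive at both
ends).  Pneumothorax is found by smoothing the HU volume with a 3D mean
filter: homogeneous pure-air pockets stay at or below the air threshold after
smoothing while aerated alveoli — a heterogeneous air/tissue mix — are pulled
above it.  Surviving seed voxels are then grown to the full extent of their
raw-air connected component so the reported pocket volume is not eroded by
the filter's boundary blending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, MaskVolume
from .errors import ConfigError, GeometryError, SegmentationError
from .volumetrics import LungPartition

__all__ = [
    "SegmentationParams",
    "segment_total_lung",
    "segment_normal_lung",
    "detect_pneumothorax",
    "derive_partition",
    "segment_all",
]

MIN_LUNG_ML = 100.0  # smaller than this, we did not find a lung


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage (defaults as documented)."""

    normal_hu_window: tuple[float, float] = (-950.0, -450.0)
    air_hu_max: float = -950.0
    smoothing_kernel: int = 5
    min_component_ml: float = 1.0
    closing_radius_mm: float = 5.0
    total_lung_hu_max: float = -250.0

    def __post_init__(self):
        low, high = self.normal_hu_window
        if not low < high:
            raise ConfigError(f"normal_hu_window low {low} must be < high {high}")
        k = self.smoothing_kernel
        if k != 1 and (k < 3 or k % 2 == 0):
            raise ConfigError(f"smoothing_kernel must be odd and >= 3 (or 1), got {k}")
        if self.min_component_ml < 0:
            raise ConfigError("min_component_ml must be >= 0")
        if self.closing_radius_mm <= 0:
            raise ConfigError("closing_radius_mm must be > 0")


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    """Spacing-aware ellipsoidal structuring element of physical radius."""
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    zz, yy, xx = np.ogrid[
        -radii[0] : radii[0] + 1, -radii[1] : radii[1] + 1, -radii[2] : radii[2] + 1
    ]
    return (
        (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    ) <= 1.0


def _drop_small_components(mask: np.ndarray, min_ml: float, voxel_ml: float) -> np.ndarray:
    if min_ml <= 0 or not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes * voxel_ml >= min_ml
    keep[0] = False
    return keep[labels]


def _border_connected(mask: np.ndarray) -> np.ndarray:
    """Subset of ``mask`` connected to any face of the volume."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    border_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_labels.update(np.unique(labels[tuple(sl)]))
    border_labels.discard(0)
    if not border_labels:
        return np.zeros_like(mask)
    lut = np.zeros(n + 1, dtype=bool)
    lut[list(border_labels)] = True
    return lut[labels]


def segment_total_lung(ct: CTVolume, params: SegmentationParams | None = None) -> MaskVolume:
    """Rule-based total-lung surrogate mask.

    Threshold at ``total_lung_hu_max``, remove air connected to the volume
    border (exterior air and the trachea), close with a physical-radius ball,
    fill holes (recovers consolidated contusion interior to the lung), and
    keep every component at least 20% the size of the largest.

    Raises
    ------
    SegmentationError
        If the retained mask is smaller than 100 mL.
    """
    params = params or SegmentationParams()
    hu = ct.voxels
    candidates = hu <= params.total_lung_hu_max
    candidates &= ~_border_connected(candidates)

    # closing with the hole-fill applied while dilated: noise tunnels from the
    # interior to the exterior are sealed by the dilation, so enclosed
    # consolidation and speckled GGO are recovered before eroding back
    structure = _ball_structure(params.closing_radius_mm, ct.spacing)
    dilated = ndimage.binary_dilation(candidates, structure=structure)
    sealed = ndimage.binary_fill_holes(dilated)
    closed = ndimage.binary_erosion(sealed, structure=structure, border_value=1)
    filled = ndimage.binary_fill_holes(closed | candidates)

    labels, n = ndimage.label(filled)
    if n == 0:
        raise SegmentationError("no lung candidate voxels found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = sizes.max()
    keep = sizes >= 0.2 * largest
    keep[0] = False
    mask = keep[labels]

    total_ml = mask.sum() * ct.voxel_volume_ml
    if total_ml < MIN_LUNG_ML:
        raise SegmentationError(
            f"largest lung candidate is {total_ml:.1f} mL (< {MIN_LUNG_ML:.0f} mL); "
            "volume does not appear to contain aerated lung"
        )
    return MaskVolume(mask, ct.spacing)


def segment_normal_lung(
    ct: CTVolume, total: MaskVolume, params: SegmentationParams | None = None
) -> MaskVolume:
    """Voxels within ``total`` whose HU lies in the normal-lung window.

    Window bounds are inclusive; components below ``min_component_ml`` are
    discarded.
    """
    params = params or SegmentationParams()
    total.check_grid(ct)
    low, high = params.normal_hu_window
    mask = total.voxels & (ct.voxels >= low) & (ct.voxels <= high)
    mask = _drop_small_components(mask, params.min_component_ml, ct.voxel_volume_ml)
    return MaskVolume(mask, ct.spacing)


def detect_pneumothorax(
    ct: CTVolume, total: MaskVolume, params: SegmentationParams | None = None
) -> MaskVolume:
    """Pleural air pockets inside ``total`` via 3D mean-filter candidate search.

    A candidate voxel is one whose mean-filtered HU is at or below
    ``air_hu_max``.  Candidates are grown to their full raw-air connected
    component, components below ``min_component_ml`` are dropped, and any
    component connected to the air column touching the superior volume face
    (trachea / exterior) is excluded.
    """
    params = params or SegmentationParams()
    total.check_grid(ct)
    hu = ct.voxels
    if params.smoothing_kernel > 1:
        filtered = ndimage.uniform_filter(hu, size=params.smoothing_kernel)
    else:
        filtered = hu
    seeds = total.voxels & (filtered <= params.air_hu_max)
    if not seeds.any():
        return MaskVolume(np.zeros_like(seeds), ct.spacing)

    # grow seeds to the full raw-air pocket (volume-true delineation)
    air_all = hu <= params.air_hu_max
    labels, n = ndimage.label(air_all)
    seed_labels = np.unique(labels[seeds])
    seed_labels = seed_labels[seed_labels > 0]

    # air connected to the superior face is airway/exterior, not pneumothorax
    top_labels = np.unique(labels[0])
    excluded = set(top_labels[top_labels > 0])

    lut = np.zeros(n + 1, dtype=bool)
    for lab in seed_labels:
        if lab not in excluded:
            lut[lab] = True
    detected = lut[labels] & total.voxels
    detected = _drop_small_components(detected, params.min_component_ml, ct.voxel_volume_ml)
    return MaskVolume(detected, ct.spacing)


def derive_partition(
    ct: CTVolume, total: MaskVolume, normal: MaskVolume, ptx: MaskVolume
) -> LungPartition:
    """Combine masks into the disjoint (normal, contusion, pneumothorax) partition.

    ``normal`` and ``ptx`` are intersected with ``total``; pneumothorax wins
    where it overlaps normal lung; contusion is the remainder of ``total``.
    """
    for m in (total, normal, ptx):
        m.check_grid(ct)
    t = total.voxels
    p = ptx.voxels & t
    n = normal.voxels & t & ~p
    c = t & ~n & ~p
    spacing = ct.spacing
    return LungPartition(
        total=MaskVolume(t, spacing),
        normal=MaskVolume(n, spacing),
        contusion=MaskVolume(c, spacing),
        pneumothorax=MaskVolume(p, spacing),
    )


def segment_all(
    ct: CTVolume,
    params: SegmentationParams | None = None,
    total: MaskVolume | None = None,
) -> LungPartition:
    """End-to-end segmentation: total (or supplied mask), normal, pneumothorax."""
    params = params or SegmentationParams()
    if total is None:
        total = segment_total_lung(ct, params)
    else:
        total.check_grid(ct)
    normal = segment_normal_lung(ct, total, params)
    ptx = detect_pneumothorax(ct, total, params)
    return derive_partition(ct, total, normal, ptx)
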