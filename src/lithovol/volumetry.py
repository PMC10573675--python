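"""Density-window segmentation and voxel volumetry of renal stones on CT.

A stone on non-contrast CT is a bright (high Hounsfield unit) object against
soft tissue and urine.  The measurement procedure implemented here is the one
an operator performs interactively: choose an inclusive HU interval (the
*density window*) that visually fits the stone, threshold the volume, label
the resulting connected components, and report each component's voxel count
and physical volume (``voxel_count x sx*sy*sz`` mm^3), together with HU
statistics and the maximum 3D diameter.

The classical geometric stone-burden estimators (sphere, ellipsoid,
Ackermann, cumulative diameter, surface area) live in
:mod:`lithovol.estimators` and are re-exported from the package root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "HUVolume",
    "DensityWindow",
    "StoneSegment",
    "SegmentationResult",
    "threshold_mask",
    "label_components",
    "measure_segment",
    "segment_stones",
    "max_pairwise_diameter",
]

#: homogeneity cut-off: a segment whose internal HU range exceeds this many
#: Hounsfield units is flagged heterogeneous (mixed-composition stone).
DEFAULT_HOMOGENEITY_HU = 600.0

# convex-hull prefilter kicks in above this component size; below it the
# exact O(k^2) pairwise scan is cheap enough.
_HULL_PREFILTER_VOXELS = 10_000


@dataclass(frozen=True)
class HUVolume:
    """A 3D grid of Hounsfield units with physical voxel spacing.

    Axis order is ``(slice, row, col)``; ``spacing`` gives the physical edge
    lengths of one voxel along those axes, in mm.  Values are assumed to be
    calibrated HU (DICOM rescale already applied).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.size == 0:
            raise ValueError("voxel grid must be a non-empty 3D array")
        if not np.all(np.isfinite(vox)):
            raise ValueError("HU values must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class DensityWindow:
    """Inclusive HU interval selected by the operator.

    This is the single tunable of the measurement: every voxel with
    ``hu_low <= HU <= hu_high`` belongs to the stone candidate mask.
    """

    hu_low: float
    hu_high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.hu_low) and np.isfinite(self.hu_high)):
            raise ValueError("window bounds must be finite")
        if self.hu_low > self.hu_high:
            raise ValueError(
                f"hu_low ({self.hu_low}) must not exceed hu_high ({self.hu_high})"
            )

    def contains(self, other: "DensityWindow") -> bool:
        return self.hu_low <= other.hu_low and other.hu_high <= self.hu_high


@dataclass(frozen=True)
class StoneSegment:
    """One labeled connected component and its measurements."""

    label: int
    voxel_count: int
    volume_mm3: float
    hu_mean: float
    hu_min: float
    hu_max: float
    max_diameter_mm: float
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    homogeneity_threshold_hu: float = DEFAULT_HOMOGENEITY_HU

    @property
    def hu_range(self) -> float:
        return self.hu_max - self.hu_min

    @property
    def is_heterogeneous(self) -> bool:
        return self.hu_range > self.homogeneity_threshold_hu


@dataclass(frozen=True)
class SegmentationResult:
    """All stone components found in a volume under one density window."""

    segments: tuple[StoneSegment, ...]
    window: DensityWindow
    connectivity: int
    min_voxels: int
    voxel_volume_mm3: float

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(s.volume_mm3 for s in self.segments))

    @property
    def total_voxel_count(self) -> int:
        return int(sum(s.voxel_count for s in self.segments))

    @property
    def n_stones(self) -> int:
        return len(self.segments)

    def to_records(self) -> list[dict]:
        return [
            {
                "label": s.label,
                "voxel_count": s.voxel_count,
                "volume_mm3": s.volume_mm3,
                "hu_mean": s.hu_mean,
                "hu_min": s.hu_min,
                "hu_max": s.hu_max,
                "hu_range": s.hu_range,
                "is_heterogeneous": s.is_heterogeneous,
                "max_diameter_mm": s.max_diameter_mm,
            }
            for s in self.segments
        ]


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_mask(vol: HUVolume, win: DensityWindow) -> np.ndarray:
    """Binary mask of voxels inside the density window (inclusive ends).

    A window that excludes every voxel yields a valid all-zero mask.
    """
    vox = vol.voxels
    return (vox >= win.hu_low) & (vox <= win.hu_high)


def label_components(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a binary mask.

    ``connectivity`` follows the 3D neighbourhood convention: 6 (faces),
    18 (faces+edges) or 26 (faces+edges+corners).  Returns ``(labelmap,
    sizes)`` where ``sizes[i]`` is the voxel count of label ``i + 1``;
    background is 0.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labelmap, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labelmap.ravel(), minlength=n + 1)[1:]
    return labelmap, sizes


def max_pairwise_diameter(coords_mm: np.ndarray) -> float:
    """Largest Euclidean distance between any two points (mm).

    Exact for any input; for large clouds the convex hull is computed first,
    which preserves the maximum pairwise distance (both extremes are hull
    vertices).
    """
    coords_mm = np.asarray(coords_mm, dtype=float)
    if coords_mm.shape[0] <= 1:
        return 0.0
    pts = coords_mm
    if pts.shape[0] > _HULL_PREFILTER_VOXELS:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            # degenerate (coplanar/collinear) clouds: fall through to exact scan
            pass
    return float(pdist(pts).max())


def measure_segment(
    labelmap: np.ndarray,
    label: int,
    vol: HUVolume,
    homogeneity_threshold: float = DEFAULT_HOMOGENEITY_HU,
    compute_diameter: bool = True,
) -> StoneSegment:
    """Measure one labeled component: volume, HU stats, max diameter.

    ``compute_diameter=False`` skips the O(k^2) maximum-diameter scan
    (reported as NaN), useful in bulk simulations that only need volumes.
    """
    idx = np.nonzero(labelmap == label)
    count = idx[0].size
    if count == 0:
        raise ValueError(f"label {label} not present in labelmap")
    hu = vol.voxels[idx].astype(float)
    spacing = np.asarray(vol.spacing)
    if compute_diameter:
        diameter = max_pairwise_diameter(np.column_stack(idx) * spacing)
    else:
        diameter = float("nan")
    bbox = tuple((int(ax.min()), int(ax.max())) for ax in idx)
    return StoneSegment(
        label=int(label),
        voxel_count=int(count),
        volume_mm3=float(count * vol.voxel_volume_mm3),
        hu_mean=float(hu.mean()),
        hu_min=float(hu.min()),
        hu_max=float(hu.max()),
        max_diameter_mm=diameter,
        bounding_box=bbox,  # type: ignore[arg-type]
        homogeneity_threshold_hu=float(homogeneity_threshold),
    )


def segment_stones(
    vol: HUVolume,
    win: DensityWindow,
    connectivity: int = 26,
    min_voxels: int = 1,
    homogeneity_threshold: float = DEFAULT_HOMOGENEITY_HU,
    compute_diameter: bool = True,
) -> SegmentationResult:
    """Full pipeline: threshold -> label -> size-filter -> measure.

    Components smaller than ``min_voxels`` are discarded and excluded from
    the total.  Segments are returned sorted by volume, largest first.
    Deterministic for fixed inputs.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = threshold_mask(vol, win)
    labelmap, sizes = label_components(mask, connectivity=connectivity)
    segments = [
        measure_segment(labelmap, lab, vol, homogeneity_threshold, compute_diameter)
        for lab in np.flatnonzero(sizes >= min_voxels) + 1
    ]
    segments.sort(key=lambda s: (-s.volume_mm3, s.label))
    return SegmentationResult(
        segments=tuple(segments),
        window=win,
        connectivity=connectivity,
        min_voxels=min_voxels,
        voxel_volume_mm3=vol.voxel_volume_mm3,
    )
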