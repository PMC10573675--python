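"""Synthetic CT phantoms with analytic ground truth, plus observer models.

The phantom generator produces small HU volumes that mimic what matters
for threshold volumetry of renal stones on non-contrast CT:

* stone HU far above soft tissue (several hundred HU of contrast),
* partial-volume blur at stone edges (Gaussian blur surrogate, the main
  source of threshold-dependent volume error),
* optional internal HU heterogeneity (dense core, less dense shell),
* single, multiple, and branched "staghorn-like" shapes (a pelvis
  ellipsoid with calyceal branches).

True volumes are analytic for spheres and ellipsoids (pi/6 * l*w*h over
axis diameters) and come from a fine-grid voxelization oracle (spacing/8)
for staghorn unions, so segmentation accuracy can be judged against exact
ground truth.  The observer model re-measures phantoms with a jittered
lower HU threshold — the one control an operator actually chooses —
producing the long-format measurement tables the agreement layer consumes.

All randomness flows through explicit seeds: identical seeds give
bit-identical volumes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .agreement import MeasurementTable
from .volumetry import DensityWindow, HUVolume, segment_stones

__all__ = [
    "StoneSpec",
    "PhantomSpec",
    "ObserverModel",
    "Phantom",
    "simulate_phantom",
    "simulate_study",
    "staghorn_components",
]

#: refinement factor of the voxelization oracle for non-analytic shapes
_ORACLE_REFINE = 8

# staghorn template (in units of the size parameter): one pelvis ellipsoid
# plus three calyceal branches at fixed angles.  Axes are full diameters.
_STAGHORN_PELVIS_AXES = (1.6, 1.2, 1.0)
_STAGHORN_BRANCH_AXES = (1.5, 0.55, 0.55)
_STAGHORN_BRANCH_DIRS = (
    (0.766, 0.643, 0.0),    # upper calyx
    (0.766, -0.643, 0.0),   # lower calyx
    (0.766, 0.0, 0.643),    # middle calyx, out of plane
)
_STAGHORN_BRANCH_OFFSET = 0.9


def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Intrinsic z-y-x Euler rotation matrix from angles in degrees."""
    az, ay, ax = (math.radians(a) for a in angles_deg)
    cz, sz = math.cos(az), math.sin(az)
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class StoneSpec:
    """One synthetic stone.

    ``axes_mm`` are full axis lengths (diameters); a sphere is an ellipsoid
    with equal axes.  ``shape="staghorn"`` expands into a union of four
    overlapping ellipsoids (pelvis + three branches) scaled by
    ``axes_mm[0]`` as the size parameter.  ``hu_shell`` (if given) makes the
    outer radial 40% of the stone take a different HU than the core,
    emulating mixed-composition stones.
    """

    shape: str
    center_mm: tuple[float, float, float]
    axes_mm: tuple[float, float, float]
    hu_core: float
    hu_shell: float | None = None
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_start: float = 0.6

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "staghorn"):
            raise ValueError(f"unknown stone shape {self.shape!r}")
        if any(a <= 0 for a in self.axes_mm):
            raise ValueError("axes must be positive")
        if self.shape == "sphere" and len(set(self.axes_mm)) != 1:
            raise ValueError("sphere requires equal axes")

    def components(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Expand to ellipsoid components: (center, semi_axes, rotation)."""
        rot = _rotation_matrix(self.rotation_deg)
        center = np.asarray(self.center_mm, dtype=float)
        if self.shape in ("sphere", "ellipsoid"):
            return [(center, np.asarray(self.axes_mm) / 2.0, rot)]
        return staghorn_components(center, self.axes_mm[0], rot)

    @property
    def extent_mm(self) -> float:
        """Conservative radius of a ball containing the stone."""
        if self.shape == "staghorn":
            s = self.axes_mm[0]
            return (_STAGHORN_BRANCH_OFFSET + _STAGHORN_BRANCH_AXES[0] / 2.0) * s
        return max(self.axes_mm) / 2.0

    def analytic_volume_mm3(self) -> float | None:
        """Closed-form volume, or None when only the oracle applies."""
        if self.shape in ("sphere", "ellipsoid"):
            l, w, h = self.axes_mm
            return math.pi / 6.0 * l * w * h
        return None


def staghorn_components(
    center: np.ndarray, size: float, rot: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pelvis ellipsoid plus three branch ellipsoids, scaled by ``size``."""
    comps = [(center, np.asarray(_STAGHORN_PELVIS_AXES) * size / 2.0, rot)]
    for d in _STAGHORN_BRANCH_DIRS:
        direction = rot @ np.asarray(d)
        c = center + _STAGHORN_BRANCH_OFFSET * size * direction
        # branch frame: long axis along the branch direction
        b_rot = _align_x_to(direction)
        comps.append((c, np.asarray(_STAGHORN_BRANCH_AXES) * size / 2.0, b_rot))
    return comps


def _align_x_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the x axis to ``direction`` (unit vector)."""
    x = np.array([1.0, 0.0, 0.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(x, d)
    c = float(x @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic HU volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu_mean: float = 40.0
    background_hu_sd: float = 15.0
    stones: tuple[StoneSpec, ...] = ()
    blur_sigma_mm: float = 0.7
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stones", tuple(self.stones))
        for st in self.stones:
            lo = min(st.hu_core, st.hu_core if st.hu_shell is None else st.hu_shell)
            if lo <= self.background_hu_mean + 300:
                raise ValueError(
                    "stone HU must exceed background by more than 300 HU "
                    "(otherwise it is not a stone-like phantom)"
                )


@dataclass(frozen=True)
class Phantom:
    """A simulated volume with its per-stone true volumes (mm^3)."""

    volume: HUVolume
    true_volumes_mm3: tuple[float, ...]
    spec: PhantomSpec

    @property
    def total_true_volume_mm3(self) -> float:
        return float(sum(self.true_volumes_mm3))


def _radial_field(
    stone: StoneSpec, coords: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> np.ndarray:
    """Normalized radial coordinate of each point w.r.t. the stone.

    <= 1 inside; for unions the minimum over components is taken.
    """
    zz, yy, xx = coords
    pts = np.stack([zz, yy, xx], axis=-1)
    rho = None
    for center, semi, rot in stone.components():
        local = (pts - center) @ rot  # = rot.T applied from the left
        q = np.sqrt(((local / semi) ** 2).sum(axis=-1))
        rho = q if rho is None else np.minimum(rho, q)
    return rho


def _true_volume(stone: StoneSpec, spacing: tuple[float, float, float]) -> float:
    analytic = stone.analytic_volume_mm3()
    if analytic is not None:
        return analytic
    # fine-grid voxelization oracle over the stone's bounding ball,
    # processed slab by slab to keep memory flat
    h = min(spacing) / _ORACLE_REFINE
    r = stone.extent_mm + 2 * h
    center = np.asarray(stone.center_mm)
    axes = [np.arange(c - r, c + r + h, h) for c in center]
    yy, xx = np.meshgrid(axes[1], axes[2], indexing="ij", sparse=False)
    comps = stone.components()
    count = 0
    zz = np.empty_like(yy)
    for z in axes[0]:
        zz.fill(z)
        pts = np.stack([zz, yy, xx], axis=-1)
        rho = None
        for c, semi, rot in comps:
            local = (pts - c) @ rot
            q2 = ((local / semi) ** 2).sum(axis=-1)
            rho = q2 if rho is None else np.minimum(rho, q2)
        count += int((rho <= 1.0).sum())
    return float(count * h**3)


def simulate_phantom(spec: PhantomSpec, compute_truth: bool = True) -> Phantom:
    """Render a phantom volume; deterministic for a fixed seed.

    True volumes come from geometry alone and are independent of the noise
    realization.  ``compute_truth=False`` skips the fine-grid voxelization
    oracle for non-analytic shapes (their truth is reported as NaN), for
    bulk simulations that only need the rendered volume.  Raises if any
    stone extends beyond the grid.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing
    for st in spec.stones:
        c = np.asarray(st.center_mm)
        if np.any(c - st.extent_mm < 0) or np.any(c + st.extent_mm > extent):
            raise ValueError(
                f"stone at {st.center_mm} (extent {st.extent_mm:.1f} mm) "
                f"exceeds grid physical extent {tuple(extent)}"
            )

    img = rng.normal(spec.background_hu_mean, spec.background_hu_sd, size=shape)
    if spec.stones:
        axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=False)
        for st in spec.stones:
            rho = _radial_field(st, (zz, yy, xx))
            inside = rho <= 1.0
            hu = np.full(shape, st.hu_core)
            if st.hu_shell is not None:
                hu[rho > st.shell_start] = st.hu_shell
            img[inside] = hu[inside]

    if spec.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_mm / spacing)
    if spec.noise_sd_hu > 0:
        img += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    vol = HUVolume(voxels=img, spacing=tuple(spacing))
    if compute_truth:
        truth = tuple(_true_volume(st, tuple(spacing)) for st in spec.stones)
    else:
        truth = tuple(
            st.analytic_volume_mm3() if st.analytic_volume_mm3() is not None
            else float("nan")
            for st in spec.stones
        )
    return Phantom(volume=vol, true_volumes_mm3=truth, spec=spec)


@dataclass(frozen=True)
class ObserverModel:
    """An observer who re-measures stones with a jittered lower threshold.

    The lower HU bound of the density window is the one control the
    operator chooses per measurement; it is drawn fresh for every replicate
    as Normal(hu_low_mean, hu_low_sd).  The upper bound is fixed and
    generous.  ``hu_low_sd`` is the repeatability knob: 0 gives a perfectly
    repeatable observer, larger values give larger replicate CVs.
    """

    hu_low_mean: float = 300.0
    hu_low_sd: float = 25.0
    hu_high: float = 4000.0
    replicates: int = 5

    def __post_init__(self) -> None:
        if self.hu_low_sd < 0:
            raise ValueError("hu_low_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


_MAX_WINDOW_RETRIES = 20


def _draw_window(model: ObserverModel, rng: np.random.Generator) -> DensityWindow:
    for _ in range(_MAX_WINDOW_RETRIES):
        lo = float(rng.normal(model.hu_low_mean, model.hu_low_sd))
        if lo <= model.hu_high:
            return DensityWindow(lo, model.hu_high)
        warnings.warn("degenerate window drawn (low > high); redrawing", stacklevel=2)
    raise RuntimeError("could not draw a valid density window; check observer model")


def simulate_study(
    phantoms: list[Phantom],
    observers: list[ObserverModel],
    seed: int = 0,
    min_voxels: int = 1,
    case_metadata: pd.DataFrame | None = None,
) -> MeasurementTable:
    """Simulate observers repeatedly measuring every phantom.

    For each (case, observer, replicate) a lower threshold is drawn from
    the observer's model, the phantom is segmented, and the total segmented
    volume is recorded.  Row count is cases x observers x replicates (with
    per-observer replicate counts).  ``case_metadata`` (indexed by 1-based
    case number) is joined onto the output table if provided.
    """
    if not phantoms:
        raise ValueError("need at least one phantom")
    rng = np.random.default_rng(seed)
    rows = []
    for case_idx, ph in enumerate(phantoms, start=1):
        for obs_idx, model in enumerate(observers, start=1):
            for rep in range(1, model.replicates + 1):
                win = _draw_window(model, rng)
                result = segment_stones(
                    ph.volume, win, min_voxels=min_voxels, compute_diameter=False
                )
                rows.append(
                    {
                        "case_id": case_idx,
                        "observer_id": f"observer_{obs_idx}",
                        "replicate": rep,
                        "volume_mm3": result.total_volume_mm3,
                    }
                )
    df = pd.DataFrame(rows)
    if case_metadata is not None:
        df = df.merge(case_metadata, left_on="case_id", right_index=True, how="left")
    return MeasurementTable(df)


# ---------------------------------------------------------------------------
# JSON round-trip for specs
# ---------------------------------------------------------------------------


def phantom_spec_from_json(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        doc = json.load(fh)
    stones = tuple(
        StoneSpec(
            shape=s["shape"],
            center_mm=tuple(s["center_mm"]),
            axes_mm=tuple(s["axes_mm"]),
            hu_core=s["hu_core"],
            hu_shell=s.get("hu_shell"),
            rotation_deg=tuple(s.get("rotation_deg", (0.0, 0.0, 0.0))),
        )
        for s in doc.get("stones", [])
    )
    return PhantomSpec(
        grid_shape=tuple(doc.get("grid_shape", (48, 48, 48))),
        spacing_mm=tuple(doc.get("spacing_mm", (1.0, 1.0, 1.0))),
        background_hu_mean=doc.get("background_hu_mean", 40.0),
        background_hu_sd=doc.get("background_hu_sd", 15.0),
        stones=stones,
        blur_sigma_mm=doc.get("blur_sigma_mm", 0.7),
        noise_sd_hu=doc.get("noise_sd_hu", 10.0),
        seed=doc.get("seed", 0),
    )
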