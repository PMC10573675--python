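"""Cohort-like phantom rosters for simulated reliability studies.

:func:`default_study_phantoms` draws a set of synthetic cases whose mix of
shapes mirrors a typical renal-stone cohort: about 30% complex
(staghorn-like branched) stones, roughly half multiple stones, roughly
half heterogeneous (mixed-composition) stones, stone densities around
700-1500 HU and per-case total volumes spanning roughly two orders of
magnitude (tens to thousands of mm^3).  Each case carries the metadata
the subgroup analyses need (complexity, homogeneity, multiplicity,
location); location is metadata only — it is an anatomical attribute, not
something computable from a stone mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import Phantom, PhantomSpec, StoneSpec, simulate_phantom

__all__ = ["default_study_phantoms"]

_GRID = (48, 48, 48)
_SPACING = (1.0, 1.0, 1.0)
_CENTER = (23.5, 23.5, 23.5)

#: cohort mix: fraction of complex (branched) and heterogeneous cases,
#: and of multiple-stone cases among the non-complex ones
P_COMPLEX = 0.3
P_HETEROGENEOUS = 0.46
P_MULTIPLE = 0.5


def _random_rotation(rng: np.random.Generator) -> tuple[float, float, float]:
    return tuple(rng.uniform(0.0, 360.0, size=3))


def default_study_phantoms(
    n_cases: int = 50, seed: int = 0, compute_truth: bool = True
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate ``n_cases`` phantoms plus their per-case metadata.

    Returns ``(phantoms, metadata)`` with metadata indexed by 1-based case
    number and columns ``is_complex``, ``is_homogeneous``, ``is_multiple``,
    ``location``.  Deterministic for a fixed seed.  ``compute_truth=False``
    skips the fine-grid truth oracle for branched stones.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    meta_rows = []
    for case in range(1, n_cases + 1):
        is_complex = bool(rng.random() < P_COMPLEX)
        is_heterogeneous = bool(rng.random() < P_HETEROGENEOUS)
        hu_core = float(rng.uniform(800.0, 1500.0))
        hu_shell = hu_core - float(rng.uniform(650.0, 750.0)) if is_heterogeneous else None
        if hu_shell is not None:
            hu_shell = max(hu_shell, 400.0)
        stones: list[StoneSpec]
        if is_complex:
            size = float(rng.uniform(5.0, 11.0))
            stones = [
                StoneSpec(
                    "staghorn",
                    _CENTER,
                    (size, size, size),
                    hu_core,
                    hu_shell=hu_shell,
                    rotation_deg=_random_rotation(rng),
                )
            ]
            is_multiple = False
        else:
            is_multiple = bool(rng.random() < P_MULTIPLE)
            n_stones = int(rng.integers(2, 4)) if is_multiple else 1
            stones = []
            # spread multiple stones along the main diagonal, well separated
            offsets = np.linspace(-10.0, 10.0, n_stones)
            for k in range(n_stones):
                axes = tuple(float(rng.uniform(5.0, 14.0)) for _ in range(3))
                if rng.random() < 0.4:  # some near-spherical stones
                    axes = (axes[0],) * 3
                center = tuple(c + offsets[k] for c in _CENTER)
                stones.append(
                    StoneSpec(
                        "sphere" if len(set(axes)) == 1 else "ellipsoid",
                        center,
                        axes,
                        hu_core,
                        hu_shell=hu_shell,
                        rotation_deg=_random_rotation(rng),
                    )
                )
        spec = PhantomSpec(
            grid_shape=_GRID,
            spacing_mm=_SPACING,
            stones=tuple(stones),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        phantoms.append(simulate_phantom(spec, compute_truth=compute_truth))
        meta_rows.append(
            {
                "case_id": case,
                "is_complex": is_complex,
                "is_homogeneous": not is_heterogeneous,
                "is_multiple": is_multiple,
                "location": str(rng.choice(["pelvis", "calyx", "other"])),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("case_id")
    return phantoms, meta
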