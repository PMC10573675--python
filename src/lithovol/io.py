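"""Readers and writers for CT volumes, segmentation results and reports.

DICOM series are read with pydicom (rescale slope/intercept applied to get
calibrated HU, slices sorted along the stack normal); NIfTI-1 volumes are
read and written with nibabel (values assumed to be HU already).
Segmentation results round-trip as JSON and CSV; agreement reports as JSON
and Markdown.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementReport
from .volumetry import HUVolume, SegmentationResult

__all__ = [
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "read_volume",
    "segmentation_to_frame",
    "write_segmentation",
    "write_report_json",
    "write_report_markdown",
]


def read_dicom_series(directory: str | Path) -> HUVolume:
    """Read a DICOM series directory into an HU volume.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal (cross product of the row/column direction cosines) and
    RescaleSlope/RescaleIntercept are applied.  Spacing is (slice spacing,
    row spacing, column spacing) in mm.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image files found in {directory}")

    first = slices[0]
    orientation = np.asarray(
        getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float
    )
    normal = np.cross(orientation[:3], orientation[3:])

    def position(ds) -> float:
        ipp = np.asarray(getattr(ds, "ImagePositionPatient", [0, 0, 0]), dtype=float)
        return float(ipp @ normal)

    slices.sort(key=position)
    arrays = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(ds.pixel_array.astype(float) * slope + intercept)
    stack = np.stack(arrays, axis=0)

    row_sp, col_sp = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1:
        slice_sp = abs(position(slices[1]) - position(slices[0])) or 1.0
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(
        float(v) for v in getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])
    )
    return HUVolume(voxels=stack, spacing=(slice_sp, row_sp, col_sp), origin=origin)


def read_nifti(path: str | Path) -> HUVolume:
    """Read a NIfTI-1 volume; voxel values are taken as HU as stored."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return HUVolume(voxels=data, spacing=tuple(float(z) for z in zooms))


def write_nifti(data: np.ndarray, spacing, path: str | Path) -> None:
    """Write a 3D array (HU volume, mask or labelmap) as NIfTI-1."""
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_volume(path: str | Path) -> HUVolume:
    """Dispatch: directory -> DICOM series, file -> NIfTI."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def segmentation_to_frame(result: SegmentationResult) -> pd.DataFrame:
    return pd.DataFrame(
        result.to_records(),
        columns=[
            "label",
            "voxel_count",
            "volume_mm3",
            "hu_mean",
            "hu_min",
            "hu_max",
            "hu_range",
            "is_heterogeneous",
            "max_diameter_mm",
        ],
    )


def write_segmentation(
    result: SegmentationResult, json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> dict:
    """Serialize a segmentation result; returns the JSON document."""
    doc = {
        "window": {"hu_low": result.window.hu_low, "hu_high": result.window.hu_high},
        "connectivity": result.connectivity,
        "min_voxels": result.min_voxels,
        "voxel_volume_mm3": result.voxel_volume_mm3,
        "n_stones": result.n_stones,
        "total_voxel_count": result.total_voxel_count,
        "total_volume_mm3": result.total_volume_mm3,
        "segments": result.to_records(),
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(doc, indent=2))
    if csv_path is not None:
        segmentation_to_frame(result).to_csv(csv_path, index=False)
    return doc


def bland_altman_plot(x, y, path: str | Path, label_x: str = "x", label_y: str = "y"):
    """Mean-vs-difference agreement plot with bias and limits of agreement.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .agreement import bland_altman

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = bland_altman(x, y)
    means, diffs = (x + y) / 2.0, x - y
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(res["bias"], color="k", lw=1, label=f"bias {res['bias']:.1f}")
    for loa in (res["loa_low"], res["loa_high"]):
        ax.axhline(loa, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of {label_x} and {label_y} (mm$^3$)")
    ax.set_ylabel(f"{label_x} - {label_y} (mm$^3$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


def write_report_json(report: AgreementReport, path: str | Path, extra: dict | None = None) -> None:
    doc = report.to_dict()
    if extra:
        doc["run"] = extra
    Path(path).write_text(json.dumps(doc, indent=2, default=float))


def write_report_markdown(report: AgreementReport, path: str | Path) -> None:
    lines = [
        "# Observer agreement report",
        "",
        f"- cases: {report.n_cases}",
        f"- observers: {report.n_observers}",
        f"- aggregation: {report.aggregation}",
        "",
        "## Pairwise agreement",
        "",
        "| pair | Lin CCC | 95% CI | bias (mm3) | RC (mm3) | t-test p |",
        "|---|---|---|---|---|---|",
    ]
    for pair, entry in report.pairwise.items():
        ccc = entry["lin_ccc"]
        ba = entry["bland_altman"]
        tp = entry["t_test"]["p"] if entry.get("t_test") else float("nan")
        lines.append(
            f"| {pair} | {ccc['ccc']:.3f} | ({ccc['ci_low']:.3f}, {ccc['ci_high']:.3f}) "
            f"| {ba['bias']:.1f} | {ba['rc']:.1f} | {tp:.2f} |"
        )
    ok = report.overall_kendall
    lines += [
        "",
        f"**Overall Kendall W**: {ok['w']:.4f} (chi2 = {ok['chi2']:.1f}, p = {ok['p']:.2g})",
        "",
        "## Per-observer repeatability",
        "",
    ]
    for obs, entry in report.per_observer.items():
        if not entry:
            lines.append(f"- {obs}: no replicates")
            continue
        parts = []
        if "cv_percent_mean" in entry:
            parts.append(
                f"mean CV {entry['cv_percent_mean']:.1f}% "
                f"(median {entry['cv_percent_median']:.1f}%)"
            )
        if "intra_kendall" in entry:
            parts.append(f"replicate concordance W {entry['intra_kendall']['w']:.3f}")
        lines.append(f"- {obs}: " + "; ".join(parts))
    if report.subgroup:
        lines += ["", "## Subgroup CV comparisons", ""]
        for key, sub in report.subgroup.items():
            levels = [k for k in sub if k != "mann_whitney"]
            desc = ", ".join(
                f"{lvl} median CV {sub[lvl]['median_cv']:.1f}% (n={sub[lvl]['n']})"
                for lvl in levels
            )
            lines.append(f"- {key}: {desc}; Mann–Whitney p = {sub['mann_whitney']['p']:.3f}")
    if report.warnings:
        lines += ["", "## Warnings", ""] + [f"- {w}" for w in report.warnings]
    Path(path).write_text("\n".join(lines) + "\n")
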