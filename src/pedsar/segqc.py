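"""Segmentation quality and morphometry validation.

Dice similarity coefficient, average (symmetric mean boundary-to-boundary)
Hausdorff distance, inter-operator summaries against a ground truth, and
literature-range morphometry checks.  DSC > 0.8 is classed "acceptable" and
DSC >= 0.9 "excellent", the thresholds conventionally applied to manual
segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from pedsar.volume import LabelVolume

__all__ = [
    "dice",
    "dsc_class",
    "boundary_voxels",
    "hausdorff_avg",
    "hausdorff_max",
    "interoperator_report",
    "ValidationRow",
    "percent_difference",
    "validate_morphometry",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_binary(x) -> np.ndarray:
    m = np.asarray(x)
    return m.astype(bool)


def dice(x, y) -> float:
    """Dice similarity coefficient 2|X ∩ Y| / (|X| + |Y|).

    Two empty masks agree perfectly and score 1.0.
    """
    X, Y = _as_binary(x), _as_binary(y)
    if X.shape != Y.shape:
        raise ValueError(f"mask shapes differ: {X.shape} vs {Y.shape}")
    denom = int(X.sum()) + int(Y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((X & Y).sum()) / denom


def dsc_class(value: float) -> str:
    """Conventional quality class for a DSC value."""
    if value >= 0.9:
        return "excellent"
    if value > 0.8:
        return "acceptable"
    return "poor"


def boundary_voxels(mask) -> np.ndarray:
    """Indices (n, 3) of mask voxels with at least one face-adjacent non-mask neighbor."""
    m = _as_binary(mask)
    if m.ndim == 2:
        struct = ndimage.generate_binary_structure(2, 1)
    else:
        struct = _FACE_STRUCT
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return np.argwhere(m & ~interior)


def _directed_mean_distance(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    d, _ = cKDTree(b_pts).query(a_pts, k=1)
    return float(np.mean(d))


def hausdorff_avg(x, y, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average boundary distance in mm.

    Mean distance from each boundary voxel of X to the nearest boundary
    voxel of Y, averaged with the reverse direction.  Symmetric in its
    arguments by construction; 0 for identical masks.
    """
    X, Y = _as_binary(x), _as_binary(y)
    if X.shape != Y.shape:
        raise ValueError(f"mask shapes differ: {X.shape} vs {Y.shape}")
    if not X.any() or not Y.any():
        raise ValueError("average Hausdorff distance requires two nonempty masks")
    sp = np.asarray(spacing_mm, dtype=float)[: X.ndim]
    bx = boundary_voxels(X) * sp
    by = boundary_voxels(Y) * sp
    return 0.5 * (_directed_mean_distance(bx, by) + _directed_mean_distance(by, bx))


def hausdorff_max(x, y, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """Classical (maximum) symmetric Hausdorff distance in mm."""
    X, Y = _as_binary(x), _as_binary(y)
    if not X.any() or not Y.any():
        raise ValueError("Hausdorff distance requires two nonempty masks")
    sp = np.asarray(spacing_mm, dtype=float)[: X.ndim]
    bx = boundary_voxels(X) * sp
    by = boundary_voxels(Y) * sp
    d_xy, _ = cKDTree(by).query(bx, k=1)
    d_yx, _ = cKDTree(bx).query(by, k=1)
    return float(max(d_xy.max(), d_yx.max()))


def interoperator_report(
    segmentations: dict[str, LabelVolume] | list[LabelVolume],
    truth: LabelVolume,
    tissues: list[str],
    mode: str = "3d",
) -> pd.DataFrame:
    """Per-(operator, tissue) DSC and average Hausdorff distance vs ground truth.

    ``mode='2d'`` evaluates slice-wise on coronal (y-constant) sections and
    averages over the slices where either mask is present; the default
    evaluates the full 3D masks.  The returned frame carries the grand
    mean +/- SD across all cells in ``df.attrs`` (SD is NaN, flagged, for a
    single cell).
    """
    if not isinstance(segmentations, dict):
        segmentations = {f"operator_{i + 1}": v for i, v in enumerate(segmentations)}
    if not segmentations:
        raise ValueError("at least one operator segmentation is required")
    rows = []
    for op_name, seg in segmentations.items():
        if seg.shape != truth.shape:
            raise ValueError(f"{op_name}: shape {seg.shape} != truth {truth.shape}")
        for tissue in tissues:
            X = seg.mask(tissue)
            Y = truth.mask(tissue)
            if mode == "2d":
                dscs, hds = [], []
                for j in range(X.shape[1]):
                    xs, ys = X[:, j, :], Y[:, j, :]
                    if not (xs.any() or ys.any()):
                        continue
                    dscs.append(dice(xs, ys))
                    if xs.any() and ys.any():
                        sp2 = (truth.spacing_mm[0], truth.spacing_mm[2])
                        hds.append(hausdorff_avg(xs, ys, sp2))
                d = float(np.mean(dscs)) if dscs else 1.0
                h = float(np.mean(hds)) if hds else np.nan
            else:
                d = dice(X, Y)
                h = hausdorff_avg(X, Y, truth.spacing_mm) if (X.any() and Y.any()) else np.nan
            rows.append({"operator": op_name, "tissue": tissue, "dsc": d,
                         "hausdorff_avg_mm": h, "dsc_class": dsc_class(d)})
    df = pd.DataFrame(rows)
    df.attrs["dsc_mean"] = float(df.dsc.mean())
    df.attrs["dsc_sd"] = float(df.dsc.std(ddof=1)) if len(df) > 1 else float("nan")
    df.attrs["hd_mean"] = float(df.hausdorff_avg_mm.mean())
    df.attrs["hd_sd"] = float(df.hausdorff_avg_mm.std(ddof=1)) if len(df) > 1 else float("nan")
    df.attrs["sd_undefined"] = len(df) <= 1
    return df


# --------------------------------------------------------------------------- morphometry


@dataclass
class ValidationRow:
    tissue: str
    measurement_type: str
    measured: float
    units: str
    ref_low: float
    ref_high: float
    percent_difference: float

    @property
    def within_range(self) -> bool:
        return self.percent_difference == 0.0


def percent_difference(measured: float, ref_low: float, ref_high: float | None = None) -> float:
    """Absolute percent difference vs a literature value or [low, high] range.

    Inside the range (or equal to a point reference) scores 0; otherwise
    100 * |measured - nearest bound| / bound, i.e. the literature value is
    the denominator.
    """
    if ref_high is None or ref_high == ref_low:
        ref = ref_low
        return 100.0 * abs(measured - ref) / ref
    if ref_low <= measured <= ref_high:
        return 0.0
    bound = ref_low if measured < ref_low else ref_high
    return 100.0 * abs(measured - bound) / bound


def validate_morphometry(measurements: pd.DataFrame, references: pd.DataFrame) -> list[ValidationRow]:
    """Join measured morphometry against literature references.

    ``measurements``: columns tissue, type, value, units.
    ``references``: columns tissue, type, ref_low, ref_high, units
    (ref_high may repeat ref_low for point references).
    Percent differences are rounded to one decimal, matching how such
    validation tables are reported.
    """
    refs = references.set_index(["tissue", "type"])
    out: list[ValidationRow] = []
    for _, m in measurements.iterrows():
        key = (m.tissue, m.type)
        if key not in refs.index:
            raise KeyError(f"no literature reference for {key}")
        r = refs.loc[key]
        lo, hi = float(r.ref_low), float(r.ref_high)
        pct = round(percent_difference(float(m.value), lo, hi), 1)
        out.append(
            ValidationRow(m.tissue, m.type, float(m.value), str(m.units), lo, hi, pct)
        )
    return out
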