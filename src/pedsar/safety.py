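"""RF safety quantities from field phasors.

Pointwise SAR, mass-weighted regional averages (head / whole body),
10g-averaged SAR and rms E-field via a centered growing-cube kernel with
exact-10g interpolation of the outermost shell (an IEC 62704-1-style
simplification), field normalizations (|B1+| at the coil center, or head
SAR to the 3.2 W/kg head-scan limit), with/without-implant comparison,
maximum-intensity projections, the Tier-3 incident tangential E-field
profile along an implant lead, and one-at-a-time sensitivity scans.

Conventions: phasor magnitudes are peak values, so pointwise SAR is
sigma |E_peak|^2 / (2 rho) and reported E-field averages are rms
(|E_rms| = |E_peak| / sqrt(2)).  Background (air) and implant voxels carry
no tissue mass and are excluded from all averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pedsar.fdtd import FieldPhasor, b1_plus

__all__ = [
    "SARResult",
    "point_sar",
    "regional_sar",
    "sar_10g",
    "e_10g_rms",
    "head_mask_from_plane",
    "evaluate_safety",
    "normalize_head_sar",
    "compare_implant",
    "tangential_e",
    "sensitivity_scan",
    "mip",
    "apply_safety_margin",
    "SAFETY_MARGIN",
]

SAFETY_MARGIN = 1.5  # multiplicative margin suggested for inter-subject variability


@dataclass
class SARResult:
    """Safety summary: pointwise map plus the regional/10g quantities."""

    sar_map: np.ndarray  # W/kg, pointwise
    sar_head: float
    sar_wb: float
    sar10g_map: np.ndarray
    sar10g_max: float
    sar10g_argmax: tuple[int, int, int]
    e10g_map: np.ndarray
    e10g_max: float  # V/m, rms
    e10g_argmax: tuple[int, int, int]
    normalization: str
    head_mass_kg: float
    body_mass_kg: float
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "sar_head_W_per_kg": self.sar_head,
            "sar_wb_W_per_kg": self.sar_wb,
            "sar10g_max_W_per_kg": self.sar10g_max,
            "e10g_max_V_per_m": self.e10g_max,
            "normalization": self.normalization,
            "head_mass_kg": self.head_mass_kg,
            "body_mass_kg": self.body_mass_kg,
        }


# --------------------------------------------------------------------------- pointwise & regional


def point_sar(E: np.ndarray, sigma: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Pointwise SAR = sigma |E_peak|^2 / (2 rho) in W/kg.

    ``E`` is the (3, ...) complex peak-phasor field; voxels with rho <= 0 or
    sigma = 0 (air, insulators) get SAR 0.
    """
    e2 = np.sum(np.abs(np.asarray(E)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sar = np.where(np.asarray(rho) > 0, np.asarray(sigma) * e2 / (2.0 * np.asarray(rho)), 0.0)
    return sar


def regional_sar(sar_map: np.ndarray, region_mask: np.ndarray, rho: np.ndarray) -> float:
    """Mass-weighted mean SAR over a region: sum(SAR rho V) / sum(rho V)."""
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region mask")
    w = np.asarray(rho)[m]
    return float(np.sum(np.asarray(sar_map)[m] * w) / np.sum(w))


def head_mask_from_plane(tissue_mask: np.ndarray, z_index: int) -> np.ndarray:
    """Head region: tissue voxels at or above an axial plane index."""
    out = np.zeros_like(np.asarray(tissue_mask, dtype=bool))
    out[:, :, z_index:] = np.asarray(tissue_mask, dtype=bool)[:, :, z_index:]
    return out


# --------------------------------------------------------------------------- 10g cube averaging


def _cube_sums(arr: np.ndarray, k: int) -> np.ndarray:
    """Sum of ``arr`` over the (2k+1)^3 cube centered at each voxel, clipped
    at the domain boundary, via an integral image."""
    if k == 0:
        return np.asarray(arr, dtype=float).copy()
    a = np.asarray(arr, dtype=float)
    I = a
    for ax in range(3):
        I = np.cumsum(I, axis=ax)
    I = np.pad(I, ((1, 0),) * 3)
    n = a.shape
    idx = [np.arange(n[d]) for d in range(3)]
    lo = [np.clip(idx[d] - k, 0, n[d]) for d in range(3)]
    hi = [np.clip(idx[d] + k + 1, 0, n[d]) for d in range(3)]
    out = np.zeros(n)
    # inclusion-exclusion over the 8 corners
    for sx, bx in ((1, hi[0]), (-1, lo[0])):
        for sy, by in ((1, hi[1]), (-1, lo[1])):
            for sz, bz in ((1, hi[2]), (-1, lo[2])):
                out += (sx * sy * sz) * I[np.ix_(bx, by, bz)]
    return out


def _mass_average(
    quantity: np.ndarray,
    rho: np.ndarray,
    tissue_mask: np.ndarray,
    voxel_volume_m3: float,
    target_mass_kg: float = 0.010,
):
    """Growing-cube mass averaging with exact-target-mass shell interpolation.

    For each tissue voxel, the centered cube is grown until the enclosed
    tissue mass reaches the target; the averaged quantity is the
    mass-weighted mean over exactly the target mass (the outermost shell
    contributes fractionally).  Voxels whose largest in-domain (clipped)
    cube cannot reach the target mass are NaN (invalid).
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    mass_vox = np.where(tissue, np.asarray(rho) * voxel_volume_m3, 0.0)
    q_mass_vox = np.where(tissue, np.asarray(quantity) * mass_vox, 0.0)
    n = tissue.shape
    kmax = (max(n) + 1) // 2
    out = np.full(n, np.nan)
    pending = tissue.copy()
    prev_mass = np.zeros(n)
    prev_qm = np.zeros(n)
    for k in range(kmax + 1):
        if not pending.any():
            break
        mass_k = _cube_sums(mass_vox, k)
        qm_k = _cube_sums(q_mass_vox, k)
        done = pending & (mass_k >= target_mass_kg)
        if done.any():
            dm = mass_k[done] - prev_mass[done]
            need = target_mass_kg - prev_mass[done]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(dm > 0, need / dm, 0.0)
            qm_target = prev_qm[done] + frac * (qm_k[done] - prev_qm[done])
            out[done] = qm_target / target_mass_kg
            pending &= ~done
        prev_mass, prev_qm = mass_k, qm_k
    return out


def sar_10g(
    sar_map: np.ndarray,
    rho: np.ndarray,
    tissue_mask: np.ndarray,
    voxel_volume_m3: float,
    target_mass_kg: float = 0.010,
):
    """10g-averaged SAR map, its maximum and argmax over valid tissue voxels."""
    m = _mass_average(sar_map, rho, tissue_mask, voxel_volume_m3, target_mass_kg)
    return m, *_nanmax_loc(m)


def e_10g_rms(
    E: np.ndarray,
    rho: np.ndarray,
    tissue_mask: np.ndarray,
    voxel_volume_m3: float,
    target_mass_kg: float = 0.010,
):
    """10g mass-averaged rms |E| map (V/m), its maximum and argmax."""
    e_rms = np.sqrt(np.sum(np.abs(np.asarray(E)) ** 2, axis=0) / 2.0)
    m = _mass_average(e_rms, rho, tissue_mask, voxel_volume_m3, target_mass_kg)
    return m, *_nanmax_loc(m)


def _nanmax_loc(m: np.ndarray):
    if np.all(np.isnan(m)):
        return float("nan"), (0, 0, 0)
    flat = np.nanargmax(m)
    loc = np.unravel_index(flat, m.shape)
    return float(m[loc]), tuple(int(i) for i in loc)


# --------------------------------------------------------------------------- pipeline-level ops


def evaluate_safety(
    fields: FieldPhasor,
    head_z_mm: float | None = None,
    target_mass_kg: float = 0.010,
) -> SARResult:
    """Full safety evaluation of a solved scene.

    ``head_z_mm`` is the world z of the axial plane above which tissue counts
    as head; the default (0, the coil-center plane) is appropriate when the
    head is centered in the head coil.
    """
    if fields.sigma is None or fields.rho is None or fields.tissue_mask is None:
        raise ValueError("fields must carry the material scene (sigma, rho, tissue_mask)")
    sar = point_sar(fields.E, fields.sigma, fields.rho)
    tissue = fields.tissue_mask
    if not tissue.any():
        raise ValueError("no tissue in the scene")
    zc = fields.cell_coords(2)
    z0 = 0.0 if head_z_mm is None else float(head_z_mm)
    z_index = int(np.searchsorted(zc, z0))
    head = head_mask_from_plane(tissue, z_index)
    if not head.any():
        head = tissue
    vv = (fields.spacing_mm * 1e-3) ** 3
    sar_head = regional_sar(sar, head, fields.rho)
    sar_wb = regional_sar(sar, tissue, fields.rho)
    s10, s10max, s10loc = sar_10g(sar, fields.rho, tissue, vv, target_mass_kg)
    e10, e10max, e10loc = e_10g_rms(fields.E, fields.rho, tissue, vv, target_mass_kg)
    head_mass = float(np.sum(fields.rho[head]) * vv)
    body_mass = float(np.sum(fields.rho[tissue]) * vv)
    return SARResult(
        sar_map=sar,
        sar_head=sar_head,
        sar_wb=sar_wb,
        sar10g_map=s10,
        sar10g_max=s10max,
        sar10g_argmax=s10loc,
        e10g_map=e10,
        e10g_max=e10max,
        e10g_argmax=e10loc,
        normalization=fields.normalization,
        head_mass_kg=head_mass,
        body_mass_kg=body_mass,
        meta={"head_z_mm": z0, "target_mass_kg": target_mass_kg},
    )


def normalize_head_sar(
    fields: FieldPhasor,
    target_W_per_kg: float = 3.2,
    head_z_mm: float | None = None,
) -> tuple[FieldPhasor, SARResult]:
    """Scale fields so the head-averaged SAR equals the head-scan limit.

    SAR is quadratic in the fields, so the field factor is
    sqrt(target / SAR_head); E-field quantities scale by that square root
    and all SAR quantities scale linearly to put SAR_head at the target.
    Idempotent.
    """
    base = evaluate_safety(fields, head_z_mm=head_z_mm)
    if base.sar_head <= 0:
        raise ValueError("head SAR is zero; cannot normalize")
    factor = np.sqrt(target_W_per_kg / base.sar_head)
    scaled = fields.scaled(factor, "headSAR_3p2")
    return scaled, evaluate_safety(scaled, head_z_mm=head_z_mm)


def compare_implant(result_with: SARResult, result_without: SARResult) -> dict:
    """Absolute and percent deltas (denominator: without-implant value)."""
    out = {}
    for key in ("sar_head", "sar_wb", "sar10g_max", "e10g_max"):
        w = getattr(result_with, key)
        wo = getattr(result_without, key)
        if w == wo:
            pct = 0.0
        elif wo != 0:
            pct = 100.0 * (w - wo) / wo
        else:
            pct = float("nan")
        out[key] = {"with": w, "without": wo, "delta": w - wo, "percent": pct}
    return out


def tangential_e(fields: FieldPhasor, path_points_mm: np.ndarray, n_samples: int = 200):
    """Tier-3 incident tangential E-field profile along a lead trajectory.

    The (implant-free) complex E phasor is interpolated at points along the
    polyline and projected on the local unit tangent.  Returns (arclength mm,
    complex tangential E) arrays; report magnitude and phase per point.
    """
    pts = np.atleast_2d(np.asarray(path_points_mm, dtype=float))
    if len(pts) < 2:
        raise ValueError("lead path needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, arcs[-1], n_samples)
    # sample positions and tangents along the polyline
    pos = np.empty((n_samples, 3))
    tan = np.empty((n_samples, 3))
    for d in range(3):
        pos[:, d] = np.interp(s, arcs, pts[:, d])
    for i, si in enumerate(s):
        j = min(int(np.searchsorted(arcs, si, side="right")) - 1, len(seg) - 1)
        t = pts[j + 1] - pts[j]
        tan[i] = t / np.linalg.norm(t)
    org = np.asarray(fields.origin_mm)
    idx = ((pos - org) / fields.spacing_mm).T  # continuous cell indices
    et = np.zeros(n_samples, dtype=complex)
    for d in range(3):
        re = ndimage.map_coordinates(fields.E[d].real, idx, order=1, mode="nearest")
        im = ndimage.map_coordinates(fields.E[d].imag, idx, order=1, mode="nearest")
        et += (re + 1j * im) * tan[:, d]
    return s, et


def sensitivity_scan(run_fn, base_config: dict, parameter: str, percent: float, outputs=None) -> dict:
    """One-at-a-time sensitivity: %-change of each output per %-change of input.

    ``run_fn(config) -> dict`` re-runs the safety pipeline; the parameter is
    perturbed by +/-percent (multiplicatively) and the normalized sensitivity
    |delta output| / output / percent is reported per output key (central
    difference over the two perturbed runs).
    """
    if percent <= 0:
        raise ValueError("percent must be positive")
    base = run_fn(base_config)
    keys = outputs or [k for k, v in base.items() if isinstance(v, (int, float))]
    hi_cfg = dict(base_config)
    lo_cfg = dict(base_config)
    hi_cfg[parameter] = base_config.get(parameter, 1.0) * (1.0 + percent / 100.0)
    lo_cfg[parameter] = base_config.get(parameter, 1.0) * (1.0 - percent / 100.0)
    hi = run_fn(hi_cfg)
    lo = run_fn(lo_cfg)
    out = {}
    for k in keys:
        if base[k] == 0:
            out[k] = 0.0 if hi[k] == lo[k] else float("inf")
            continue
        dpct = 100.0 * (hi[k] - lo[k]) / base[k] / 2.0  # % change per +percent input
        out[k] = abs(dpct) / percent
    return out


def mip(volume_map: np.ndarray, axis: int, png_path=None) -> np.ndarray:
    """Maximum intensity projection along an axis; optionally write a PNG."""
    arr = np.asarray(volume_map, dtype=float)
    img = np.nanmax(arr, axis=axis)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        shown = ax.imshow(img.T, origin="lower", cmap="inferno")
        fig.colorbar(shown, ax=ax, shrink=0.8)
        ax.set_title("max-intensity projection")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return img


def apply_safety_margin(limit: float, margin: float = SAFETY_MARGIN) -> float:
    """Margin-adjusted exposure limit: the computed quantity is compared
    against limit / margin (equivalently the prediction is multiplied by the
    margin) to cover inter-subject variability."""
    return limit / margin
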