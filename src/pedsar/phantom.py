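"""Synthetic pediatric voxel phantoms, implant insertion, and label-map cleanup.

The generator builds a desk-scale stand-in for a segmented whole-body child
model out of nested geometric shells (ellipsoids, elliptic cylinders, tubes,
boxes) rasterized by voxel-center sampling, inserts a vagus-nerve-stimulator
style implant (lead + insulation + cuff electrodes + pulse generator), and
implements the label-map cleanup steps used when finalizing a segmentation:
modal-neighborhood filling of unlabeled interior voxels and nearest-neighbor
resampling to a target isotropic resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from pedsar.volume import LabelVolume

__all__ = [
    "Shell",
    "PhantomSpec",
    "ImplantSpec",
    "build_phantom",
    "insert_implant",
    "fill_unlabeled",
    "resample_labels",
    "body_mask_from_labels",
    "default_child_spec",
    "default_vns_spec",
]

# Implant label IDs, deliberately far from tissue IDs.
CONDUCTOR_ID = 100
INSULATION_ID = 101
ELECTRODE_ID = 102
IMPLANT_LABELS = {
    CONDUCTOR_ID: "Implant Conductor",
    INSULATION_ID: "Implant Insulation",
    ELECTRODE_ID: "Implant Electrode",
}


# --------------------------------------------------------------------------- specs


@dataclass
class Shell:
    """One geometric primitive painted into the phantom.

    kind:
      - ``ellipsoid``: params center (3,), semiaxes (3,)
      - ``cylinder``: params center (3,), radii (rx, ry), length, axis in {x,y,z}
      - ``tube``: params center (3,), inner_radius, outer_radius, length, axis
      - ``box``: params center (3,), size (3,)
    All lengths in mm (world coordinates).  Shells listed later are painted
    over earlier ones, so a nested anatomy is listed outside-in.
    """

    tissue: str
    kind: str
    params: dict
    priority: int | None = None  # defaults to list order; equal explicit priorities may not overlap


@dataclass
class PhantomSpec:
    shells: list[Shell]
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] | None = None  # derived from shell extents when None
    body_height_mm: float = 861.0
    rng_seed: int = 0
    jitter_mm: float = 0.0  # optional seeded surface roughness on shell boundaries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text())
        shells = [Shell(**s) for s in raw.pop("shells")]
        for key in ("spacing_mm", "origin_mm", "shape"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(shells=shells, **raw)


@dataclass
class ImplantSpec:
    """A VNS-like implant: lead polyline, cuff electrodes, and an IPG box.

    Cuff electrodes are annuli centered on the nerve trajectory (here: the
    local lead axis) with the device dimensions diameter 1.4 mm, length
    1 mm, wall thickness 0.3 mm; the lead conductor is 1 mm in diameter and
    wrapped by 0.5 mm of insulation everywhere except at the electrode
    contacts.
    """

    lead_path: np.ndarray  # (n, 3) world points, mm
    lead_diameter_mm: float = 1.0
    insulation_thickness_mm: float = 0.5
    electrode_positions_mm: tuple[float, ...] = ()  # arclengths along the lead
    electrode_diameter_mm: float = 1.4
    electrode_length_mm: float = 1.0
    electrode_thickness_mm: float = 0.3
    ipg_center_mm: tuple[float, float, float] | None = None
    ipg_size_mm: tuple[float, float, float] = (24.0, 8.0, 24.0)
    conductor_id: int = CONDUCTOR_ID
    insulation_id: int = INSULATION_ID
    electrode_id: int = ELECTRODE_ID

    def __post_init__(self) -> None:
        self.lead_path = np.atleast_2d(np.asarray(self.lead_path, dtype=float))
        if self.lead_path.shape[0] and self.lead_path.shape[1] != 3:
            raise ValueError("lead_path must be an (n, 3) array of world points")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImplantSpec":
        raw = yaml.safe_load(Path(path).read_text())
        raw["lead_path"] = np.asarray(raw["lead_path"], dtype=float)
        if raw.get("electrode_positions_mm") is not None:
            raw["electrode_positions_mm"] = tuple(raw.get("electrode_positions_mm", ()))
        if raw.get("ipg_center_mm") is not None:
            raw["ipg_center_mm"] = tuple(raw["ipg_center_mm"])
        if raw.get("ipg_size_mm") is not None:
            raw["ipg_size_mm"] = tuple(raw["ipg_size_mm"])
        return cls(**raw)

    def arclengths(self) -> np.ndarray:
        if len(self.lead_path) < 2:
            return np.zeros(len(self.lead_path))
        seg = np.linalg.norm(np.diff(self.lead_path, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def point_at(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """World point and unit tangent at arclength ``s`` along the lead."""
        arcs = self.arclengths()
        s = float(np.clip(s, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right") - 1)
        i = min(i, len(arcs) - 2)
        seg = self.lead_path[i + 1] - self.lead_path[i]
        seg_len = np.linalg.norm(seg)
        t = seg / seg_len if seg_len > 0 else np.array([0.0, 0.0, 1.0])
        return self.lead_path[i] + t * (s - arcs[i]), t


# --------------------------------------------------------------------------- rasterization


def _world_grids(shape, spacing, origin):
    ax = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _shell_mask(shell: Shell, X, Y, Z, jitter: float, rng: np.random.Generator) -> np.ndarray:
    p = shell.params
    kind = shell.kind.lower()
    if kind == "ellipsoid":
        cx, cy, cz = p["center"]
        ax_, ay, az = p["semiaxes"]
        r2 = ((X - cx) / ax_) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
        inside = r2 <= 1.0
    elif kind in ("cylinder", "tube"):
        axis = p.get("axis", "z")
        cx, cy, cz = p["center"]
        length = p["length"]
        order = {"x": (Y, Z, X, cy, cz, cx), "y": (X, Z, Y, cx, cz, cy), "z": (X, Y, Z, cx, cy, cz)}[axis]
        U, V, W, cu, cv, cw = order
        if kind == "cylinder":
            radii = p.get("radii", (p.get("radius"), p.get("radius")))
            ru, rv = (radii if isinstance(radii, (tuple, list)) else (radii, radii))
            radial = ((U - cu) / ru) ** 2 + ((V - cv) / rv) ** 2 <= 1.0
        else:
            rr = (U - cu) ** 2 + (V - cv) ** 2
            radial = (rr >= p["inner_radius"] ** 2) & (rr <= p["outer_radius"] ** 2)
        inside = radial & (np.abs(W - cw) <= length / 2.0)
    elif kind == "box":
        cx, cy, cz = p["center"]
        sx, sy, sz = p["size"]
        inside = (np.abs(X - cx) <= sx / 2) & (np.abs(Y - cy) <= sy / 2) & (np.abs(Z - cz) <= sz / 2)
    else:
        raise ValueError(f"unknown shell kind {shell.kind!r}")
    if jitter > 0:
        # seeded surface roughness: erode a random subset of the boundary rind
        inside = inside.copy()
        rind = inside & ~ndimage.binary_erosion(inside)
        vals = inside[rind]
        vals[rng.random(vals.size) < min(jitter, 1.0) * 0.5] = False
        inside[rind] = vals
    return inside


def build_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the shell list into a label volume (voxel-center sampling).

    Shells are painted in list order so that inner anatomy, listed later,
    overwrites its surroundings.  Shells carrying the same explicit
    ``priority`` must be disjoint; an overlap raises with the offending
    pair named.  Output is deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.shape is not None:
        shape = tuple(int(n) for n in spec.shape)
    else:
        shape = _derive_shape(spec)
    if not spec.shells:
        return LabelVolume(np.zeros(shape, dtype=np.int16), spec.spacing_mm, spec.origin_mm, {})

    X, Y, Z = _world_grids(shape, spec.spacing_mm, spec.origin_mm)
    data = np.zeros(shape, dtype=np.int16)
    label_map: dict[int, str] = {}
    name_to_id: dict[str, int] = {}
    painted_by_priority: dict[int, list[tuple[str, np.ndarray]]] = {}

    for idx, shell in enumerate(spec.shells):
        mask = _shell_mask(shell, X, Y, Z, spec.jitter_mm, rng)
        prio = shell.priority
        if prio is not None:
            for other_name, other_mask in painted_by_priority.get(prio, []):
                if np.any(mask & other_mask):
                    raise ValueError(
                        f"shells {other_name!r} and {shell.tissue!r} share priority {prio} but overlap"
                    )
            painted_by_priority.setdefault(prio, []).append((shell.tissue, mask))
        if shell.tissue not in name_to_id:
            name_to_id[shell.tissue] = len(name_to_id) + 1
            label_map[name_to_id[shell.tissue]] = shell.tissue
        data[mask] = name_to_id[shell.tissue]

    # drop labels fully overwritten by later shells
    present = set(np.unique(data).tolist())
    label_map = {k: v for k, v in label_map.items() if k in present}
    return LabelVolume(data, spec.spacing_mm, spec.origin_mm, label_map)


def _derive_shape(spec: PhantomSpec) -> tuple[int, int, int]:
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for shell in spec.shells:
        c = np.asarray(shell.params["center"], dtype=float)
        kind = shell.kind.lower()
        if kind == "ellipsoid":
            ext = np.asarray(shell.params["semiaxes"], dtype=float)
        elif kind in ("cylinder", "tube"):
            axis = {"x": 0, "y": 1, "z": 2}[shell.params.get("axis", "z")]
            if kind == "cylinder":
                radii = shell.params.get("radii", (shell.params.get("radius"),) * 2)
                ru, rv = radii if isinstance(radii, (tuple, list)) else (radii, radii)
            else:
                ru = rv = shell.params["outer_radius"]
            ext = np.empty(3)
            perp = [d for d in range(3) if d != axis]
            ext[perp[0]], ext[perp[1]] = ru, rv
            ext[axis] = shell.params["length"] / 2.0
        elif kind == "box":
            ext = np.asarray(shell.params["size"], dtype=float) / 2.0
        else:
            raise ValueError(f"unknown shell kind {shell.kind!r}")
        lo = np.minimum(lo, c - ext)
        hi = np.maximum(hi, c + ext)
    if not np.all(np.isfinite(lo)):
        return (1, 1, 1)
    sp = np.asarray(spec.spacing_mm)
    org = np.asarray(spec.origin_mm)
    pad = 2  # voxels of air margin
    n = np.ceil((hi - org) / sp).astype(int) + 1 + pad
    if np.any(lo < org - sp / 2):
        raise ValueError(
            f"shell extents reach {lo} mm, below the volume origin {tuple(org)}; lower origin_mm"
        )
    return tuple(int(v) for v in n)


# --------------------------------------------------------------------------- implant


def _supercover_voxels(vol: LabelVolume, path: np.ndarray) -> list[tuple[int, int, int]]:
    """Ordered voxels traversed by the polyline (dense sub-voxel stepping)."""
    step = 0.25 * min(vol.spacing_mm)
    out: list[tuple[int, int, int]] = []
    seen = set()
    for a, b in zip(path[:-1], path[1:]):
        seg_len = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(seg_len / step)) + 1)
        pts = a + np.linspace(0, 1, n)[:, None] * (b - a)
        idx = np.rint(vol.index_coords(pts)).astype(int)
        for ijk in map(tuple, idx):
            if ijk not in seen:
                seen.add(ijk)
                out.append(ijk)
    return out


def _within_radius_of_path(vol: LabelVolume, path: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius`` mm of the polyline."""
    mask = np.zeros(vol.shape, dtype=bool)
    sp = np.asarray(vol.spacing_mm)
    org = np.asarray(vol.origin_mm)
    for a, b in zip(path[:-1], path[1:]):
        lo = np.minimum(a, b) - radius - sp
        hi = np.maximum(a, b) + radius + sp
        i0 = np.maximum(np.floor((lo - org) / sp), 0).astype(int)
        i1 = np.minimum(np.ceil((hi - org) / sp) + 1, vol.shape).astype(int)
        if np.any(i0 >= i1):
            continue
        ax = [org[d] + np.arange(i0[d], i1[d]) * sp[d] for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        P = np.stack([X, Y, Z], axis=-1)
        d = b - a
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.linalg.norm(P - a, axis=-1)
        else:
            t = np.clip(((P - a) @ d) / L2, 0.0, 1.0)
            dist = np.linalg.norm(P - (a + t[..., None] * d), axis=-1)
        sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub |= dist <= radius
    return mask


def insert_implant(vol: LabelVolume, implant: ImplantSpec) -> LabelVolume:
    """Rasterize the implant into a copy of the volume.

    The lead conductor is a 26-connected voxel chain along the path (at least
    one voxel wide regardless of grid coarseness), wrapped by insulation
    voxels everywhere except at electrode contacts, where annular cuff
    electrodes touch tissue.  All other voxels keep their original label.
    """
    path = implant.lead_path
    if len(path) < 2:
        return vol.copy()
    # pre: the lead must lie inside the body
    idx = np.rint(vol.index_coords(path)).astype(int)
    for v, ijk in zip(path, idx):
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(vol.shape)) or vol.data[tuple(ijk)] == 0:
            raise ValueError(f"lead path exits the body at vertex {tuple(float(x) for x in v)} mm")

    out = vol.copy()
    new_map = dict(out.label_map)
    new_map[implant.conductor_id] = IMPLANT_LABELS[CONDUCTOR_ID]
    new_map[implant.insulation_id] = IMPLANT_LABELS[INSULATION_ID]
    new_map[implant.electrode_id] = IMPLANT_LABELS[ELECTRODE_ID]

    lead_r = implant.lead_diameter_mm / 2.0
    conductor = _within_radius_of_path(vol, path, lead_r)
    for ijk in _supercover_voxels(vol, path):
        conductor[ijk] = True

    # insulation: distance shell around the lead, plus a 1-voxel wrap so the
    # conductor chain is covered even on grids coarser than the insulation
    insul = _within_radius_of_path(vol, path, lead_r + implant.insulation_thickness_mm)
    insul |= ndimage.binary_dilation(conductor, structure=np.ones((3, 3, 3), dtype=bool))
    insul &= ~conductor

    # cuff electrodes: annuli centered on the nerve trajectory (local lead axis)
    electrode = np.zeros(vol.shape, dtype=bool)
    contact_zone = np.zeros(vol.shape, dtype=bool)
    r_out = implant.electrode_diameter_mm / 2.0
    r_in = max(r_out - implant.electrode_thickness_mm, 0.0)
    for s in implant.electrode_positions_mm:
        center, tangent = implant.point_at(s)
        half = implant.electrode_length_mm / 2.0
        seg = np.vstack([center - tangent * half, center + tangent * half])
        annulus = _within_radius_of_path(vol, seg, r_out)
        annulus &= ~_within_radius_of_path(vol, seg, r_in)
        if not annulus.any():  # grid too coarse to resolve the cuff: use nearest voxel
            ijk = tuple(np.clip(np.rint(vol.index_coords(center)[0]).astype(int), 0, np.asarray(vol.shape) - 1))
            annulus[ijk] = True
        electrode |= annulus
        contact_zone |= _within_radius_of_path(vol, seg, r_out + max(vol.spacing_mm))
    insul &= ~contact_zone  # insulation is open at the electrode contact faces

    body = out.data > 0
    out.data[insul & body] = implant.insulation_id
    out.data[conductor & body] = implant.conductor_id
    out.data[electrode & body] = implant.electrode_id

    if implant.ipg_center_mm is not None:
        c = np.asarray(implant.ipg_center_mm)
        s = np.asarray(implant.ipg_size_mm) / 2.0
        ipg = _box_mask(vol, c - s, c + s)
        out.data[ipg & body] = implant.conductor_id
    out.label_map = {k: v for k, v in new_map.items() if k in set(np.unique(out.data).tolist())}
    return out


def _box_mask(vol: LabelVolume, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    sp = np.asarray(vol.spacing_mm)
    org = np.asarray(vol.origin_mm)
    i0 = np.maximum(np.ceil((lo - org) / sp - 0.0), 0).astype(int)
    i1 = np.minimum(np.floor((hi - org) / sp) + 1, vol.shape).astype(int)
    mask = np.zeros(vol.shape, dtype=bool)
    if np.all(i0 < i1):
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = True
    return mask


# --------------------------------------------------------------------------- cleanup


def body_mask_from_labels(vol: LabelVolume) -> np.ndarray:
    """Interior mask: labeled voxels with enclosed cavities filled."""
    return ndimage.binary_fill_holes(vol.data > 0)


def fill_unlabeled(vol: LabelVolume, body_mask: np.ndarray) -> tuple[LabelVolume, int]:
    """Replace unlabeled interior voxels with the modal label of their neighborhood.

    Each zero voxel inside ``body_mask`` is assigned the most frequent
    nonzero label among its 26 neighbors; the pass is iterated until no
    fillable voxels remain.  Ties are broken toward the smallest tissue ID.
    Returns the filled volume and the number of voxels filled.  Raises if an
    interior zero component has no labeled neighbor at any iteration.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if body_mask.shape != vol.shape:
        raise ValueError("body_mask shape mismatch")
    data = vol.data.copy()
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    labels = sorted(set(np.unique(data).tolist()) - {0})
    n_filled = 0
    while True:
        holes = (data == 0) & body_mask
        n_holes = int(holes.sum())
        if n_holes == 0:
            break
        best_count = np.zeros(vol.shape, dtype=np.float32)
        best_label = np.zeros(vol.shape, dtype=data.dtype)
        for lid in labels:  # ascending IDs + strict '>' == smallest-ID tie-break
            cnt = ndimage.convolve((data == lid).astype(np.float32), kernel, mode="constant")
            take = holes & (cnt > best_count)
            best_count[take] = cnt[take]
            best_label[take] = lid
        fillable = holes & (best_count > 0)
        n_new = int(fillable.sum())
        if n_new == 0:
            sizes = [int(s) for s in np.bincount(ndimage.label(holes)[0].ravel())[1:] if s > 0]
            raise ValueError(
                f"unlabeled interior component(s) with no labeled neighbor; component sizes {sizes}"
            )
        data[fillable] = best_label[fillable]
        n_filled += n_new
    return LabelVolume(data, vol.spacing_mm, vol.origin_mm, dict(vol.label_map)), n_filled


def resample_labels(vol: LabelVolume, target_spacing_mm) -> LabelVolume:
    """Nearest-neighbor resampling to a new voxel spacing.

    The sampled world extent (outer voxel corners) is preserved to within
    one voxel; voxel centers of the new grid are looked up in the old grid
    by rounding, so a uniform-label region never acquires new labels.
    """
    if np.isscalar(target_spacing_mm):
        target_spacing_mm = (target_spacing_mm,) * 3
    new_sp = np.asarray([float(s) for s in target_spacing_mm])
    if np.any(new_sp <= 0):
        raise ValueError("target spacing must be strictly positive")
    old_sp = np.asarray(vol.spacing_mm)
    old_org = np.asarray(vol.origin_mm)
    if np.allclose(new_sp, old_sp):
        return vol.copy()
    corner = old_org - old_sp / 2.0
    extent = np.asarray(vol.shape) * old_sp
    new_shape = np.maximum(np.rint(extent / new_sp).astype(int), 1)
    new_org = corner + new_sp / 2.0
    idx = [
        np.clip(np.rint((new_org[d] + np.arange(new_shape[d]) * new_sp[d] - old_org[d]) / old_sp[d]).astype(int),
                0, vol.shape[d] - 1)
        for d in range(3)
    ]
    data = vol.data[np.ix_(idx[0], idx[1], idx[2])]
    label_map = {k: v for k, v in vol.label_map.items() if k in set(np.unique(data).tolist())}
    return LabelVolume(data, tuple(new_sp), tuple(new_org), label_map)


# --------------------------------------------------------------------------- defaults


def default_child_spec(spacing_mm: float = 2.0, rng_seed: int = 0) -> PhantomSpec:
    """A ~86 cm, ~13 kg two-to-three-year-old stand-in phantom.

    Head: nested skin/skull/CSF/grey-matter/white-matter ellipsoid shells on
    a neck cylinder.  Torso: elliptic skin/fat/muscle cylinders containing
    two lungs, a heart, and a spine column.  Two legs with a bone core
    complete the 861 mm standing height.  Organ sizes are set so the brain
    is ~1.1 L and the heart ~53 cm3, in the range tabulated for this age.
    """
    shells = [
        # legs (z = 0 .. 380)
        Shell("Skin", "cylinder", dict(center=(-52, 0, 190), radii=(40, 40), length=380, axis="z")),
        Shell("Skin", "cylinder", dict(center=(52, 0, 190), radii=(40, 40), length=380, axis="z")),
        Shell("Muscle", "cylinder", dict(center=(-52, 0, 190), radii=(33, 33), length=364, axis="z")),
        Shell("Muscle", "cylinder", dict(center=(52, 0, 190), radii=(33, 33), length=364, axis="z")),
        Shell("Bone (Cortical)", "cylinder", dict(center=(-52, 0, 190), radii=(9, 9), length=356, axis="z")),
        Shell("Bone (Cortical)", "cylinder", dict(center=(52, 0, 190), radii=(9, 9), length=356, axis="z")),
        # torso (z = 380 .. 645)
        Shell("Skin", "cylinder", dict(center=(0, 0, 512.5), radii=(100, 65), length=265, axis="z")),
        Shell("Fat", "cylinder", dict(center=(0, 0, 512.5), radii=(94, 59), length=253, axis="z")),
        Shell("Muscle", "cylinder", dict(center=(0, 0, 512.5), radii=(86, 52), length=245, axis="z")),
        Shell("Bone (Cortical)", "cylinder", dict(center=(0, -40, 512.5), radii=(10, 10), length=245, axis="z")),
        Shell("Lung", "ellipsoid", dict(center=(-58, -5, 565), semiaxes=(26, 38, 72))),
        Shell("Lung", "ellipsoid", dict(center=(58, -5, 565), semiaxes=(26, 38, 72))),
        Shell("Heart Muscle", "ellipsoid", dict(center=(8, 0, 535), semiaxes=(22, 23, 25))),
        # neck (z = 645 .. 702)
        Shell("Skin", "cylinder", dict(center=(0, 0, 673.5), radii=(36, 36), length=57, axis="z")),
        Shell("Muscle", "cylinder", dict(center=(0, 0, 673.5), radii=(30, 30), length=57, axis="z")),
        Shell("Bone (Cortical)", "cylinder", dict(center=(0, -10, 673.5), radii=(8, 8), length=57, axis="z")),
        # head (center z = 780, crown 858)
        Shell("Skin", "ellipsoid", dict(center=(0, 0, 780), semiaxes=(74, 87, 78))),
        Shell("Bone (Cortical)", "ellipsoid", dict(center=(0, 0, 780), semiaxes=(68, 81, 72))),
        Shell("Cerebrospinal Fluid", "ellipsoid", dict(center=(0, 0, 780), semiaxes=(63, 76, 67))),
        Shell("Brain (Grey Matter)", "ellipsoid", dict(center=(0, 0, 780), semiaxes=(58, 71, 62))),
        Shell("Brain (White Matter)", "ellipsoid", dict(center=(0, 0, 780), semiaxes=(45, 55, 48))),
    ]
    sp = float(spacing_mm)
    return PhantomSpec(
        shells=shells,
        spacing_mm=(sp, sp, sp),
        origin_mm=(-118.0, -104.0, -2.0),
        body_height_mm=861.0,
        rng_seed=rng_seed,
    )


def default_vns_spec() -> ImplantSpec:
    """VNS-like implant matched to :func:`default_child_spec` geometry.

    The pulse generator sits in the left upper chest; the lead runs up the
    left side of the neck to two cuff electrodes on the nerve trajectory.
    """
    path = np.array(
        [
            (-45.0, 20.0, 612.0),
            (-30.0, 15.0, 642.0),
            (-18.0, 5.0, 660.0),
            (-18.0, 5.0, 690.0),
        ]
    )
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    total = float(np.sum(seg))
    return ImplantSpec(
        lead_path=path,
        electrode_positions_mm=(total - 16.0, total - 10.0),
        ipg_center_mm=(-45.0, 20.0, 600.0),
        ipg_size_mm=(24.0, 8.0, 24.0),
    )
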