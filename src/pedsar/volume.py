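"""Integer-labeled voxel volumes with world geometry and NIfTI round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume"]


@dataclass
class LabelVolume:
    """A 3D integer tissue-label grid with voxel spacing and world origin.

    Voxel (i, j, k) has its center at ``origin_mm + index * spacing_mm``
    (RAS-like axes, 0-based indices).  Label 0 is background (air outside
    the body); every nonzero label that occurs in ``data`` must have an
    entry in ``label_map``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels present in data but absent from label_map: {sorted(missing)}")

    # ------------------------------------------------------------------ geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Voxel-center world coordinates (mm) for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def index_coords(self, world_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for an (n, 3) array of world points (mm)."""
        pts = np.atleast_2d(np.asarray(world_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    # ------------------------------------------------------------------ labels

    def label_id(self, name: str) -> int:
        for lid, lname in self.label_map.items():
            if lname == name:
                return lid
        raise KeyError(f"no label named {name!r}")

    def mask(self, name_or_id: str | int) -> np.ndarray:
        lid = name_or_id if isinstance(name_or_id, (int, np.integer)) else self.label_id(name_or_id)
        return self.data == lid

    def voxel_counts(self) -> dict[str, int]:
        """Per-tissue voxel counts for all nonzero labels."""
        ids, counts = np.unique(self.data, return_counts=True)
        return {self.label_map[int(i)]: int(c) for i, c in zip(ids, counts) if i != 0}

    def tissue_volumes_cm3(self) -> dict[str, float]:
        vv = self.voxel_volume_mm3 / 1000.0
        return {name: n * vv for name, n in self.voxel_counts().items()}

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing_mm, self.origin_mm, dict(self.label_map))

    # ------------------------------------------------------------------ I/O

    def to_nifti(self, path: str | Path) -> None:
        """Write a NIfTI-1 volume plus a ``.labels.json`` sidecar with the label map."""
        path = Path(path)
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.data.astype(np.int16), affine)
        nib.save(img, str(path))
        sidecar = _sidecar_path(path)
        sidecar.write_text(json.dumps({str(k): v for k, v in self.label_map.items()}, indent=1))

    @classmethod
    def from_nifti(cls, path: str | Path, label_map: dict[int, str] | None = None) -> "LabelVolume":
        path = Path(path)
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        data = np.asarray(img.dataobj).astype(np.int32)
        if label_map is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                label_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
            else:
                label_map = {int(i): f"label_{int(i)}" for i in np.unique(data) if i != 0}
        return cls(data, spacing, origin, label_map)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            return path.with_name(name[: -len(suff)] + ".labels.json")
    return path.with_suffix(".labels.json")
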