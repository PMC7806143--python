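"""Tissue property tables and pediatric dielectric scaling.

Adult tissue dielectric properties (Gabriel-dispersion / IT'IS-consistent
values at 64 and 128 MHz) are shipped as a packaged CSV together with the
child/adult scaling ratios derived from rat dielectric measurements: the
water content of tissue falls with age, so a young child's conductivity and
permittivity exceed the adult values.  Bone, brain, and skin carry their own
measured ratios (conductivity 2.4, 1.6, 1.5; permittivity 1.99, 1.33, 1.29);
other soft tissues use the averaged soft-tissue ratio (1.4 / 1.22); body
fluids (air, bile, blood, CSF, urine) are not scaled.  The same table houses
mass density and 3 T MR relaxation properties (T1, T2, PD) per tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from pedsar.volume import LabelVolume

__all__ = [
    "TissueTable",
    "ChildPropertySet",
    "scale_to_child",
    "tissue_weight",
    "assign_mr_properties",
    "SOFT_TISSUE_FALLBACK_RATIOS",
]

# Averaged scaling ratio among measured soft tissues (conductivity, permittivity):
# the fallback applied to soft tissues without their own published ratios.
SOFT_TISSUE_FALLBACK_RATIOS = {"ratio_sigma": 1.4, "ratio_eps": 1.22}

_COLUMNS = [
    "tissue",
    "f_MHz",
    "sigma_S_per_m",
    "eps_r",
    "ratio_sigma",
    "ratio_eps",
    "density_kg_m3",
    "T1_ms",
    "T2_ms",
    "PD",
]


@dataclass
class TissueTable:
    """Adult per-tissue properties plus pediatric scaling ratios.

    ``df`` has one row per (tissue, frequency); density and MR columns are
    frequency-independent and simply repeated.
    """

    df: pd.DataFrame
    donor_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"tissue table missing columns {missing}")
        self.df = self.df.copy()
        bad = self.df[(self.df.sigma_S_per_m < 0) | (self.df.eps_r < 1)]
        bad = bad[bad.tissue != "Air"]
        if len(bad):
            raise ValueError(f"non-physical dielectric values for {sorted(bad.tissue.unique())}")
        t = self.df.dropna(subset=["T1_ms", "T2_ms"])
        bad_relax = t[t.T2_ms > t.T1_ms]
        if len(bad_relax):
            raise ValueError(f"T2 > T1 for {sorted(bad_relax.tissue.unique())}")

    # ----------------------------------------------------------------- access

    @classmethod
    def default(cls) -> "TissueTable":
        """The packaged adult table (44 tissues at 64 and 128 MHz)."""
        data_dir = resources.files("pedsar") / "data"
        df = pd.read_csv(str(data_dir / "adult_tissue_properties.csv"))
        donors = json.loads((data_dir / "donor_tissues.json").read_text())
        donors.pop("_comment", None)
        return cls(df, donors)

    @classmethod
    def from_csv(cls, path: str | Path, donor_map: dict[str, str] | None = None) -> "TissueTable":
        return cls(pd.read_csv(path), donor_map or {})

    def tissues(self) -> list[str]:
        return sorted(self.df.tissue.unique())

    def resolve(self, tissue: str) -> str:
        """Map a tissue name through the donor table if it has no row of its own."""
        if tissue in set(self.df.tissue):
            return tissue
        if tissue in self.donor_map:
            return self.donor_map[tissue]
        raise KeyError(f"tissue {tissue!r} not in table and no donor assigned")

    def row(self, tissue: str, f_mhz: float | None = None) -> pd.Series:
        name = self.resolve(tissue)
        sub = self.df[self.df.tissue == name]
        if f_mhz is not None:
            sub = sub[sub.f_MHz == f_mhz]
            if sub.empty:
                raise KeyError(f"no {name!r} row at {f_mhz} MHz (table frequencies: "
                               f"{sorted(self.df.f_MHz.unique())})")
        return sub.iloc[0]

    def density(self, tissue: str) -> float:
        return float(self.row(tissue).density_kg_m3)

    def mr_properties(self, tissue: str) -> tuple[float, float, float]:
        r = self.row(tissue)
        return float(r.T1_ms), float(r.T2_ms), float(r.PD)


@dataclass
class ChildPropertySet:
    """Per-tissue pediatric dielectric properties at one frequency."""

    df: pd.DataFrame  # columns: tissue, sigma_S_per_m, eps_r, density_kg_m3
    f_mhz: float
    donor_map: dict[str, str]

    def resolve(self, tissue: str) -> str:
        if tissue in set(self.df.tissue):
            return tissue
        if tissue in self.donor_map:
            return self.donor_map[tissue]
        raise KeyError(f"tissue {tissue!r} not in child property set and no donor assigned")

    def row(self, tissue: str) -> pd.Series:
        return self.df[self.df.tissue == self.resolve(tissue)].iloc[0]

    def sigma(self, tissue: str) -> float:
        return float(self.row(tissue).sigma_S_per_m)

    def eps_r(self, tissue: str) -> float:
        return float(self.row(tissue).eps_r)

    def density(self, tissue: str) -> float:
        return float(self.row(tissue).density_kg_m3)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def scale_to_child(table: TissueTable, f_mhz: float) -> ChildPropertySet:
    """Scale the adult dielectric table to a ~2.5-year-old at one frequency.

    sigma_child = ratio_sigma * sigma_adult and eps_child = ratio_eps *
    eps_adult, element-wise.  Rows with a missing ratio fall back to the
    averaged soft-tissue ratio; fluids carry ratio 1.0 and pass through
    unchanged.  Density is age-invariant here (the ~1.7% lean-tissue
    difference is treated as an uncertainty, not a model input).
    """
    sub = table.df[table.df.f_MHz == f_mhz].copy()
    if sub.empty:
        raise ValueError(f"table has no rows at {f_mhz} MHz; available: {sorted(table.df.f_MHz.unique())}")
    for col in ("ratio_sigma", "ratio_eps"):
        if sub[col].isna().any():
            missing = sorted(sub[sub[col].isna()].tissue)
            sub[col] = sub[col].fillna(SOFT_TISSUE_FALLBACK_RATIOS[col])
            if sub[col].isna().any():
                raise ValueError(f"no scaling ratio and no fallback for tissues {missing}")
    out = pd.DataFrame(
        {
            "tissue": sub.tissue,
            "sigma_S_per_m": sub.sigma_S_per_m * sub.ratio_sigma,
            "eps_r": sub.eps_r * sub.ratio_eps,
            "density_kg_m3": sub.density_kg_m3,
            "ratio_sigma": sub.ratio_sigma,
            "ratio_eps": sub.ratio_eps,
        }
    ).reset_index(drop=True)
    return ChildPropertySet(out, float(f_mhz), dict(table.donor_map))


def tissue_weight(volume_cm3: float, density_kg_m3: float) -> float:
    """Tissue weight in grams from volume (cm^3) and mass density (kg/m^3)."""
    if volume_cm3 < 0 or density_kg_m3 < 0:
        raise ValueError("volume and density must be non-negative")
    return volume_cm3 * density_kg_m3 / 1000.0  # kg/m^3 == mg/mm^3 == g/1000cm^3 * 1000


def assign_mr_properties(
    vol: LabelVolume, table: TissueTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise T1 (ms), T2 (ms), and proton-density maps from the label volume.

    Background (label 0) is air: PD = 0 and relaxation times 0.  Raises if
    any label's tissue has no MR properties in the table.
    """
    t1 = np.zeros(vol.shape, dtype=np.float64)
    t2 = np.zeros(vol.shape, dtype=np.float64)
    pd_map = np.zeros(vol.shape, dtype=np.float64)
    unknown: list[int] = []
    for lid, name in vol.label_map.items():
        mask = vol.data == lid
        if not mask.any():
            continue
        try:
            T1, T2, PD = table.mr_properties(name)
        except KeyError:
            unknown.append(lid)
            continue
        if np.isnan(T1) or np.isnan(T2) or np.isnan(PD):
            if PD == 0 or (not np.isnan(PD) and PD == 0.0):  # air-like: signal-free
                continue
            unknown.append(lid)
            continue
        t1[mask], t2[mask], pd_map[mask] = T1, T2, PD
    if unknown:
        raise KeyError(f"labels without MR properties: {sorted(unknown)} "
                       f"({[vol.label_map[i] for i in sorted(unknown)]})")
    return t1, t2, pd_map
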