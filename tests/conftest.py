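import numpy as np
import pandas as pd
import pytest

from pedsar.fdtd import CoilSpec, GridSpec, run_fdtd
from pedsar.tissues import ChildPropertySet, TissueTable
from pedsar.volume import LabelVolume


def make_sphere_volume(spacing_mm: float, radius_mm: float = 60.0, extent_mm: float = 150.0,
                       tissue: str = "TestMedium") -> LabelVolume:
    """Homogeneous sphere centered at the world origin."""
    n = int(extent_mm / spacing_mm) * 2 + 1
    ax = (np.arange(n) - n // 2) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    data = ((X**2 + Y**2 + Z**2) <= radius_mm**2).astype(np.int16)
    return LabelVolume(data, (spacing_mm,) * 3, (ax[0], ax[0], ax[0]), {1: tissue})


def sphere_props(sigma=0.5, eps_r=5.0, rho=1000.0) -> ChildPropertySet:
    """Single-medium property set for the conducting-sphere oracle scenes;
    weakly polarizable so the quasi-static eddy-current solution applies."""
    df = pd.DataFrame(
        {"tissue": ["TestMedium"], "sigma_S_per_m": [sigma], "eps_r": [eps_r],
         "density_kg_m3": [rho]}
    )
    return ChildPropertySet(df, 64.0, {})


@pytest.fixture(scope="session")
def tissue_table() -> TissueTable:
    return TissueTable.default()


@pytest.fixture(scope="session")
def vacuum_fields_8mm():
    """Empty birdcage solved at 8 mm (quadrature-mode reference)."""
    return run_fdtd(None, None, CoilSpec(), GridSpec(spacing_mm=8.0))


@pytest.fixture(scope="session")
def sphere_fields_4mm():
    """Conducting sphere (sigma 0.5 S/m, rho 1000 kg/m3, R 60 mm) in the coil
    at the resolved 4 mm desk grid; shared by the quasi-static SAR check,
    energy bookkeeping, and the normalization tests."""
    vol = make_sphere_volume(4.0)
    return run_fdtd(vol, sphere_props(), CoilSpec(), GridSpec(spacing_mm=4.0, anchor_world_mm=(0, 0, 0)))


@pytest.fixture(scope="session")
def sphere_fields_8mm():
    """Same sphere scene at 8 mm, for the grid-refinement comparison."""
    vol = make_sphere_volume(8.0)
    return run_fdtd(vol, sphere_props(), CoilSpec(), GridSpec(spacing_mm=8.0, anchor_world_mm=(0, 0, 0)))
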