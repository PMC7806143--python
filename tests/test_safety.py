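import numpy as np
import pytest

from pedsar import safety
from pedsar.fdtd import FieldPhasor


def _uniform_fields(shape=(10, 10, 10), e0=100.0, spacing=4.0, sigma=0.5, rho=1000.0):
    E = np.zeros((3, *shape), complex)
    E[0] = e0
    B = np.zeros((3, *shape), complex)
    B[0] = 2e-6
    B[1] = -2e-6j
    org = tuple(-(s - 1) / 2.0 * spacing for s in shape)
    return FieldPhasor(
        E=E, B=B, f0_hz=64e6, spacing_mm=spacing, origin_mm=org,
        labels=np.ones(shape, np.int32), sigma=np.full(shape, sigma),
        eps_r=np.full(shape, 50.0), rho=np.full(shape, rho),
        tissue_mask=np.ones(shape, bool),
    )


# --------------------------------------------------------------------------- point & regional SAR


def test_point_sar_examples():
    E = np.zeros((3, 1, 1, 1), complex)
    assert safety.point_sar(E, np.zeros((1, 1, 1)), np.ones((1, 1, 1))) == 0.0
    E[0] = 100.0
    sar = safety.point_sar(E, np.full((1, 1, 1), 0.5), np.full((1, 1, 1), 1000.0))
    assert sar[0, 0, 0] == pytest.approx(2.5)  # sigma |E|^2 / (2 rho)
    sar4 = safety.point_sar(2 * E, np.full((1, 1, 1), 0.5), np.full((1, 1, 1), 1000.0))
    assert sar4[0, 0, 0] == pytest.approx(10.0)


def test_regional_sar_weighted_mean():
    sar = np.array([1.0, 3.0])[:, None, None] * np.ones((2, 2, 2))
    rho = np.ones((2, 2, 2))
    assert safety.regional_sar(sar, np.ones((2, 2, 2), bool), rho) == pytest.approx(2.0)
    assert safety.regional_sar(np.full((2, 2, 2), 5.0), np.ones((2, 2, 2), bool), rho) == 5.0
    with pytest.raises(ValueError, match="empty"):
        safety.regional_sar(sar, np.zeros((2, 2, 2), bool), rho)


# --------------------------------------------------------------------------- 10g cube averaging


def _brute_force_10g(quantity, rho, tissue, vv, target=0.010):
    """Independent naive cube-growth oracle with exact-mass interpolation."""
    n = quantity.shape
    out = np.full(n, np.nan)
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                if not tissue[i, j, k]:
                    continue
                prev_m = prev_qm = 0.0
                for r in range(max(n) + 1):
                    sl = tuple(slice(max(0, c - r), min(s, c + r + 1))
                               for c, s in zip((i, j, k), n))
                    t = tissue[sl]
                    m = float(np.sum(rho[sl][t]) * vv)
                    qm = float(np.sum((quantity[sl] * rho[sl])[t]) * vv)
                    if m >= target:
                        frac = (target - prev_m) / (m - prev_m) if m > prev_m else 0.0
                        out[i, j, k] = (prev_qm + frac * (qm - prev_qm)) / target
                        break
                    prev_m, prev_qm = m, qm
    return out


def test_10g_uniform_field_is_identity():
    shape = (12, 12, 12)
    sar = np.full(shape, 3.0)
    rho = np.full(shape, 1000.0)
    tissue = np.ones(shape, bool)
    vv = (8e-3) ** 3  # 0.512 g voxels
    m, mx, _ = safety.sar_10g(sar, rho, tissue, vv)
    assert np.allclose(m[~np.isnan(m)], 3.0)
    assert mx == pytest.approx(3.0)


def test_10g_hot_voxel_dilution_identity():
    shape = (15, 15, 15)
    sar = np.zeros(shape)
    sar[7, 7, 7] = 100.0
    rho = np.full(shape, 1000.0)
    tissue = np.ones(shape, bool)
    vv = (5e-3) ** 3  # 0.125 g per voxel << 10 g
    m_vox = 1000.0 * vv
    m, mx, loc = safety.sar_10g(sar, rho, tissue, vv)
    assert mx == pytest.approx(100.0 * m_vox / 0.010, rel=1e-9)
    # the hot voxel itself attains the max (ties with neighbors whose exact-10g
    # cube contains the full hot mass are allowed)
    assert m[7, 7, 7] == pytest.approx(mx, rel=1e-9)
    assert m[loc] == pytest.approx(mx, rel=1e-9)


def test_10g_matches_brute_force_oracle_on_random_fields():
    rng = np.random.default_rng(0)
    shape = (8, 8, 8)
    vv = (9e-3) ** 3  # ~0.73-0.95 g voxels: 10 g needs a dozen voxels
    for trial in range(20):
        sar = rng.gamma(2.0, 1.0, shape)
        rho = rng.uniform(900, 1300, shape)
        tissue = rng.random(shape) < 0.9
        got, gmax, _ = safety.sar_10g(sar, rho, tissue, vv)
        want = _brute_force_10g(sar, rho, tissue, vv)
        assert np.allclose(got, want, equal_nan=True), f"trial {trial}"
        e = np.sqrt(np.sum(np.abs(np.stack([sar, 0 * sar, 0 * sar])) ** 2, axis=0) / 2)
        got_e, _, _ = safety.e_10g_rms(np.stack([sar + 0j, 0 * sar, 0 * sar]), rho, tissue, vv)
        want_e = _brute_force_10g(e, rho, tissue, vv)
        assert np.allclose(got_e, want_e, equal_nan=True)


def test_10g_invalid_when_domain_mass_insufficient():
    shape = (3, 3, 3)
    rho = np.full(shape, 1000.0)
    vv = (2e-3) ** 3  # 27 voxels x 8 mg = 0.2 g < 10 g
    m, mx, _ = safety.sar_10g(np.ones(shape), rho, np.ones(shape, bool), vv)
    assert np.all(np.isnan(m))
    assert np.isnan(mx)


def test_e10g_scales_linearly_with_field():
    f = _uniform_fields()
    vv = (f.spacing_mm * 1e-3) ** 3
    _, e1, _ = safety.e_10g_rms(f.E, f.rho, f.tissue_mask, vv)
    _, e3, _ = safety.e_10g_rms(3.0 * f.E, f.rho, f.tissue_mask, vv)
    assert e3 == pytest.approx(3 * e1)
    assert e1 == pytest.approx(100.0 / np.sqrt(2))  # rms of a uniform 100 V/m peak phasor


# --------------------------------------------------------------------------- invariants


def test_global_phase_rotation_leaves_all_quantities_unchanged():
    f = _uniform_fields()
    rot = f.scaled(np.exp(1j * 1.234), f.normalization)
    a = safety.evaluate_safety(f)
    b = safety.evaluate_safety(rot)
    assert a.sar_wb == pytest.approx(b.sar_wb)
    assert a.sar10g_max == pytest.approx(b.sar10g_max)
    assert a.e10g_max == pytest.approx(b.e10g_max)


def test_energy_bookkeeping_identity_on_synthetic_fields():
    rng = np.random.default_rng(5)
    shape = (9, 9, 9)
    E = rng.normal(size=(3, *shape)) + 1j * rng.normal(size=(3, *shape))
    f = _uniform_fields(shape)
    f = FieldPhasor(E=E * 50, B=f.B, f0_hz=64e6, spacing_mm=f.spacing_mm, origin_mm=f.origin_mm,
                    labels=f.labels, sigma=f.sigma, eps_r=f.eps_r, rho=f.rho,
                    tissue_mask=f.tissue_mask)
    res = safety.evaluate_safety(f)
    vv = (f.spacing_mm * 1e-3) ** 3
    total_power = float(np.sum(f.sigma * np.sum(np.abs(f.E) ** 2, axis=0) / 2.0) * vv)
    assert res.sar_wb * res.body_mass_kg == pytest.approx(total_power, rel=1e-9)


def test_sar_hierarchy_10g_between_wb_and_pointwise(sphere_fields_8mm):
    from pedsar.fdtd import normalize_b1

    res = safety.evaluate_safety(normalize_b1(sphere_fields_8mm))
    assert res.sar_wb <= res.sar10g_max <= res.sar_map.max() + 1e-12


# --------------------------------------------------------------------------- comparisons & helpers


def _result_like(**kw):
    base = dict(sar_map=np.zeros((1, 1, 1)), sar_head=0.0, sar_wb=0.0,
                sar10g_map=np.zeros((1, 1, 1)), sar10g_max=0.0, sar10g_argmax=(0, 0, 0),
                e10g_map=np.zeros((1, 1, 1)), e10g_max=0.0, e10g_argmax=(0, 0, 0),
                normalization="B1_2uT", head_mass_kg=1.0, body_mass_kg=5.0)
    base.update(kw)
    return safety.SARResult(**base)


def test_compare_implant_percent_deltas():
    with_i = _result_like(sar10g_max=0.7137, sar_head=0.2064)
    without = _result_like(sar10g_max=0.4858, sar_head=0.2046)
    rep = safety.compare_implant(with_i, without)
    assert rep["sar10g_max"]["percent"] == pytest.approx(46.91, abs=0.05)
    assert rep["sar_head"]["percent"] == pytest.approx(0.88, abs=0.01)
    same = safety.compare_implant(without, without)
    assert all(v["percent"] == 0 and v["delta"] == 0 for v in same.values())


def test_tangential_e_profiles():
    f = _uniform_fields(shape=(20, 20, 20), e0=100.0)  # E along +x
    # straight path along x: tangential = |E|
    path = np.array([[-30.0, 0, 0], [30.0, 0, 0]])
    _, et = safety.tangential_e(f, path, n_samples=50)
    assert np.allclose(np.abs(et), 100.0)
    # straight path along y: perpendicular -> 0
    path = np.array([[0, -30.0, 0], [0, 30.0, 0]])
    _, et = safety.tangential_e(f, path, n_samples=50)
    assert np.allclose(np.abs(et), 0.0)
    # semicircle in the xy-plane: |cos(angle)| profile
    theta = np.linspace(0, np.pi, 80)
    pts = np.stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros_like(theta)], axis=1)
    s, et = safety.tangential_e(f, pts, n_samples=80)
    frac = s / s[-1]
    expect = 100.0 * np.abs(np.sin(np.pi * frac))  # tangent dot x-hat = -sin(theta)
    assert np.allclose(np.abs(et[2:-2]), expect[2:-2], atol=2.5)


def test_sensitivity_scan_density_law_and_inert_parameter():
    f = _uniform_fields()
    vv = (f.spacing_mm * 1e-3) ** 3

    def run(cfg):
        rho = f.rho * cfg.get("density_scale", 1.0)
        sar = safety.point_sar(f.E * cfg.get("air_density_scale", 1.0) ** 0, f.sigma, rho)
        return {"sar_wb": safety.regional_sar(sar, f.tissue_mask, rho)}

    # analytic 1/rho dependence: d ln(SAR) / d ln(rho) = -1
    sens = safety.sensitivity_scan(run, {"density_scale": 1.0}, "density_scale", 1.7)
    assert sens["sar_wb"] == pytest.approx(1.0, abs=0.01)
    inert = safety.sensitivity_scan(run, {"air_density_scale": 1.0}, "air_density_scale", 5.0)
    assert inert["sar_wb"] == 0.0


def test_mip_properties(tmp_path):
    vol = np.zeros((6, 7, 8))
    vol[2, 3, 4] = 9.0
    img = safety.mip(vol, axis=1, png_path=tmp_path / "m.png")
    assert img.shape == (6, 8)
    assert img[2, 4] == 9.0
    assert img.max() == vol.max()
    assert (tmp_path / "m.png").exists()
    assert np.allclose(safety.mip(np.full((3, 3, 3), 2.0), 0), 2.0)


def test_safety_margin_helper():
    assert safety.apply_safety_margin(3.2) == pytest.approx(3.2 / 1.5)
    assert safety.SAFETY_MARGIN == 1.5
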