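import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from pedsar import segqc
from pedsar.volume import LabelVolume


# --------------------------------------------------------------------------- Dice


def test_dice_identity_and_disjoint():
    a = np.zeros((4, 4, 4), bool)
    a[1:3, 1:3, 1:3] = True
    assert segqc.dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert segqc.dice(a, b) == 0.0


def test_dice_hand_computed_formula():
    # |X| = 3, |Y| = 5, |X ∩ Y| = 2 -> 2*2/8 = 0.5
    x = np.zeros(10, bool)
    y = np.zeros(10, bool)
    x[:3] = True
    y[1:6] = True
    assert segqc.dice(x, y) == pytest.approx(0.5)


def test_dice_both_empty_is_one_and_shape_mismatch_raises():
    assert segqc.dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0
    with pytest.raises(ValueError, match="shapes"):
        segqc.dice(np.zeros((2, 2), bool), np.zeros((3, 2), bool))


def test_dice_agrees_with_set_oracle_on_random_masks():
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.random((8, 8, 8)) < rng.uniform(0.05, 0.6)
        y = rng.random((8, 8, 8)) < rng.uniform(0.05, 0.6)
        xs = set(map(tuple, np.argwhere(x)))
        ys = set(map(tuple, np.argwhere(y)))
        expect = 1.0 if not (xs or ys) else 2 * len(xs & ys) / (len(xs) + len(ys))
        assert segqc.dice(x, y) == pytest.approx(expect)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    x=hnp.arrays(bool, (5, 5, 5), elements=st.booleans()),
    y=hnp.arrays(bool, (5, 5, 5), elements=st.booleans()),
)
def test_dice_symmetric_bounded_and_maximal_on_equality(x, y):
    d = segqc.dice(x, y)
    assert 0.0 <= d <= 1.0
    assert d == segqc.dice(y, x)
    assert segqc.dice(x, x) == 1.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    measured=st.floats(0.1, 1e4),
    lo=st.floats(0.1, 1e4),
    width=st.floats(0.0, 1e3),
)
def test_percent_difference_nonnegative_and_zero_inside_range(measured, lo, width):
    hi = lo + width
    pct = segqc.percent_difference(measured, lo, hi)
    assert pct >= 0.0
    assert (pct == 0.0) == (lo <= measured <= hi)


def test_dsc_quality_classes():
    assert segqc.dsc_class(0.95) == "excellent"
    assert segqc.dsc_class(0.9) == "excellent"
    assert segqc.dsc_class(0.85) == "acceptable"
    assert segqc.dsc_class(0.8) == "poor"  # strictly greater than 0.8 is acceptable


# --------------------------------------------------------------------------- Hausdorff


def _brute_force_avg_hd(x, y, spacing):
    """All-pairs oracle: mean nearest boundary distance, symmetrized."""
    sp = np.asarray(spacing, dtype=float)

    def boundary(m):
        er = ndimage.binary_erosion(m, ndimage.generate_binary_structure(m.ndim, 1), border_value=0)
        return np.argwhere(m & ~er) * sp[: m.ndim]

    bx, by = boundary(x), boundary(y)
    d_xy = np.mean([min(np.linalg.norm(p - q) for q in by) for p in bx])
    d_yx = np.mean([min(np.linalg.norm(p - q) for q in bx) for p in by])
    return 0.5 * (d_xy + d_yx)


def test_hausdorff_identical_masks_zero():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    assert segqc.hausdorff_avg(m, m) == 0.0
    assert segqc.hausdorff_max(m, m) == 0.0


def test_parallel_plates_distance():
    # two 1-voxel plates 4 voxels apart at 1 mm spacing -> 4.0 mm
    x = np.zeros((8, 6, 6), bool)
    y = np.zeros((8, 6, 6), bool)
    x[1] = True
    y[5] = True
    assert segqc.hausdorff_avg(x, y, (1, 1, 1)) == pytest.approx(4.0)
    assert segqc.hausdorff_avg(x, y, (1, 1, 1)) == pytest.approx(_brute_force_avg_hd(x, y, (1, 1, 1)))


def test_hausdorff_symmetric_and_empty_raises():
    rng = np.random.default_rng(3)
    x = rng.random((6, 6, 6)) < 0.3
    y = rng.random((6, 6, 6)) < 0.3
    assert segqc.hausdorff_avg(x, y) == pytest.approx(segqc.hausdorff_avg(y, x))
    with pytest.raises(ValueError, match="nonempty"):
        segqc.hausdorff_avg(x, np.zeros_like(y))


def test_hausdorff_avg_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    spacing = (1.0, 0.5, 2.0)
    for _ in range(25):
        x = ndimage.binary_dilation(rng.random((10, 10, 10)) < 0.02)
        y = ndimage.binary_dilation(rng.random((10, 10, 10)) < 0.02)
        if not (x.any() and y.any()):
            continue
        assert segqc.hausdorff_avg(x, y, spacing) == pytest.approx(
            _brute_force_avg_hd(x, y, spacing))


# --------------------------------------------------------------------------- inter-operator


def _two_tissue_volume(shift=0):
    data = np.zeros((16, 16, 16), np.int16)
    data[3 + shift:8 + shift, 3:8, 3:8] = 1
    data[10:14, 10:14, 10:14] = 2
    return LabelVolume(data, (1, 1, 1), (0, 0, 0), {1: "Liver", 2: "Spleen"})


def test_identical_operators_perfect_scores():
    truth = _two_tissue_volume()
    df = segqc.interoperator_report({"a": truth, "b": truth}, truth, ["Liver", "Spleen"])
    assert np.allclose(df.dsc, 1.0)
    assert np.allclose(df.hausdorff_avg_mm, 0.0)
    assert df.attrs["dsc_sd"] == 0.0


def test_dsc_decreases_monotonically_with_dilation():
    truth = _two_tissue_volume()
    dscs = []
    for k in (0, 1, 2):
        data = truth.data.copy()
        if k:
            m = ndimage.binary_dilation(truth.data == 1, iterations=k)
            data[m] = 1
        op = LabelVolume(data, (1, 1, 1), (0, 0, 0), dict(truth.label_map))
        df = segqc.interoperator_report([op], truth, ["Liver"])
        dscs.append(df.dsc.iloc[0])
    assert dscs[0] > dscs[1] > dscs[2]


def test_single_cell_sd_flagged_undefined():
    truth = _two_tissue_volume()
    df = segqc.interoperator_report([truth], truth, ["Liver"])
    assert df.attrs["sd_undefined"]
    assert np.isnan(df.attrs["dsc_sd"])
    assert df.dsc.iloc[0] == 1.0


def test_coronal_slice_mode_runs():
    truth = _two_tissue_volume()
    op = _two_tissue_volume(shift=1)
    df3 = segqc.interoperator_report([op], truth, ["Liver"], mode="3d")
    df2 = segqc.interoperator_report([op], truth, ["Liver"], mode="2d")
    assert 0 < df2.dsc.iloc[0] < 1 and 0 < df3.dsc.iloc[0] < 1


# --------------------------------------------------------------------------- morphometry


def test_percent_difference_conventions():
    assert segqc.percent_difference(1052, 1064) == pytest.approx(100 * 12 / 1064)
    assert segqc.percent_difference(108.7, 110, 120) == pytest.approx(100 * 1.3 / 110)
    assert segqc.percent_difference(335, 299.7, 426.2) == 0.0
    assert segqc.percent_difference(130, 110, 120) == pytest.approx(100 * 10 / 120)


def test_validation_rows_reproduce_reported_differences():
    measurements = pd.DataFrame(
        [
            ("Brain", "weight", 1052, "g"),
            ("Brain CSF", "volume", 108.7, "cm3"),
            ("Liver", "volume", 335, "cm3"),
            ("Spleen", "weight", 38.5, "g"),
        ],
        columns=["tissue", "type", "value", "units"],
    )
    references = pd.DataFrame(
        [
            ("Brain", "weight", 1064, 1064, "g"),
            ("Brain CSF", "volume", 110, 120, "cm3"),
            ("Liver", "volume", 299.7, 426.2, "cm3"),
            ("Spleen", "weight", 37, 37, "g"),
        ],
        columns=["tissue", "type", "ref_low", "ref_high", "units"],
    )
    rows = segqc.validate_morphometry(measurements, references)
    by_tissue = {r.tissue: r for r in rows}
    assert by_tissue["Brain"].percent_difference == 1.1
    assert by_tissue["Brain CSF"].percent_difference == 1.2
    assert by_tissue["Liver"].percent_difference == 0.0
    assert by_tissue["Liver"].within_range
    assert by_tissue["Spleen"].percent_difference == 4.1


def test_missing_reference_raises():
    m = pd.DataFrame([("Thing", "weight", 1.0, "g")], columns=["tissue", "type", "value", "units"])
    r = pd.DataFrame(columns=["tissue", "type", "ref_low", "ref_high", "units"])
    with pytest.raises(KeyError):
        segqc.validate_morphometry(m, r)
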