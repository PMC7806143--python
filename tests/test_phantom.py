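import numpy as np
import pytest

from pedsar import phantom as ph
from pedsar.volume import LabelVolume


def _single_sphere_spec(radius=50.0, spacing=2.0):
    shells = [ph.Shell("Muscle", "ellipsoid", dict(center=(0, 0, 0), semiaxes=(radius,) * 3))]
    return ph.PhantomSpec(shells=shells, spacing_mm=(spacing,) * 3,
                          origin_mm=(-radius - 6,) * 3, rng_seed=0)


def test_sphere_volume_matches_analytic():
    radius = 50.0
    vol = ph.build_phantom(_single_sphere_spec(radius, 2.0))
    measured = vol.voxel_counts()["Muscle"] * vol.voxel_volume_mm3
    analytic = 4.0 / 3.0 * np.pi * radius**3
    assert abs(measured - analytic) / analytic < 0.05


def test_empty_shell_list_gives_empty_volume():
    vol = ph.build_phantom(ph.PhantomSpec(shells=[], shape=(4, 4, 4)))
    assert vol.label_map == {}
    assert not vol.data.any()


def test_build_deterministic_for_fixed_seed():
    spec = ph.default_child_spec(4.0, rng_seed=7)
    a = ph.build_phantom(spec)
    b = ph.build_phantom(spec)
    assert np.array_equal(a.data, b.data)


def test_equal_priority_overlap_raises_with_pair_named():
    shells = [
        ph.Shell("Fat", "ellipsoid", dict(center=(0, 0, 0), semiaxes=(10, 10, 10)), priority=1),
        ph.Shell("Muscle", "ellipsoid", dict(center=(5, 0, 0), semiaxes=(10, 10, 10)), priority=1),
    ]
    spec = ph.PhantomSpec(shells=shells, spacing_mm=(2, 2, 2), origin_mm=(-20, -20, -20))
    with pytest.raises(ValueError, match="'Fat' and 'Muscle'"):
        ph.build_phantom(spec)


def test_default_child_phantom_anatomy():
    vol = ph.build_phantom(ph.default_child_spec(4.0))
    names = set(vol.label_map.values())
    assert {"Skin", "Bone (Cortical)", "Cerebrospinal Fluid", "Brain (Grey Matter)",
            "Brain (White Matter)", "Muscle", "Fat", "Lung", "Heart Muscle"} <= names
    nz = np.argwhere(vol.data > 0)
    height = (nz[:, 2].max() - nz[:, 2].min() + 1) * vol.spacing_mm[2]
    assert 820 <= height <= 880  # ~86 cm standing height


# --------------------------------------------------------------------------- implant


def _muscle_block(spacing=0.3, size_mm=50.0):
    n = int(size_mm / spacing)
    data = np.ones((n, n, n), dtype=np.int16)
    return LabelVolume(data, (spacing,) * 3, (0, 0, 0), {1: "Muscle"})


def _chain_26_connected(voxels: set[tuple[int, int, int]], start, end) -> bool:
    """Graph-traversal oracle: BFS over 26-neighborhood from start to end."""
    frontier = [start]
    seen = {start}
    while frontier:
        cur = frontier.pop()
        if cur == end:
            return True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    nxt = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                    if nxt in voxels and nxt not in seen:
                        seen.add(nxt)
                        frontier.append(nxt)
    return False


def test_straight_lead_conductor_chain_is_26_connected():
    vol = _muscle_block(0.3)
    path = np.array([[10.0, 25.0, 5.0], [10.0, 25.0, 45.0]])  # 40 mm straight lead
    out = ph.insert_implant(vol, ph.ImplantSpec(lead_path=path))
    cond = np.argwhere(out.data == ph.CONDUCTOR_ID)
    vox = set(map(tuple, cond))
    start = tuple(cond[np.argmin(cond[:, 2])])
    end = tuple(cond[np.argmax(cond[:, 2])])
    assert _chain_26_connected(vox, start, end)
    # insulation wraps the conductor away from electrode contacts
    insul = out.data == ph.INSULATION_ID
    assert insul.sum() > 0


def test_zero_length_path_returns_input_unchanged():
    vol = _muscle_block(1.0, 20.0)
    out = ph.insert_implant(vol, ph.ImplantSpec(lead_path=np.zeros((1, 3)) + 5.0))
    assert np.array_equal(out.data, vol.data)


def test_cuff_electrode_voxels_within_annulus_diameter():
    vol = _muscle_block(0.2, 30.0)
    path = np.array([[15.0, 15.0, 5.0], [15.0, 15.0, 25.0]])
    spec = ph.ImplantSpec(lead_path=path, electrode_positions_mm=(15.0,))
    out = ph.insert_implant(vol, spec)
    elec = np.argwhere(out.data == ph.ELECTRODE_ID)
    assert len(elec)
    world = out.world_coords(elec)
    r = np.sqrt((world[:, 0] - 15.0) ** 2 + (world[:, 1] - 15.0) ** 2)
    assert np.all(r <= 1.4 / 2.0 + max(out.spacing_mm))  # within the 1.4 mm cuff diameter


def test_lead_path_outside_body_raises_with_vertex():
    vol = _muscle_block(1.0, 20.0)
    path = np.array([[5.0, 5.0, 5.0], [100.0, 5.0, 5.0]])
    with pytest.raises(ValueError, match=r"exits the body at vertex \(100"):
        ph.insert_implant(vol, ph.ImplantSpec(lead_path=path))


def test_implant_alters_only_implant_labeled_voxels():
    vol = ph.build_phantom(ph.default_child_spec(4.0))
    out = ph.insert_implant(vol, ph.default_vns_spec())
    changed = out.data != vol.data
    assert set(np.unique(out.data[changed]).tolist()) <= {ph.CONDUCTOR_ID, ph.INSULATION_ID, ph.ELECTRODE_ID}


# --------------------------------------------------------------------------- fill_unlabeled


def _block_with_hole():
    data = np.full((5, 5, 5), 2, dtype=np.int16)  # muscle
    data[2, 2, 2] = 0
    return LabelVolume(data, (1, 1, 1), (0, 0, 0), {2: "Muscle"})


def test_fill_unanimous_neighborhood():
    vol = _block_with_hole()
    filled, n = ph.fill_unlabeled(vol, np.ones(vol.shape, bool))
    assert n == 1
    assert filled.data[2, 2, 2] == 2


def test_fill_modal_label_wins():
    # 15 fat vs 11 skin neighbors around the hole -> fat
    data = np.zeros((3, 3, 3), dtype=np.int16)
    flat = [1] * 15 + [2] * 11  # fat id 1, skin id 2
    it = iter(flat)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                if (i, j, k) != (1, 1, 1):
                    data[i, j, k] = next(it)
    vol = LabelVolume(data, (1, 1, 1), (0, 0, 0), {1: "Fat", 2: "Skin"})
    filled, n = ph.fill_unlabeled(vol, np.ones(vol.shape, bool))
    assert n == 1
    assert filled.data[1, 1, 1] == 1


def test_fill_tie_breaks_to_smallest_id():
    data = np.zeros((3, 3, 1), dtype=np.int16)
    data[0, :, 0] = 5
    data[2, :, 0] = 3  # 3 neighbors each for labels 3 and 5 around (1,1)
    vol = LabelVolume(data, (1, 1, 1), (0, 0, 0), {3: "A", 5: "B"})
    mask = np.zeros(vol.shape, bool)
    mask[1, 1, 0] = True
    filled, _ = ph.fill_unlabeled(vol, mask)
    assert filled.data[1, 1, 0] == 3


def test_fill_no_zeros_is_identity_and_idempotent():
    vol = _block_with_hole()
    once, n1 = ph.fill_unlabeled(vol, np.ones(vol.shape, bool))
    twice, n2 = ph.fill_unlabeled(once, np.ones(vol.shape, bool))
    assert n1 == 1 and n2 == 0
    assert np.array_equal(once.data, twice.data)


def test_fill_component_without_labeled_neighbor_raises():
    vol = LabelVolume(np.zeros((4, 4, 4), np.int16), (1, 1, 1), (0, 0, 0), {})
    with pytest.raises(ValueError, match="component size"):
        ph.fill_unlabeled(vol, np.ones(vol.shape, bool))


# --------------------------------------------------------------------------- resampling


def test_resample_uniform_block_stays_uniform():
    vol = LabelVolume(np.full((10, 10, 10), 4, np.int16), (2, 2, 2), (0, 0, 0), {4: "Fat"})
    out = ph.resample_labels(vol, 1.0)
    assert np.all(out.data == 4)
    assert out.spacing_mm == (1.0, 1.0, 1.0)


def test_resample_identity_spacing_is_voxelwise_identity():
    vol = ph.build_phantom(ph.default_child_spec(8.0))
    out = ph.resample_labels(vol, 8.0)
    assert np.array_equal(out.data, vol.data)


def test_resample_preserves_sphere_volume_within_3pct():
    vol = ph.build_phantom(_single_sphere_spec(50.0, 2.0))
    fine = ph.resample_labels(vol, 0.5)
    v_coarse = vol.voxel_counts()["Muscle"] * vol.voxel_volume_mm3
    v_fine = fine.voxel_counts()["Muscle"] * fine.voxel_volume_mm3
    assert abs(v_fine - v_coarse) / v_coarse < 0.03


def test_resample_never_introduces_new_labels():
    vol = ph.build_phantom(ph.default_child_spec(8.0))
    for target in (3.0, 5.0, 12.0):
        out = ph.resample_labels(vol, target)
        assert set(np.unique(out.data)) <= set(np.unique(vol.data))


def test_resample_preserves_world_extent_within_one_voxel():
    vol = LabelVolume(np.ones((16, 12, 8), np.int16), (2, 2, 2), (0, 0, 0), {1: "Fat"})
    out = ph.resample_labels(vol, 3.0)
    old_extent = np.asarray(vol.shape) * 2.0
    new_extent = np.asarray(out.shape) * 3.0
    assert np.all(np.abs(old_extent - new_extent) <= 3.0)
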