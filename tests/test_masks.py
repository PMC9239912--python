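import numpy as np
import pytest

from connforge.grid import (
    BinaryMask,
    GridMismatchError,
    LabelVolume,
    ParcellationTable,
    VoxelGrid,
)
from connforge.masks import (
    extract_interface,
    label_gray_matter,
    label_interface,
    merge_subcortical,
    neighbor_offsets,
    reassign_lesions,
    roi_centroids,
    roi_volumes,
)


def brute_force_interface(gm: np.ndarray, wm: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent oracle: explicit double loop over voxels and offsets."""
    offsets = neighbor_offsets(connectivity)
    shape = np.asarray(gm.shape)
    out = np.zeros_like(wm)
    for vox in np.argwhere(wm & ~gm):
        for off in offsets:
            nbr = vox + off
            if np.any(nbr < 0) or np.any(nbr >= shape):
                continue
            if gm[tuple(nbr)]:
                out[tuple(vox)] = True
                break
    return out


def _mask(grid, data):
    return BinaryMask(grid, data)


class TestMergeSubcortical:
    def test_union(self, grid12):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[1, 1, 1] = True
        b[2, 2, 2] = True
        out = merge_subcortical(_mask(grid12, a), _mask(grid12, b))
        assert out.data[1, 1, 1] and out.data[2, 2, 2]
        assert out.n_voxels == 2

    def test_empty_subcortical_is_identity(self, grid12, rng):
        gm = rng.random((12, 12, 12)) < 0.3
        out = merge_subcortical(
            _mask(grid12, gm), _mask(grid12, np.zeros((12, 12, 12), bool))
        )
        assert np.array_equal(out.data, gm)

    def test_matches_logical_or_oracle(self, rng):
        grid = VoxelGrid.isotropic((16, 16, 16))
        gm = rng.random((16, 16, 16)) < 0.4
        sub = rng.random((16, 16, 16)) < 0.2
        out = merge_subcortical(_mask(grid, gm), _mask(grid, sub))
        assert np.array_equal(out.data, np.logical_or(gm, sub))

    def test_grid_mismatch(self, grid12):
        other = VoxelGrid.isotropic((10, 10, 10))
        with pytest.raises(GridMismatchError):
            merge_subcortical(
                _mask(grid12, np.zeros((12, 12, 12), bool)),
                _mask(other, np.zeros((10, 10, 10), bool)),
            )


class TestReassignLesions:
    def test_lesion_voxel_moves_to_wm(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        wm = np.zeros((12, 12, 12), bool)
        les = np.zeros((12, 12, 12), bool)
        gm[3, 3, 3] = True
        les[3, 3, 3] = True
        gm2, wm2 = reassign_lesions(
            _mask(grid12, gm), _mask(grid12, wm), _mask(grid12, les)
        )
        assert not gm2.data[3, 3, 3]
        assert wm2.data[3, 3, 3]

    def test_empty_lesions_identity(self, grid12, rng):
        gm = rng.random((12, 12, 12)) < 0.3
        wm = rng.random((12, 12, 12)) < 0.3
        gm2, wm2 = reassign_lesions(
            _mask(grid12, gm),
            _mask(grid12, wm),
            _mask(grid12, np.zeros((12, 12, 12), bool)),
        )
        assert np.array_equal(gm2.data, gm)
        assert np.array_equal(wm2.data, wm)

    def test_set_arithmetic_oracle(self, grid12, rng):
        gm = rng.random((12, 12, 12)) < 0.4
        wm = rng.random((12, 12, 12)) < 0.4
        les = rng.random((12, 12, 12)) < 0.2
        gm2, wm2 = reassign_lesions(
            _mask(grid12, gm), _mask(grid12, wm), _mask(grid12, les)
        )
        # enumerate voxels: oracle via explicit set operations
        gm_set = {tuple(v) for v in np.argwhere(gm)}
        wm_set = {tuple(v) for v in np.argwhere(wm)}
        les_set = {tuple(v) for v in np.argwhere(les)}
        gm_expect = gm_set - les_set
        wm_expect = wm_set | (gm_set & les_set)
        assert {tuple(v) for v in np.argwhere(gm2.data)} == gm_expect
        assert {tuple(v) for v in np.argwhere(wm2.data)} == wm_expect

    def test_total_tissue_conserved(self, grid12, rng):
        gm = rng.random((12, 12, 12)) < 0.4
        wm = rng.random((12, 12, 12)) < 0.4
        les = rng.random((12, 12, 12)) < 0.2
        gm2, wm2 = reassign_lesions(
            _mask(grid12, gm), _mask(grid12, wm), _mask(grid12, les)
        )
        before = np.logical_or(gm, wm).sum()
        after = np.logical_or(gm2.data, wm2.data).sum()
        assert after == before


class TestLabelGrayMatter:
    def test_direct_lookup(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        gm[5, 5, 5] = True
        parc = np.zeros((12, 12, 12), int)
        parc[5, 5, 5] = 7
        out = label_gray_matter(_mask(grid12, gm), LabelVolume(grid12, parc))
        assert out.data[5, 5, 5] == 7
        assert (out.data != 0).sum() == 1

    def test_outside_gm_is_zero(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        parc = np.full((12, 12, 12), 3)
        out = label_gray_matter(_mask(grid12, gm), LabelVolume(grid12, parc))
        assert not out.data.any()

    def test_no_fill_by_default(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        gm[5, 5, 5] = True
        parc = np.zeros((12, 12, 12), int)
        parc[5, 5, 6] = 3  # labeled neighbor, but fill disabled
        out = label_gray_matter(_mask(grid12, gm), LabelVolume(grid12, parc))
        assert out.data[5, 5, 5] == 0

    def test_fill_within_radius(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        gm[5, 5, 5] = True
        parc = np.zeros((12, 12, 12), int)
        parc[5, 5, 6] = 3  # 1 voxel = 1 mm away
        out = label_gray_matter(
            _mask(grid12, gm), LabelVolume(grid12, parc), fill_radius_mm=2.0
        )
        assert out.data[5, 5, 5] == 3

    def test_fill_respects_radius(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        gm[5, 5, 5] = True
        parc = np.zeros((12, 12, 12), int)
        parc[5, 5, 9] = 3  # 4 mm away, beyond radius 2
        out = label_gray_matter(
            _mask(grid12, gm), LabelVolume(grid12, parc), fill_radius_mm=2.0
        )
        assert out.data[5, 5, 5] == 0

    def test_fill_matches_exhaustive_nearest_neighbor(self, rng):
        grid = VoxelGrid.isotropic((10, 10, 10))
        gm = rng.random((10, 10, 10)) < 0.5
        parc = np.where(rng.random((10, 10, 10)) < 0.3,
                        rng.integers(1, 5, (10, 10, 10)), 0)
        radius = 3.0
        out = label_gray_matter(
            _mask(grid, gm), LabelVolume(grid, parc), fill_radius_mm=radius
        )
        labeled_vox = np.argwhere(parc > 0)
        for vox in np.argwhere(gm):
            expect = parc[tuple(vox)]
            if expect == 0:
                d = np.linalg.norm(labeled_vox - vox, axis=1)
                if d.size and d.min() <= radius:
                    expect = parc[tuple(labeled_vox[np.argmin(d)])]
            got = out.data[tuple(vox)]
            if expect == 0:
                assert got == 0
            else:
                # equidistant labeled voxels make the exact pick ambiguous;
                # require the label to come from *a* nearest labeled voxel
                d = np.linalg.norm(labeled_vox - vox, axis=1)
                nearest = labeled_vox[d <= d.min() + 1e-9]
                allowed = {parc[tuple(v)] for v in nearest}
                if parc[tuple(vox)] > 0:
                    allowed = {parc[tuple(vox)]}
                assert got in allowed


class TestExtractInterface:
    def test_line_example(self):
        grid = VoxelGrid.isotropic((4, 1, 1))
        gm = np.array([[[True]], [[False]], [[False]], [[False]]])
        wm = np.array([[[False]], [[True]], [[True]], [[False]]])
        out = extract_interface(BinaryMask(grid, gm), BinaryMask(grid, wm), 6)
        assert np.argwhere(out.data).tolist() == [[1, 0, 0]]

    def test_no_gm_gives_empty(self, grid12, rng):
        wm = rng.random((12, 12, 12)) < 0.5
        out = extract_interface(
            _mask(grid12, np.zeros((12, 12, 12), bool)), _mask(grid12, wm), 26
        )
        assert not out.data.any()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force(self, grid12, connectivity):
        rng = np.random.default_rng(connectivity)
        gm = rng.random((12, 12, 12)) < 0.3
        wm = rng.random((12, 12, 12)) < 0.3
        out = extract_interface(_mask(grid12, gm), _mask(grid12, wm), connectivity)
        assert np.array_equal(out.data, brute_force_interface(gm, wm, connectivity))

    def test_overlap_treated_as_gm(self, grid12):
        gm = np.zeros((12, 12, 12), bool)
        wm = np.zeros((12, 12, 12), bool)
        gm[5, 5, 5] = True
        wm[5, 5, 5] = True  # overlapping voxel: GM wins, not interface
        wm[5, 5, 6] = True
        out = extract_interface(_mask(grid12, gm), _mask(grid12, wm), 6)
        assert not out.data[5, 5, 5]
        assert out.data[5, 5, 6]

    def test_monotone_in_connectivity(self, grid12, rng):
        gm = rng.random((12, 12, 12)) < 0.3
        wm = rng.random((12, 12, 12)) < 0.3
        r6 = extract_interface(_mask(grid12, gm), _mask(grid12, wm), 6).data
        r18 = extract_interface(_mask(grid12, gm), _mask(grid12, wm), 18).data
        r26 = extract_interface(_mask(grid12, gm), _mask(grid12, wm), 26).data
        assert not (r6 & ~r18).any()
        assert not (r18 & ~r26).any()

    def test_bad_connectivity(self, grid12):
        z = np.zeros((12, 12, 12), bool)
        with pytest.raises(ValueError):
            extract_interface(_mask(grid12, z), _mask(grid12, z), 10)


class TestLabelInterface:
    def _setup(self, grid12):
        iface = np.zeros((12, 12, 12), bool)
        iface[5, 5, 5] = True
        labels = np.zeros((12, 12, 12), int)
        return iface, labels

    def test_single_neighbor(self, grid12):
        iface, labels = self._setup(grid12)
        labels[5, 5, 6] = 7
        out = label_interface(
            BinaryMask(grid12, iface), LabelVolume(grid12, labels), 6
        )
        assert out.data[5, 5, 5] == 7

    def test_majority(self, grid12):
        iface, labels = self._setup(grid12)
        labels[5, 5, 6] = 3
        labels[5, 5, 4] = 3
        labels[5, 6, 5] = 5
        out = label_interface(
            BinaryMask(grid12, iface), LabelVolume(grid12, labels), 6
        )
        assert out.data[5, 5, 5] == 3

    def test_tie_breaks_to_smallest_label(self, grid12):
        iface, labels = self._setup(grid12)
        labels[5, 5, 6] = 9
        labels[5, 5, 4] = 2
        out = label_interface(
            BinaryMask(grid12, iface), LabelVolume(grid12, labels), 6
        )
        assert out.data[5, 5, 5] == 2

    def test_all_unlabeled_neighbors_stay_zero(self, grid12):
        iface, labels = self._setup(grid12)
        out = label_interface(
            BinaryMask(grid12, iface), LabelVolume(grid12, labels), 26
        )
        assert out.data[5, 5, 5] == 0

    def test_nonzero_only_on_interface_with_existing_labels(self, phantom):
        from connforge.masks import extract_interface as ei

        iface = ei(phantom.gm, phantom.wm, 26)
        out = label_interface(iface, phantom.parcellation, 26)
        assert not out.data[~iface.data].any()
        present = set(np.unique(out.data[out.data > 0]))
        assert present <= set(phantom.parcellation.labels_present().tolist())


class TestCentroidsAndVolumes:
    def test_centroid_midpoint(self, grid12, small_table):
        labels = np.zeros((12, 12, 12), int)
        labels[0, 0, 0] = 1
        labels[2, 0, 0] = 1
        out = roi_centroids(LabelVolume(grid12, labels), small_table)
        row = out[out["index"] == 1].iloc[0]
        assert (row.x, row.y, row.z) == (1.0, 0.0, 0.0)

    def test_single_voxel_identity(self, grid12, small_table):
        labels = np.zeros((12, 12, 12), int)
        labels[3, 4, 5] = 2
        out = roi_centroids(LabelVolume(grid12, labels), small_table)
        row = out[out["index"] == 2].iloc[0]
        assert (row.x, row.y, row.z) == (3.0, 4.0, 5.0)

    def test_missing_roi_flagged(self, grid12, small_table):
        labels = np.zeros((12, 12, 12), int)
        labels[1, 1, 1] = 1
        out = roi_centroids(LabelVolume(grid12, labels), small_table)
        assert not out[out["index"] == 1].iloc[0].missing
        assert out[out["index"] == 3].iloc[0].missing

    def test_diagonal_affine_oracle(self, small_table):
        grid = VoxelGrid((8, 8, 8), np.diag([2.0, 2.0, 2.0, 1.0]))
        labels = np.zeros((8, 8, 8), int)
        labels[1, 1, 1] = 1
        labels[3, 1, 1] = 1
        out = roi_centroids(LabelVolume(grid, labels), small_table)
        row = out[out["index"] == 1].iloc[0]
        # oracle: transform each voxel then average
        world = grid.voxel_to_world(np.array([[1, 1, 1], [3, 1, 1]]))
        assert np.allclose([row.x, row.y, row.z], world.mean(axis=0))
        assert (row.x, row.y, row.z) == (4.0, 2.0, 2.0)

    def test_volume_counting(self, grid12, small_table):
        labels = np.zeros((12, 12, 12), int)
        labels[0, 0, :5] = 2
        out = roi_volumes(LabelVolume(grid12, labels), small_table)
        row = out[out["index"] == 2].iloc[0]
        assert row.n_voxels == 5
        assert row.volume_mm3 == pytest.approx(5.0)

    def test_absent_label_zero(self, grid12, small_table):
        labels = np.zeros((12, 12, 12), int)
        out = roi_volumes(LabelVolume(grid12, labels), small_table)
        assert (out["n_voxels"] == 0).all()

    def test_counts_match_histogram_oracle(self, grid12, rng, small_table):
        labels = rng.integers(0, 4, (12, 12, 12))
        out = roi_volumes(LabelVolume(grid12, labels), small_table)
        hist = {i: int((labels == i).sum()) for i in (1, 2, 3)}
        for _, row in out.iterrows():
            assert row.n_voxels == hist[row["index"]]
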