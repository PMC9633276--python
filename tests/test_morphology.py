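"""Cluster labeling, linearity/width metrics, filtering and the pipeline."""

import numpy as np
import pytest

import pvsmaps as p
from pvsmaps.morphology import Cluster, _mask_from_clusters
from conftest import tiny_block_world


def flood_fill_components(data, connectivity=26):
    """Independent BFS flood-fill labeling oracle."""
    if connectivity == 26:
        neigh = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(data, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(data)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in neigh:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < data.shape[a] for a in range(3)):
                    if data[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(sorted(comp))
    return comps


class TestLabelComponents:
    def test_corner_touching_voxels_depend_on_connectivity(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[0, 0, 0] = data[1, 1, 1] = True
        mask = p.Mask(data)
        assert len(p.label_components(mask, connectivity=26)) == 1
        assert len(p.label_components(mask, connectivity=6)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert p.label_components(p.Mask(np.zeros((5, 5, 5), dtype=bool))) == []

    def test_matches_flood_fill_oracle_on_truth_mask(self):
        spec = p.PhantomSpec(shape=(72, 72, 72), n_tubes=12, seed=7)
        _, truth, _, _ = p.generate_phantom(spec)
        clusters = p.label_components(truth, connectivity=26)
        oracle = flood_fill_components(truth.data, 26)
        assert len(clusters) == 12
        assert len(oracle) == 12
        got = sorted(sorted(map(tuple, c.voxels)) for c in clusters)
        assert got == sorted(oracle)

    def test_deterministic_lexicographic_order(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[6, 6, 6] = True
        data[1, 1, 1] = True
        data[3, 0, 7] = True
        clusters = p.label_components(p.Mask(data))
        firsts = [tuple(c.voxels[0]) for c in clusters]
        assert firsts == sorted(firsts)
        assert [c.id for c in clusters] == [1, 2, 3]


class TestLinearity:
    def test_collinear_voxels_fully_linear(self):
        c = Cluster(id=1, voxels=[(i, 2, 3) for i in range(10)])
        assert p.compute_linearity(c) == pytest.approx(1.0)

    def test_solid_cube_is_isotropic(self):
        vox = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]
        c = Cluster(id=1, voxels=vox)
        assert p.compute_linearity(c) == pytest.approx(1 / 3, abs=1e-12)

    def test_random_blob_matches_eigen_oracle(self):
        rng = np.random.default_rng(11)
        vox = rng.integers(0, 12, size=(40, 3))
        c = Cluster(id=1, voxels=vox)
        got = p.compute_linearity(c)
        x = vox - vox.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(x.T @ x / len(x)))[::-1]
        assert got == pytest.approx(evals[0] / evals.sum(), abs=1e-10)

    def test_tiny_clusters_trivially_collinear(self):
        assert p.compute_linearity(Cluster(id=1, voxels=[(0, 0, 0)])) == 1.0
        assert p.compute_linearity(Cluster(id=1, voxels=[(0, 0, 0), (3, 1, 2)])) == 1.0

    def test_bounded_below_by_one_third(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            vox = np.unique(rng.integers(0, 6, size=(30, 3)), axis=0)
            if len(vox) < 3:
                continue
            lin = p.compute_linearity(Cluster(id=1, voxels=vox))
            assert 1 / 3 - 1e-9 <= lin <= 1.0 + 1e-9


class TestWidth:
    def test_collinear_has_zero_width(self):
        c = Cluster(id=1, voxels=[(i, 4, 4) for i in range(12)])
        assert p.compute_width(c) == pytest.approx(0.0, abs=1e-9)

    def test_axis_aligned_plate_width_is_in_plane_extent(self):
        vox = [(i, j, 0) for i in range(20) for j in range(20)]
        c = Cluster(id=1, voxels=vox)
        # PC1 and PC2 lie in the plate; the perpendicular extent along PC2 is 19
        assert p.compute_width(c) == pytest.approx(19.0, abs=1e-6)

    def test_sphere_width_close_to_diameter(self):
        r = 5
        idx = np.indices((2 * r + 1,) * 3) - r
        vox = np.argwhere((idx**2).sum(axis=0) <= r * r)
        c = Cluster(id=1, voxels=vox)
        assert p.compute_width(c) == pytest.approx(2 * r, abs=1.0)

    def test_width_matches_projection_oracle(self):
        rng = np.random.default_rng(13)
        vox = np.unique(rng.integers(0, 15, size=(60, 3)), axis=0)
        c = Cluster(id=1, voxels=vox)
        got = p.compute_width(c)
        x = vox - vox.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x / len(x))
        order = np.argsort(evals)[::-1]
        proj = x @ evecs[:, order][:, 1:]
        assert got == pytest.approx((proj.max(0) - proj.min(0)).max(), abs=1e-10)


class TestFilterClusters:
    def _mk(self, voxels):
        c = Cluster(id=1, voxels=voxels)
        p.compute_linearity(c)
        p.compute_width(c)
        return c

    def test_small_cluster_rejected_for_size_first(self):
        c = self._mk([(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)])
        accepted, rejected = p.filter_clusters([c], p.ThresholdSet(cluster_thr=5))
        assert accepted == [] and rejected[0].reject_reason == "size"

    def test_straight_tube_accepted(self):
        c = self._mk([(i, 0, 0) for i in range(10)])
        accepted, rejected = p.filter_clusters([c], p.ThresholdSet())
        assert rejected == [] and accepted[0].passed

    def test_wide_plate_rejected_for_width(self):
        c = self._mk([(i, j, 0) for i in range(30) for j in range(17)])
        accepted, rejected = p.filter_clusters([c], p.ThresholdSet(linearity_thr=0.01))
        assert accepted == [] and rejected[0].reject_reason == "width"

    def test_reason_order_size_before_linearity(self):
        # 4-voxel square fails size AND linearity; size is reported
        c = self._mk([(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)])
        _, rejected = p.filter_clusters([c], p.ThresholdSet(cluster_thr=5, linearity_thr=0.99))
        assert rejected[0].reject_reason == "size"

    def test_raising_thresholds_never_accepts_more(self, small_phantom, small_domain):
        vol = small_phantom[0]
        seg = p.segment(vol, small_domain)
        all_clusters = seg.clusters + seg.rejected
        base_n = len(p.filter_clusters(all_clusters, p.ThresholdSet())[0])
        for thr in [p.ThresholdSet(cluster_thr=8), p.ThresholdSet(linearity_thr=0.95)]:
            assert len(p.filter_clusters(all_clusters, thr)[0]) <= base_n


class TestSegmentPipeline:
    def test_noiseless_phantom_fully_recovered(self, small_phantom, small_domain):
        vol, truth, _, _ = small_phantom
        seg = p.segment(vol, small_domain)
        fp, fn = p.match_clusters(seg, truth)
        assert (fp, fn) == (0, 0)
        assert seg.cluster_count == 8

    def test_blobs_rejected_by_linearity(self):
        spec = p.PhantomSpec(shape=(80, 80, 80), n_tubes=5, n_blobs=5, seed=2)
        vol, truth, tissue, table = p.generate_phantom(spec)
        seg = p.segment(vol, p.phantom_search_domain(tissue))
        fp, fn = p.match_clusters(seg, truth)
        assert (fp, fn) == (0, 0)
        linearity_rejects = [c for c in seg.rejected if c.reject_reason == "linearity"]
        assert len([c for c in linearity_rejects if c.size >= 40]) >= 5

    def test_empty_search_domain_gives_empty_segmentation(self):
        vol, domain = tiny_block_world()
        shape = vol.shape
        empty_domain = p.SearchDomain(
            search=p.Mask(np.zeros(shape, dtype=bool), label="search"),
            wm=domain.wm,
            excluded_ventricles=domain.excluded_ventricles,
        )
        seg = p.segment(vol, empty_domain)
        assert seg.cluster_count == 0 and seg.mask.count == 0

    def test_mask_contained_in_candidates_and_domain(self, small_phantom, small_domain):
        vol = small_phantom[0]
        work = p.normalize_intensity(vol, small_domain.brain)
        scores = p.compute_scores(work, small_domain, 2)
        cand = p.threshold_candidates(scores, p.ThresholdSet())
        seg = p.segment(vol, small_domain)
        assert not np.any(seg.mask.data & ~cand.data)
        assert not np.any(cand.data & ~small_domain.search.data)

    def test_rotation_invariance_of_cluster_metrics(self):
        spec = p.PhantomSpec(shape=(64, 64, 64), n_tubes=6, seed=9)
        _, truth, _, _ = p.generate_phantom(spec)
        base = p.label_components(truth)
        rotated = p.Mask(np.rot90(truth.data, k=1, axes=(0, 1)).copy())
        rot = p.label_components(rotated)
        key = lambda cs: sorted((c.size, round(c.linearity, 9), round(c.width, 9)) for c in cs)
        assert key(base) == key(rot)

    def test_agrees_with_naive_reference_on_small_grid(self):
        """End-to-end pipeline vs a reference built from the loop oracles."""
        from test_detect import naive_scores
        rng = np.random.default_rng(17)
        shape = (18, 18, 18)
        data = np.full(shape, 0.7) + rng.normal(0, 0.01, shape)
        for start in [(4, 4, 4), (10, 12, 6)]:
            for t in range(6):
                data[start[0] + t, start[1], start[2]] = 0.38
        vol = p.Volume(data)
        search = np.zeros(shape, dtype=bool)
        search[1:17, 1:17, 1:17] = True
        domain = p.SearchDomain(
            search=p.Mask(search, label="search"),
            wm=p.Mask(search, label="WM"),
            excluded_ventricles=p.Mask(np.zeros(shape, dtype=bool), label="ventricles"),
        )
        thr = p.ThresholdSet()
        seg = p.segment(vol, domain, thr, normalize=False)

        med, mean = naive_scores(vol, domain, 2)
        cand = (med >= thr.median_thr) & (mean >= thr.difference_thr) & search
        comps = flood_fill_components(cand, 26)
        expected = np.zeros(shape, dtype=bool)
        for comp in comps:
            vox = np.array(comp)
            c = Cluster(id=0, voxels=vox)
            lin = p.compute_linearity(c)
            wid = p.compute_width(c)
            if len(vox) >= thr.cluster_thr and lin >= thr.linearity_thr and wid <= thr.width_thr:
                expected[tuple(vox.T)] = True
        assert np.array_equal(seg.mask.data, expected)


class TestEditSegmentation:
    def test_remove_all_empties_mask_and_logs(self, small_phantom, small_domain):
        vol = small_phantom[0]
        seg = p.segment(vol, small_domain)
        edited = p.edit_segmentation(seg, remove=[c.id for c in seg.clusters])
        assert edited.mask.count == 0
        assert len(edited.edit_log) == 1
        assert all(c.reject_reason == "manual" for c in edited.rejected[-seg.cluster_count:])

    def test_adding_missed_tubes_restores_recall(self, small_phantom, small_domain):
        vol, truth, _, _ = small_phantom
        seg = p.segment(vol, small_domain, p.ThresholdSet(cluster_thr=10))
        fp, fn_before = p.match_clusters(seg, truth)
        missed = p.Mask(truth.data & ~seg.mask.data, label="PVS_manual")
        if missed.count:
            edited = p.edit_segmentation(seg, add=missed)
            _, fn_after = p.match_clusters(edited, truth)
            assert fn_after == 0

    def test_noop_edit_is_identity(self, small_phantom, small_domain):
        vol = small_phantom[0]
        seg = p.segment(vol, small_domain)
        edited = p.edit_segmentation(seg)
        assert np.array_equal(edited.mask.data, seg.mask.data)
        assert [c.id for c in edited.clusters] == [c.id for c in seg.clusters]

    def test_unknown_cluster_id_is_error(self, small_phantom, small_domain):
        seg = p.segment(small_phantom[0], small_domain)
        with pytest.raises(KeyError):
            p.edit_segmentation(seg, remove=[99999])
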