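"""Segmentation unit and property tests.

Oracles: direct Pearson correlation, closed-form normalized-cut penalties
on tiny graphs, brute force over all bipartitions for the spectral split,
a naive exhaustive scan for the Otsu threshold, and synthetic nucleus
images with known geometry for the post-processing chain.
"""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import linescan as ls
from linescan.segment import (SegmentationParams, affinity_ca1pc,
                              affinity_normcut, ca1pc_postprocess,
                              ca1pc_process_image, evaluate_segmentation,
                              iterative_partition, ncut_penalty,
                              otsu_threshold, pixel_correlations,
                              spectral_split, Partition)


# ----------------------------------------------------------------------
# oracles
def brute_force_ncut(w):
    """Best normalized cut over all bipartitions of a small graph."""
    n = w.shape[0]
    best = (np.inf, None)
    for bits in range(1, 2 ** (n - 1)):
        a = [i for i in range(n) if bits >> i & 1]
        b = [i for i in range(n) if not bits >> i & 1]
        pen = ncut_penalty(w, a, b)
        if pen < best[0]:
            best = (pen, (a, b))
    return best


def between_class_variance(values, threshold):
    lo = values[values < threshold]
    hi = values[values >= threshold]
    if len(lo) == 0 or len(hi) == 0:
        return 0.0
    return len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2


def naive_otsu(values):
    """Exhaustive scan of all 255 cut positions of the 256-bin histogram."""
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_i = -np.inf, None
    for i in range(255):
        w0 = hist[:i + 1].sum()
        w1 = hist[i + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:i + 1] * centers[:i + 1]).sum() / w0
        mu1 = (hist[i + 1:] * centers[i + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best:
            best, best_i = var, i
    return edges[best_i + 1]


def random_connected_graph(n, rng):
    """Random symmetric weighted graph, guaranteed connected by a path."""
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = rng.uniform(0.05, 1.0)
    extra = rng.integers(0, 2, size=(n, n))
    vals = rng.uniform(0.05, 1.0, size=(n, n))
    mask = np.triu(extra, 1).astype(bool)
    w[mask] = vals[mask]
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return sp.csr_matrix(w)


# ----------------------------------------------------------------------
class TestPixelCorrelations:
    def test_identical_series_correlate_one(self, rng):
        trace = rng.normal(size=100)
        stack = np.zeros((100, 2, 2))
        stack[:, 0, 0] = trace
        stack[:, 0, 1] = trace
        stack[:, 1, :] = rng.normal(size=(100, 2))
        c = pixel_correlations(stack, num_pcs=50, neighborhood=(1, 1))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_sinusoids_correlate_minus_one(self):
        t = np.linspace(0, 8 * np.pi, 200)
        stack = np.zeros((200, 1, 2))
        stack[:, 0, 0] = np.sin(t)
        stack[:, 0, 1] = -np.sin(t)
        c = pixel_correlations(stack, num_pcs=10, neighborhood=(1, 1))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_independent_noise_weakly_correlated(self, rng):
        stack = rng.normal(size=(1000, 3, 3))
        c = pixel_correlations(stack, num_pcs=1000, neighborhood=(1, 1))
        off = c.toarray()[np.triu_indices(9, 1)]
        assert np.abs(off).max() < 0.2

    def test_zero_variance_pixel_correlates_zero(self, rng):
        stack = rng.normal(size=(50, 1, 2))
        stack[:, 0, 1] = 3.0
        c = pixel_correlations(stack, num_pcs=50, neighborhood=(1, 1))
        assert c[0, 1] == 0.0

    def test_symmetric_and_restricted_to_neighborhood(self, rng):
        stack = rng.normal(size=(40, 4, 6))
        c = pixel_correlations(stack, num_pcs=5, neighborhood=(1, 2))
        assert (abs(c - c.T) > 1e-12).nnz == 0
        dense = c.toarray()
        # pixel (0,0)=index 0 and pixel (3,0)=index 18 are 3 rows apart
        assert dense[0, 18] == 0.0


class TestAffinities:
    def params(self, **kw):
        base = dict(max_dist=(1, 1), spatial_decay=(1.0, 1.0), k_c=9.0)
        base.update(kw)
        return SegmentationParams(**base)

    def test_zero_correlation_horizontal_neighbor(self):
        corr = sp.csr_matrix((4, 4))
        w = affinity_normcut(corr, (2, 2), self.params())
        assert w[0, 1] == pytest.approx(np.exp(-1.0))

    def test_perfect_correlation_amplifies_by_exp_kc(self):
        corr = sp.csr_matrix((4, 4))
        corr = sp.lil_matrix((4, 4))
        corr[0, 1] = corr[1, 0] = 1.0
        w = affinity_normcut(corr.tocsr(), (2, 2), self.params())
        assert w[0, 1] == pytest.approx(np.exp(9.0) * np.exp(-1.0))

    def test_beyond_cutoff_is_zero(self):
        corr = sp.csr_matrix((6, 6))
        w = affinity_normcut(corr, (2, 3), self.params(max_dist=(1, 1)))
        assert w[0, 2] == 0.0  # two columns apart, r_x = 1

    def test_ca1pc_factor_unchanged_when_dark(self):
        w = affinity_normcut(sp.csr_matrix((4, 4)), (2, 2), self.params())
        w2 = affinity_ca1pc(w, np.zeros((2, 2)), k_i=3.0)
        np.testing.assert_allclose(w2.toarray(), w.toarray())

    def test_ca1pc_ridge_attenuates_crossing_edges(self):
        params = self.params(max_dist=(0, 2), spatial_decay=(1.0, 2.0))
        i_star = np.zeros((1, 3))
        i_star[0, 1] = 2.0  # bright ridge between pixels 0 and 2
        w = affinity_normcut(sp.csr_matrix((3, 3)), (1, 3), params)
        w2 = affinity_ca1pc(w, i_star, k_i=1.5)
        factor = w2[0, 2] / w[0, 2]
        assert factor == pytest.approx(np.exp(-1.5 * 2.0))
        assert w2[0, 2] == pytest.approx(w2[2, 0])

    def test_ca1pc_only_decreases_weights(self, rng):
        params = self.params(max_dist=(2, 2))
        w = affinity_normcut(sp.csr_matrix((36, 36)), (6, 6), params)
        i_star = rng.uniform(0, 1, size=(6, 6))
        w2 = affinity_ca1pc(w, i_star, k_i=2.0)
        assert (w2.toarray() <= w.toarray() + 1e-12).all()


class TestNcutPenalty:
    def test_weak_bridge_two_cliques(self):
        for eps in (1e-2, 1e-4):
            w = np.zeros((4, 4))
            w[0, 1] = w[1, 0] = 1.0
            w[2, 3] = w[3, 2] = 1.0
            w[1, 2] = w[2, 1] = eps
            pen = ncut_penalty(sp.csr_matrix(w), [0, 1], [2, 3])
            expected = eps / (2 + eps) * 2
            assert pen == pytest.approx(expected)

    def test_isolated_vertex_cut_dominates(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        pen = ncut_penalty(sp.csr_matrix(w), [1], [0, 2])
        assert pen >= 1.0

    def test_symmetry(self, rng):
        w = rng.uniform(0, 1, size=(6, 6))
        w = sp.csr_matrix(np.triu(w, 1) + np.triu(w, 1).T)
        a, b = [0, 2, 4], [1, 3, 5]
        assert ncut_penalty(w, a, b) == pytest.approx(ncut_penalty(w, b, a))

    def test_zero_association_side_is_maximal(self):
        w = sp.csr_matrix((3, 3))
        assert ncut_penalty(w, [0], [1, 2]) == 2.0


class TestSpectralSplit:
    def test_disconnected_components_split_first(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = w[3, 4] = w[4, 3] = 1.0
        a, b, pen = spectral_split(sp.csr_matrix(w))
        assert pen == 0.0
        assert {frozenset(a), frozenset(b)} == {frozenset({0, 1}),
                                                frozenset({2, 3, 4})}

    def test_barbell_splits_between_cliques(self):
        n = 6
        w = np.zeros((12, 12))
        for block in (range(6), range(6, 12)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        w[5, 6] = w[6, 5] = 0.1
        a, b, pen = spectral_split(sp.csr_matrix(w))
        assert {frozenset(a), frozenset(b)} == {frozenset(range(6)),
                                                frozenset(range(6, 12))}

    @pytest.mark.parametrize("seed", range(10))
    def test_within_factor_of_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        w = random_connected_graph(n, rng)
        best_pen, _ = brute_force_ncut(w)
        _, _, pen = spectral_split(w)
        assert pen <= 1.05 * best_pen + 1e-12

    def test_deterministic(self, rng):
        w = random_connected_graph(10, rng)
        r1 = spectral_split(w)
        r2 = spectral_split(w)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[2] == r2[2]


class TestIterativePartition:
    def make_grid_graph(self, R, C, weight=1.0):
        n = R * C
        w = sp.lil_matrix((n, n))
        for r in range(R):
            for c in range(C):
                i = r * C + c
                if c + 1 < C:
                    w[i, i + 1] = w[i + 1, i] = weight
                if r + 1 < R:
                    w[i, i + C] = w[i + C, i] = weight
        return w.tocsr()

    def test_small_uniform_region_not_split(self):
        w = self.make_grid_graph(10, 10)
        params = SegmentationParams(cut_min_size=50, cut_max_size=150,
                                    cut_max_pen=0.01)
        parts = iterative_partition(w, params)
        assert len(parts) == 1
        assert len(parts[0].pixels) == 100

    def test_oversized_region_always_split(self):
        w = self.make_grid_graph(15, 20)  # 300 px > cut_max_size
        params = SegmentationParams(cut_min_size=50, cut_max_size=150,
                                    cut_max_pen=1e-9)
        parts = iterative_partition(w, params)
        assert len(parts) >= 2

    def test_partitions_disjoint_and_covering(self, rng):
        w = self.make_grid_graph(12, 12)
        params = SegmentationParams(cut_min_size=20, cut_max_size=60,
                                    cut_max_pen=0.2)
        parts = iterative_partition(w, params)
        all_pixels = np.concatenate([p.pixels for p in parts])
        assert len(all_pixels) == 144
        assert len(set(all_pixels.tolist())) == 144

    def test_well_separated_blobs_recovered(self, ds_path):
        # nine correlated blobs on a grid; each partition overlaps one blob
        movie, truth = ls.generate_movie(ls.nuclei_scene(7, num_cells=9))
        ds = ls.Dataset([[movie]], ds_path()) if isinstance(movie, np.ndarray) \
            else movie
        rois = ds.segment(variant="normcut", label="nc")
        # every true nucleus lies mostly inside a single partition
        supports = [r.support() for r in rois]
        for troi in truth["rois"]:
            ts = troi.support()
            overlaps = sorted((np.logical_and(ts, s).sum() for s in supports),
                              reverse=True)
            assert overlaps[0] / ts.sum() > 0.5


class TestCa1pcProcessing:
    def test_constant_image_unchanged(self):
        img = np.full((20, 30), 3.5)
        np.testing.assert_array_equal(
            ca1pc_process_image(img, 14, 7), img)

    def test_contrast_of_dark_disk_increases(self):
        rr, cc = np.mgrid[0:40, 0:60]
        disk = (rr - 20) ** 2 + (cc - 30) ** 2 <= 25
        img = np.where(disk, 90.0, 100.0)  # faint dark disk
        out = ca1pc_process_image(img, 14, 7)
        def michelson(im):
            lo, hi = im[disk].mean(), im[~disk].mean()
            return (hi - lo) / (hi + lo)
        assert michelson(out) > michelson(img)

    def test_non_finite_rejected(self):
        img = np.ones((10, 10))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ca1pc_process_image(img, 14, 7)


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        thr = otsu_threshold(np.array([0, 0, 0, 10, 10, 10.0]))
        assert 0 < thr < 10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_exhaustive_scan(self, seed):
        """Equivalent to the exhaustive maximizer: same class assignment
        and same achieved between-class variance (ties across empty bins
        leave the threshold value itself ambiguous)."""
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(0, 1, 60),
                                 rng.normal(5, 2, 40)])
        ours = otsu_threshold(values)
        naive = naive_otsu(values)
        np.testing.assert_array_equal(values < ours, values < naive)
        assert between_class_variance(values, ours) == pytest.approx(
            between_class_variance(values, naive))

    def test_shift_equivariance(self, rng):
        values = rng.uniform(0, 10, 100)
        assert otsu_threshold(values + 50) == pytest.approx(
            otsu_threshold(values) + 50)

    def test_agrees_with_skimage_within_one_bin(self, rng):
        from skimage.filters import threshold_otsu
        values = np.concatenate([rng.normal(0, 1, 50),
                                 rng.normal(8, 1, 50)])
        ours = otsu_threshold(values)
        theirs = threshold_otsu(values, nbins=256)
        bin_width = (values.max() - values.min()) / 256
        assert abs(ours - theirs) <= bin_width + 1e-12

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_threshold(np.full(10, 3.0))


class TestCa1pcPostprocess:
    def params(self):
        return SegmentationParams(variant="ca1pc", min_roi_size=20,
                                  min_cut_size=40,
                                  circularity_threshold=0.5,
                                  x_diameter=14, y_diameter=7)

    def make_partition(self, shape):
        return Partition(np.arange(shape[0] * shape[1]), 0.0)

    def test_dark_disk_becomes_one_roi(self):
        shape = (20, 20)
        rr, cc = np.mgrid[0:20, 0:20]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 16  # r=4, area ~ 49
        i_star = np.where(disk, 0.1, 1.0)
        rois = ca1pc_postprocess([self.make_partition(shape)], i_star,
                                 self.params())
        assert len(rois) == 1
        overlap = (rois[0].support() & disk).sum()
        assert overlap / disk.sum() > 0.8

    def test_thin_dark_line_rejected_by_circularity(self):
        shape = (20, 40)
        i_star = np.ones(shape)
        i_star[10, 5:35] = 0.0  # 30-px dark line, 1 px wide
        rois = ca1pc_postprocess([self.make_partition(shape)], i_star,
                                 self.params())
        assert len(rois) == 0

    def test_small_dark_region_rejected_by_size(self):
        shape = (20, 20)
        i_star = np.ones(shape)
        i_star[9:11, 9:14] = 0.0  # 10 px < min_roi_size 20
        rois = ca1pc_postprocess([self.make_partition(shape)], i_star,
                                 self.params())
        assert len(rois) == 0

    def test_small_partition_skipped_entirely(self):
        i_star = np.zeros((6, 6))
        i_star[:3] = 1.0
        part = Partition(np.arange(36), 0.0)  # 36 px < min_cut_size 40
        assert len(ca1pc_postprocess([part], i_star, self.params())) == 0

    def test_constant_partition_skipped(self):
        i_star = np.full((10, 10), 2.0)
        part = Partition(np.arange(100), 0.0)
        assert len(ca1pc_postprocess([part], i_star, self.params())) == 0


class TestEvaluateSegmentation:
    def masks(self, centers, im_shape=(30, 30)):
        rois = []
        for r, c in centers:
            m = np.zeros(im_shape, dtype=bool)
            m[r:r + 4, c:c + 4] = True
            rois.append(ls.Roi(mask=m))
        return ls.RoiList(rois)

    def test_perfect_match(self):
        truth = self.masks([(2, 2), (10, 10), (20, 20)])
        fn, fp, matching = evaluate_segmentation(truth, truth)
        assert fn == 0 and fp == 0 and len(matching) == 3

    def test_counting_with_spurious_and_missed(self):
        truth = self.masks([(i * 3, j * 6) for i in range(5)
                            for j in range(2)])  # 10 ROIs
        found = self.masks([(i * 3, j * 6) for i in range(4)
                            for j in range(2)]  # 8 of them
                           + [(25, 25), (25, 1)])  # 2 spurious
        fn, fp, _ = evaluate_segmentation(found, truth)
        assert fn == pytest.approx(0.2)
        assert fp == pytest.approx(0.2)

    def test_below_threshold_counts_both_ways(self):
        truth = self.masks([(5, 5)])
        m = np.zeros((30, 30), dtype=bool)
        m[5:9, 8:12]  # J = 1/7 with the 4x4 at (5,5)? build overlap < 0.25
        m[5:9, 8:12] = True
        found = ls.RoiList([ls.Roi(mask=m)])
        fn, fp, matching = evaluate_segmentation(found, truth, 0.25)
        assert fn == 1.0 and fp == 1.0 and matching == []

    def test_empty_truth_rejected(self):
        found = self.masks([(5, 5)])
        with pytest.raises(ValueError, match="empty truth"):
            evaluate_segmentation(found, ls.RoiList([]))
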