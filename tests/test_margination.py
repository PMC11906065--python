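"""PCA reduction, k-means clustering, NCC maps and margination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from icgmargin.exceptions import (
    DomainError,
    EmptyClusterError,
    UndefinedCorrelationError,
    ValidationError,
)
from icgmargin.margination import (
    NCCMaps,
    PipelineParams,
    cluster_kmeans,
    choose_n_components,
    marginate,
    ncc,
    ncc_maps,
    reduce_pca,
    run_pipeline,
    select_chamber_clusters,
)
from icgmargin.preprocess import PixelTimeSeriesMatrix


def _matrix(traces: np.ndarray, frame_rate: float = 10.0) -> PixelTimeSeriesMatrix:
    n = traces.shape[0]
    coords = np.column_stack([np.arange(n) // 100, np.arange(n) % 100])
    return PixelTimeSeriesMatrix(coords=coords, traces=traces, frame_rate=frame_rate)


class TestPca:
    def test_rank_one_data_reconstructs_exactly(self, rng):
        base = rng.normal(0, 1, 20)
        scales = rng.uniform(0.5, 3.0, 50)
        traces = np.outer(scales, base)
        mat = _matrix(traces)
        emb, pca = reduce_pca(mat, 1)
        recon = pca.inverse_transform(emb)
        np.testing.assert_allclose(recon, traces, atol=1e-8)
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_rank_limited_data_reaches_total_variance(self, rng):
        # N=10 centered traces have rank <= 9, so d=9 explains everything
        traces = rng.normal(0, 1, (10, 15))
        _, pca = reduce_pca(_matrix(traces), 9)
        assert pca.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_errors(self, rng):
        mat = _matrix(rng.normal(0, 1, (30, 8)))
        with pytest.raises(DomainError):
            reduce_pca(mat, 8)  # d >= T
        with pytest.raises(DomainError):
            reduce_pca(mat, 0)

    def test_sign_convention_makes_embedding_deterministic(self, rng):
        traces = rng.normal(0, 1, (60, 15))
        mat = _matrix(traces)
        emb1, pca1 = reduce_pca(mat, 3)
        emb2, pca2 = reduce_pca(mat, 3)
        np.testing.assert_array_equal(emb1, emb2)
        # largest-magnitude loading of every component is positive
        peaks = pca1.components_[
            np.arange(3), np.abs(pca1.components_).argmax(axis=1)
        ]
        assert np.all(peaks > 0)

    def test_two_family_phantom_is_low_rank(self, small_phantom):
        from icgmargin.preprocess import (
            extract_timeseries,
            isolate_fluorescence_channel,
            threshold_foreground,
        )

        stack, _ = small_phantom
        mono = isolate_fluorescence_channel(stack)
        mat = extract_timeseries(mono, threshold_foreground(mono))
        _, pca = reduce_pca(mat, 2)
        assert pca.explained_variance_ratio_.sum() >= 0.95

    def test_choose_n_components_caps_at_max(self, rng):
        traces = rng.normal(0, 1, (50, 30))  # white noise: needs many comps
        mat = _matrix(traces)
        assert choose_n_components(mat, max_components=5) == 5


class TestKmeans:
    def test_recovers_well_separated_clouds_exactly(self, rng):
        centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        pts = np.vstack([c + rng.normal(0, 1.0, (40, 2)) for c in centers])
        traces = rng.normal(0, 1, (120, 6)) + pts[:, :1]  # traces only feed centers_ts
        mat = _matrix(traces)
        result = cluster_kmeans(mat, pts, k=3, seed=0)
        # oracle: brute-force nearest true center
        oracle = np.argmin(
            ((pts[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
        )
        # labels must match the oracle partition up to renaming
        for j in range(3):
            members = result.labels[oracle == j]
            assert np.all(members == members[0])
        assert len({result.labels[oracle == j][0] for j in range(3)}) == 3

    def test_centers_are_mean_of_member_traces_and_auc_their_sum(self, rng):
        pts = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(50, 1, (30, 2))])
        traces = rng.uniform(0, 10, (60, 8))
        mat = _matrix(traces)
        result = cluster_kmeans(mat, pts, k=2, seed=1)
        for j in range(2):
            np.testing.assert_allclose(
                result.centers_ts[j], traces[result.labels == j].mean(axis=0), atol=1e-9
            )
            assert result.auc[j] == pytest.approx(result.centers_ts[j].sum())

    def test_identical_points_exercise_empty_cluster_path(self):
        import warnings

        pts = np.zeros((40, 2))
        traces = np.tile(np.arange(8.0), (40, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn duplicate-point warning
            with pytest.raises(EmptyClusterError):
                cluster_kmeans(_matrix(traces), pts, k=2, seed=0)

    def test_fixed_seed_is_deterministic(self, rng):
        pts = rng.normal(0, 5, (80, 3))
        traces = rng.uniform(0, 1, (80, 10))
        mat = _matrix(traces)
        r1 = cluster_kmeans(mat, pts, k=4, seed=7)
        r2 = cluster_kmeans(mat, pts, k=4, seed=7)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_too_few_points_rejected(self, rng):
        pts = rng.normal(0, 1, (15, 2))
        with pytest.raises(DomainError):
            cluster_kmeans(_matrix(pts.copy()), pts, k=2, seed=0)


class TestClusterSelection:
    def _result_with_auc(self, auc):
        from icgmargin.margination import ClusteringResult

        k = len(auc)
        centers = np.tile(np.asarray(auc, dtype=float)[:, None] / 4, (1, 4))
        return ClusteringResult(
            embedding=np.zeros((10, 2)),
            labels=np.zeros(10, dtype=int),
            centers_ts=centers,
            auc=np.asarray(auc, dtype=float),
        )

    def test_highest_auc_pair_descending(self):
        assert select_chamber_clusters(self._result_with_auc([5, 50, 40])) == (1, 2)

    def test_tie_broken_by_lower_id(self):
        assert select_chamber_clusters(self._result_with_auc([10, 10, 3])) == (0, 1)

    def test_requires_enough_clusters(self):
        with pytest.raises(DomainError):
            select_chamber_clusters(self._result_with_auc([1.0]), n_select=2)


class TestNcc:
    def test_identity_and_negation_are_exact(self, rng):
        a = rng.normal(0, 3, 50)
        assert ncc(a, a) == 1.0
        assert ncc(a, -a) == -1.0

    def test_hand_computed_values(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        # orthogonal even signal: deviations (-1.5,-.5,.5,1.5)·(.5,-.5,-.5,.5) cancel
        assert ncc(a, np.array([1.0, -1.0, -1.0, 1.0])) == 0.0
        # alternating signal: deviations dot to -2, norms sqrt(5)·sqrt(4)
        assert ncc(a, np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(
            -2.0 / math.sqrt(20.0)
        )

    def test_matches_prefactor_formula_definition(self, rng):
        # independent oracle: literal 1/(T-1) sum of standardized products
        a = rng.normal(0, 2, 31)
        b = rng.normal(5, 7, 31)
        t = a.size
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        assert ncc(a, b) == pytest.approx(float((za * zb).sum() / (t - 1)), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            ncc(np.ones(5), np.arange(5.0))

    def test_length_mismatch_and_short_signals_rejected(self):
        with pytest.raises(ValidationError):
            ncc(np.arange(4.0), np.arange(5.0))
        with pytest.raises(DomainError):
            ncc(np.array([1.0]), np.array([2.0]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        data=arrays(
            np.float64,
            st.integers(3, 40),
            elements=st.floats(-100.0, 100.0, allow_nan=False),
        ),
        alpha=st.floats(0.1, 10.0),
        beta=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance_and_antisymmetry(self, data, alpha, beta):
        if np.ptp(data) < 1e-3:  # numerically degenerate: rescaling would
            return  # annihilate the signal's variance in float
        ref = np.random.default_rng(data.size).normal(0, 1, data.size)
        base = ncc(data, ref)
        assert ncc(alpha * data + beta, ref) == pytest.approx(base, abs=1e-9)
        assert ncc(-alpha * data + beta, ref) == pytest.approx(-base, abs=1e-9)
        assert ncc(ref, data) == pytest.approx(base, abs=1e-12)
        assert -1.0 <= base <= 1.0


class TestNccMaps:
    def test_pixel_matching_center_one_gets_diff_one(self, rng):
        t = 20
        c1 = np.sin(np.linspace(0, 3, t)) * 10 + 50
        c2_seed = rng.normal(0, 1, t)
        # build c2 exactly NCC-orthogonal to c1
        d1 = c1 - c1.mean()
        d2 = c2_seed - c2_seed.mean()
        d2 = d2 - (d1 @ d2) / (d1 @ d1) * d1
        c2 = d2 + 30
        traces = np.vstack([c1, c2, np.full(t, 7.0)])
        coords = np.array([[0, 0], [0, 1], [1, 0]])
        mat = PixelTimeSeriesMatrix(coords=coords, traces=traces, frame_rate=10.0)
        maps = ncc_maps(mat, np.vstack([c1, c2]), (2, 2))
        assert maps.ncc_c1[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert maps.ncc_c2[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert maps.ncc_diff[0, 0] == pytest.approx(1.0, abs=1e-6)
        # zero-variance pixel is missing everywhere
        assert np.isnan(maps.ncc_c1[1, 0]) and np.isnan(maps.ncc_diff[1, 0])
        # non-foreground pixel is missing
        assert np.isnan(maps.ncc_c1[1, 1])

    def test_identical_centers_give_zero_diff(self, rng):
        traces = rng.normal(50, 10, (30, 25))
        mat = _matrix(traces)
        center = rng.normal(0, 1, 25)
        maps = ncc_maps(mat, np.vstack([center, center]), (1, 100))
        defined = ~np.isnan(maps.ncc_diff)
        np.testing.assert_allclose(maps.ncc_diff[defined], 0.0, atol=1e-12)

    def test_zero_variance_center_rejected(self, rng):
        mat = _matrix(rng.normal(0, 1, (20, 10)))
        with pytest.raises(UndefinedCorrelationError):
            ncc_maps(mat, np.vstack([np.ones(10), np.arange(10.0)]), (1, 100))

    def test_map_values_within_bounds(self, rng):
        traces = rng.normal(0, 1, (200, 30))
        mat = _matrix(traces)
        centers = rng.normal(0, 1, (2, 30))
        maps = ncc_maps(mat, centers, (2, 100))
        for m, bound in ((maps.ncc_c1, 1.0), (maps.ncc_c2, 1.0), (maps.ncc_diff, 2.0)):
            vals = m[~np.isnan(m)]
            assert np.all(np.abs(vals) <= bound + 1e-12)


class TestMarginate:
    def _maps(self, diff):
        diff = np.asarray(diff, dtype=float)
        return NCCMaps(ncc_c1=diff / 2, ncc_c2=-diff / 2, ncc_diff=diff)

    def test_zero_epsilon_partitions_foreground(self):
        diff = np.array([[0.5, -0.5], [0.0, np.nan]])
        res = marginate(self._maps(diff), epsilon=0.0)
        assert res.chamber1_mask.grid.tolist() == [[1, 0], [0, 0]]
        assert res.chamber2_mask.grid.tolist() == [[0, 1], [0, 0]]
        assert res.boundary_mask.grid.tolist() == [[0, 0], [1, 0]]

    def test_epsilon_two_puts_everything_in_boundary(self, rng):
        diff = rng.uniform(-2, 2, (6, 6))
        res = marginate(self._maps(diff), epsilon=2.0)
        assert res.chamber1_mask.n_pixels == 0 and res.chamber2_mask.n_pixels == 0
        assert res.boundary_mask.n_pixels == 36

    def test_masks_are_disjoint(self, rng):
        diff = rng.uniform(-2, 2, (20, 20))
        diff[rng.random((20, 20)) < 0.2] = np.nan
        res = marginate(self._maps(diff), epsilon=0.1)
        total = (
            res.chamber1_mask.grid + res.chamber2_mask.grid + res.boundary_mask.grid
        )
        assert total.max() <= 1
        assert total.sum() == np.count_nonzero(~np.isnan(diff))

    def test_largest_component_filter(self):
        diff = np.zeros((5, 9))
        diff[0, 0] = 0.5  # 1-pixel blob
        diff[2:5, 4:9] = 0.5  # 15-pixel blob
        res = marginate(self._maps(diff), epsilon=0.1, largest_component_only=True)
        assert res.chamber1_mask.n_pixels == 15
        assert res.chamber1_mask.grid[0, 0] == 0

    def test_negative_epsilon_rejected(self):
        with pytest.raises(DomainError):
            marginate(self._maps(np.zeros((3, 3))), epsilon=-0.1)


class TestPipelineOnPhantom:
    def test_chambers_recovered_and_ncc_contrast(self, small_phantom):
        from icgmargin.evaluation import evaluate_batch

        stack, truth = small_phantom
        result, clustering, mat = run_pipeline(stack, PipelineParams(seed=0))
        report = evaluate_batch([result], [tuple(truth.chamber_masks)])
        assert report.min >= 0.6
        # the NCC difference separates the chambers: opposite mean signs,
        # and center 1 correlates differently with the two true chambers
        maps = result.maps
        m1 = truth.chamber_masks[0].grid.astype(bool)
        m2 = truth.chamber_masks[1].grid.astype(bool)
        d1, d2 = np.nanmean(maps.ncc_diff[m1]), np.nanmean(maps.ncc_diff[m2])
        assert d1 * d2 < 0 and min(abs(d1), abs(d2)) > 0.05
        assert abs(np.nanmean(maps.ncc_c1[m1]) - np.nanmean(maps.ncc_c1[m2])) > 0.1

    def test_end_to_end_determinism(self, small_phantom):
        stack, _ = small_phantom
        r1, c1, _ = run_pipeline(stack, PipelineParams(seed=0))
        r2, c2, _ = run_pipeline(stack, PipelineParams(seed=0))
        np.testing.assert_array_equal(r1.chamber1_mask.grid, r2.chamber1_mask.grid)
        np.testing.assert_array_equal(r1.chamber2_mask.grid, r2.chamber2_mask.grid)
        np.testing.assert_array_equal(r1.boundary_mask.grid, r2.boundary_mask.grid)
        np.testing.assert_array_equal(r1.maps.ncc_diff, r2.maps.ncc_diff)
        np.testing.assert_array_equal(c1.labels, c2.labels)

    def test_noiseless_two_family_labels_match_truth(self):
        # rim-free noiseless phantom: traces form exactly two curve
        # families, and 2-means separates them exactly
        from conftest import small_config
        from icgmargin.phantom_sim import generate_phantom
        from icgmargin.preprocess import (
            extract_timeseries,
            isolate_fluorescence_channel,
            threshold_foreground,
        )
        from icgmargin.margination import cluster_kmeans, reduce_pca

        stack, truth = generate_phantom(small_config(noise_sd=0.0, rim_width=0.0))
        mono = isolate_fluorescence_channel(stack)
        mat = extract_timeseries(mono, threshold_foreground(mono))
        emb, _ = reduce_pca(mat, 2)
        res = cluster_kmeans(mat, emb, k=2, seed=0)
        fam = truth.chamber_masks[1].grid[mat.coords[:, 0], mat.coords[:, 1]]
        # every pixel of a family carries the same label, families differ
        lab0 = res.labels[fam == 0]
        lab1 = res.labels[fam == 1]
        assert len(set(lab0)) == 1 and len(set(lab1)) == 1 and lab0[0] != lab1[0]
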