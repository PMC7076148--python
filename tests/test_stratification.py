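"""Covariate extraction, correlation PCA, k-means strata and elbow scan."""

import itertools

import numpy as np
import pytest

from gridsurvey import (
    CovariateRaster,
    GridSpec,
    assign_strata,
    build_frame,
    extract_covariates,
    fit_pca,
    kmeans_scan,
    suggest_k,
)
from gridsurvey.stratify import KMeansScan


@pytest.fixture
def frame():
    grid = GridSpec(origin_x=0, origin_y=1, cell_size=0.1, n_rows=6, n_cols=6)
    rng = np.random.default_rng(0)
    mask = rng.uniform(size=grid.shape) < 0.8
    pop = rng.lognormal(size=grid.shape)
    return build_frame(mask, pop, grid)


def raster_like(frame, values_2d, name="x", kind="continuous"):
    return CovariateRaster(name=name, array=values_2d, kind=kind)


class TestExtractCovariates:
    def test_continuous_identity(self, frame):
        arr = np.arange(36, dtype=float).reshape(6, 6)
        stack = extract_covariates(frame, [raster_like(frame, arr)])
        rows = frame.cells["row"].to_numpy()
        cols = frame.cells["col"].to_numpy()
        assert np.array_equal(stack.matrix[:, 0], arr[rows, cols])
        assert stack.p == 1

    def test_one_hot_completeness(self, frame):
        arr = np.where(np.indices((6, 6)).sum(0) % 2 == 0, 1.0, 2.0)
        stack = extract_covariates(
            frame, [raster_like(frame, arr, name="cat", kind="categorical")]
        )
        assert stack.p == 2
        assert np.allclose(stack.matrix.sum(axis=1), 1.0)
        assert set(stack.columns["name"]) == {"cat=1", "cat=2"}

    def test_sixteen_attributes_from_mixed_covariates(self, frame):
        """8 continuous + categoricals contributing 8 levels -> p = 16."""
        rng = np.random.default_rng(1)
        rasters = [
            raster_like(frame, rng.normal(size=(6, 6)), name=f"c{i}")
            for i in range(8)
        ]
        for name, levels in (("cat_a", 4), ("cat_b", 4)):
            arr = rng.integers(1, levels + 1, size=(6, 6)).astype(float)
            rasters.append(raster_like(frame, arr, name=name, kind="categorical"))
        stack = extract_covariates(frame, rasters)
        assert stack.p == 16
        kinds = stack.columns["kind"].value_counts()
        assert kinds["continuous"] == 8 and kinds["indicator"] == 8

    def test_missing_values_imputed_with_warning(self, frame):
        arr = np.full((6, 6), 2.0)
        arr[0, 0] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            stack = extract_covariates(frame, [raster_like(frame, arr)])
        assert not np.isnan(stack.matrix).any()

    def test_grid_mismatch_rejected(self, frame):
        bad = CovariateRaster(name="bad", array=np.ones((3, 3)))
        with pytest.raises(ValueError, match="does not match grid"):
            extract_covariates(frame, [bad])

    def test_single_level_categorical_warns(self, frame):
        with pytest.warns(UserWarning, match="single level"):
            extract_covariates(
                frame,
                [raster_like(frame, np.ones((6, 6)), name="c", kind="categorical")],
            )


class TestPCA:
    def test_perfectly_correlated_columns_collapse_to_one(self, frame):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 6))
        stack = extract_covariates(
            frame,
            [raster_like(frame, x, "a"), raster_like(frame, 3.0 * x + 1.0, "b")],
        )
        pca = fit_pca(stack, variance_threshold=0.5)
        assert pca.q == 1
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_single_column_scores_are_zscores(self, frame):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 6))
        stack = extract_covariates(frame, [raster_like(frame, x)])
        pca = fit_pca(stack, 0.9)
        col = stack.matrix[:, 0]
        z = (col - col.mean()) / col.std(ddof=1)
        # sign convention fixes the orientation: scores equal +z
        assert np.allclose(pca.scores[:, 0], z)

    def test_eigenvalues_match_dense_eigendecomposition(self, frame):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 6))
        rasters = [
            raster_like(frame, base * w + rng.normal(size=(6, 6)), name=f"v{i}")
            for i, w in enumerate([2.0, 1.5, 1.0, 0.5, 0.0, -1.0])
        ]
        stack = extract_covariates(frame, rasters)
        pca = fit_pca(stack, variance_threshold=0.9)
        Z = (stack.matrix - stack.matrix.mean(0)) / stack.matrix.std(0, ddof=1)
        corr = np.corrcoef(Z, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(pca.explained_variance, eig, atol=1e-8)
        assert pca.explained_variance_ratio[: pca.q].sum() >= 0.9

    def test_constant_column_dropped_with_warning(self, frame):
        rng = np.random.default_rng(5)
        stack = extract_covariates(
            frame,
            [
                raster_like(frame, rng.normal(size=(6, 6)), "a"),
                raster_like(frame, np.full((6, 6), 3.0), "const"),
            ],
        )
        with pytest.warns(UserWarning, match="constant column"):
            pca = fit_pca(stack, 0.9)
        assert pca.dropped_columns == ["const"]

    def test_full_reconstruction(self, frame):
        rng = np.random.default_rng(6)
        rasters = [
            raster_like(frame, rng.normal(size=(6, 6)), name=f"v{i}") for i in range(4)
        ]
        stack = extract_covariates(frame, rasters)
        pca = fit_pca(stack, variance_threshold=1.0)
        Z = (stack.matrix - stack.matrix.mean(0)) / stack.matrix.std(0, ddof=1)
        assert np.allclose(pca.scores @ pca.loadings.T, Z, atol=1e-10)


def exhaustive_best_2partition_wss(points):
    """Brute-force minimum WSS over every 2-partition of <= 12 points."""
    m = len(points)
    best = np.inf
    for r in range(1, m // 2 + 1):
        for combo in itertools.combinations(range(m), r):
            a = np.zeros(m, dtype=bool)
            a[list(combo)] = True
            wss = 0.0
            for part in (points[a], points[~a]):
                wss += ((part - part.mean(axis=0)) ** 2).sum()
            best = min(best, wss)
    return best


class TestKMeansScan:
    def test_k1_is_total_sum_of_squares(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3))
        scan = kmeans_scan(pts, k_range=[1, 2, 3], seed=0)
        tss = ((pts - pts.mean(0)) ** 2).sum()
        assert scan.wss[0] == pytest.approx(tss)
        assert scan.explained_share[0] == 0.0

    def test_k_equals_m_is_zero(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(8, 2))
        scan = kmeans_scan(pts, k_range=range(1, 9), seed=0)
        assert scan.wss[-1] == pytest.approx(0.0, abs=1e-12)
        assert scan.explained_share[-1] == pytest.approx(1.0)

    def test_k_beyond_m_rejected(self):
        with pytest.raises(ValueError):
            kmeans_scan(np.zeros((3, 2)), k_range=[1, 4])

    def test_wss_nonincreasing_and_share_bounded(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(60, 4))
        scan = kmeans_scan(pts, k_range=range(1, 11), seed=1, n_starts=5)
        assert np.all(np.diff(scan.wss) <= 1e-9)
        assert np.all((scan.explained_share >= 0) & (scan.explained_share <= 1))
        assert np.all(np.diff(scan.explained_share) >= -1e-9)

    def test_two_blobs_match_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(10)
        pts = np.vstack(
            [rng.normal([0, 0], 0.3, (6, 2)), rng.normal([4, 4], 0.3, (6, 2))]
        )
        scan = kmeans_scan(pts, k_range=[1, 2], seed=0)
        assert scan.wss[1] == pytest.approx(exhaustive_best_2partition_wss(pts))


class TestSuggestK:
    def make_scan(self, k_values, wss):
        wss = np.asarray(wss, dtype=float)
        return KMeansScan(
            k_values=np.asarray(k_values),
            wss=wss,
            explained_share=1 - wss / wss[0],
            seed=0,
            n_starts=1,
        )

    def test_sharp_bend_detected(self):
        # piecewise linear, slope change at k = 3
        scan = self.make_scan([1, 2, 3, 4, 5], [100, 60, 20, 18, 16])
        assert suggest_k(scan)[0] == 3

    def test_linear_curve_has_no_elbow(self):
        scan = self.make_scan([1, 2, 3, 4, 5], [100, 80, 60, 40, 20])
        assert suggest_k(scan) == []

    def test_three_gaussian_clusters_recovered(self):
        rng = np.random.default_rng(11)
        pts = np.vstack(
            [rng.normal(c, 0.25, (30, 2)) for c in ([0, 0], [5, 0], [0, 5])]
        )
        scan = kmeans_scan(pts, k_range=range(1, 9), seed=2, n_starts=10)
        assert suggest_k(scan)[0] == 3

    def test_short_scan_rejected(self):
        scan = self.make_scan([1, 2], [10, 5])
        with pytest.raises(ValueError):
            suggest_k(scan)


class TestAssignStrata:
    def test_k1_single_stratum(self):
        pts = np.random.default_rng(12).normal(size=(10, 2))
        strat = assign_strata(pts, k=1, seed=0)
        assert np.array_equal(strat.labels, np.zeros(10, dtype=int))

    def test_blobs_recovered_up_to_permutation(self):
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(6, 0.2, (15, 2))])
        truth = np.repeat([0, 1], 15)
        strat = assign_strata(pts, k=2, seed=0)
        agreement = max(
            (strat.labels == truth).mean(), (strat.labels == 1 - truth).mean()
        )
        assert agreement == 1.0

    def test_deterministic_under_seed(self):
        pts = np.random.default_rng(14).normal(size=(50, 3))
        a = assign_strata(pts, k=4, seed=99)
        b = assign_strata(pts, k=4, seed=99)
        assert np.array_equal(a.labels, b.labels)

    def test_relabelled_by_descending_mean_population(self):
        rng = np.random.default_rng(15)
        pts = np.vstack([rng.normal(0, 0.2, (10, 1)), rng.normal(5, 0.2, (10, 1))])
        pop = np.concatenate([np.full(10, 100.0), np.full(10, 1.0)])
        strat = assign_strata(pts, k=2, seed=0, populations=pop)
        # stratum 0 must be the high-population context
        assert pop[strat.labels == 0].mean() > pop[strat.labels == 1].mean()

    def test_partition_covers_frame(self):
        pts = np.random.default_rng(16).normal(size=(33, 2))
        strat = assign_strata(pts, k=5, seed=1)
        assert strat.counts().sum() == 33
        assert (strat.counts() > 0).all()
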