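import numpy as np
import pandas as pd
import pytest

from toibn.evaluation import (
    binarize_zscore,
    cnr,
    euler_comparison,
    full_report,
    group_differences,
    mae_to_reference,
    subject_variability,
)
from toibn.topology import euler_characteristic
from toibn.volumes import VolumeGrid, flatten


def _grid(shape=(6, 6, 3)):
    mask = np.ones(shape, bool)
    return VolumeGrid(mask.astype(float), mask)


class TestBinarize:
    def test_threshold_is_strict_zero_on_zscores(self, rng):
        g = _grid()
        v = rng.normal(size=g.n_voxels)
        b = binarize_zscore(v, g)
        z = (v - v.mean()) / v.std()
        np.testing.assert_array_equal(b.flat_values(), (z > 0).astype(float))

    def test_constant_map_rejected(self):
        g = _grid()
        with pytest.raises(ValueError, match="constant"):
            binarize_zscore(np.ones(g.n_voxels), g)

    def test_scale_and_shift_invariant(self, rng):
        g = _grid()
        v = rng.normal(size=g.n_voxels)
        a = binarize_zscore(v, g).flat_values()
        b = binarize_zscore(3.0 * v + 7.0, g).flat_values()
        np.testing.assert_array_equal(a, b)


class TestEulerComparison:
    def test_identical_maps_give_zero(self, rng):
        g = _grid()
        ref = rng.normal(size=g.n_voxels)
        diffs = euler_comparison(np.stack([ref, ref]), ref, g)
        np.testing.assert_array_equal(diffs, [0, 0])

    def test_extra_blob_raises_chi_by_one(self):
        shape = (9, 9, 3)
        mask = np.ones(shape, bool)
        g = VolumeGrid(mask.astype(float), mask)
        ref3 = np.zeros(shape)
        ref3[2, 2, 1] = 5.0
        ref = flatten(ref3, mask)
        subj3 = ref3.copy()
        subj3[6, 6, 1] = 5.0  # far from the reference blob
        subj = flatten(subj3, mask)
        diffs = euler_comparison(subj[None, :], ref, g)
        assert diffs[0] == 1


class TestMae:
    def test_identical_after_affine(self, rng):
        v = rng.normal(size=100)
        assert mae_to_reference(2.0 * v + 1.0, v) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        # z-scores of (0,2) are (-1,1); of (2,0) are (1,-1); MAE = 2
        assert mae_to_reference(np.array([0.0, 2.0]), np.array([2.0, 0.0])) == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mae_to_reference(np.zeros(3), np.zeros(4))


class TestVariability:
    def test_identical_subjects(self, rng):
        g = _grid()
        ref = rng.normal(size=g.n_voxels)
        stack = np.stack([ref] * 4)
        corrs, vox_sd = subject_variability(stack, ref, g)
        np.testing.assert_allclose(corrs, 1.0)
        np.testing.assert_allclose(vox_sd, 0.0, atol=1e-12)

    def test_anticorrelated_pair(self, rng):
        g = _grid()
        ref = rng.normal(size=g.n_voxels)
        v = rng.normal(size=g.n_voxels)
        corrs, _ = subject_variability(np.stack([v, -v, v]), ref, g)
        # pairs: (v,-v) = -1, (v,v) = 1, (-v,v) = -1
        np.testing.assert_allclose(np.sort(corrs), [-1.0, -1.0, 1.0], atol=1e-12)

    def test_needs_three_subjects(self, rng):
        g = _grid()
        ref = rng.normal(size=g.n_voxels)
        with pytest.raises(ValueError, match="3 subjects"):
            subject_variability(np.stack([ref, ref]), ref, g)

    def test_constant_subject_gives_nan_corr(self, rng):
        g = _grid()
        ref = rng.normal(size=g.n_voxels)
        stack = np.stack([ref, np.zeros(g.n_voxels), ref])
        corrs, _ = subject_variability(stack, ref, g)
        assert np.isnan(corrs[0]) and np.isnan(corrs[2])
        assert corrs[1] == pytest.approx(1.0)

    def test_sd_recovers_generative_noise(self, rng):
        # subjects = reference + iid N(0, 0.2) noise: every voxel's
        # across-subject SD concentrates near 0.2
        g = _grid((8, 8, 4))
        ref = rng.normal(size=g.n_voxels)
        stack = ref + 0.2 * rng.normal(size=(40, g.n_voxels))
        _, vox_sd = subject_variability(stack, ref, g)
        assert vox_sd.mean() == pytest.approx(0.2, rel=0.1)


class TestCnr:
    def _setup(self, values_by_cluster, csf_values):
        # 1D layout: first len(csf_values) voxels are CSF
        n_csf = len(csf_values)
        vals = np.array(csf_values + values_by_cluster, dtype=float)
        shape = (len(vals), 1, 1)
        mask = np.ones(shape, bool)
        grid = VolumeGrid(mask.astype(float), mask)
        csf = np.zeros(shape, bool)
        csf[:n_csf] = True
        csf_grid = VolumeGrid(csf.astype(float), csf)
        return vals, grid, csf_grid

    def test_forced_example(self):
        # non-CSF values cluster into {0}, {1}, {3}; CSF sd = 0.5
        vals, grid, csf_grid = self._setup(
            [0.0] * 5 + [1.0] * 5 + [3.0] * 5, [-0.5, 0.5, -0.5, 0.5]
        )
        assert cnr(vals, grid, csf_grid) == pytest.approx((3.0 - 1.0) / 0.5)

    def test_scale_invariant(self):
        vals, grid, csf_grid = self._setup(
            [0.0] * 5 + [1.0] * 5 + [3.0] * 5, [-0.5, 0.5, -0.5, 0.5]
        )
        assert cnr(7.0 * vals, grid, csf_grid) == pytest.approx(cnr(vals, grid, csf_grid))

    def test_constant_csf_gives_nan(self):
        vals, grid, csf_grid = self._setup([0.0] * 5 + [1.0] * 5 + [3.0] * 5, [0.0, 0.0])
        assert np.isnan(cnr(vals, grid, csf_grid))

    def test_degenerate_clustering_gives_nan(self):
        vals, grid, csf_grid = self._setup([1.0] * 12, [-0.5, 0.5])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert np.isnan(cnr(vals, grid, csf_grid))

    def test_csf_outside_brain_mask_rejected(self, rng):
        shape = (6, 6, 3)
        csf = np.zeros(shape, bool)
        csf[0, 0, 0] = True
        csf_grid = VolumeGrid(csf.astype(float), csf)
        brain = np.ones(shape, bool)
        brain[0, 0, 0] = False  # the lone CSF voxel is outside the brain
        grid = VolumeGrid(brain.astype(float), brain)
        with pytest.raises(ValueError, match="CSF"):
            cnr(rng.normal(size=grid.n_voxels), grid, csf_grid)


class TestGroupDifferences:
    def test_bh_example(self):
        # four networks engineered to give raw p-values where BH matters;
        # oracle check against statsmodels directly
        rng = np.random.default_rng(0)
        vp = rng.normal(size=(10, 4)) + np.array([2.0, 1.0, 0.5, 0.0])
        vc = rng.normal(size=(10, 4))
        df = group_differences(vp, vc)
        from scipy import stats
        from statsmodels.stats.multitest import multipletests

        praw = np.array(
            [stats.ttest_ind(vp[:, k], vc[:, k]).pvalue for k in range(4)]
        )
        np.testing.assert_allclose(df["p_raw"], praw, atol=1e-12)
        np.testing.assert_allclose(
            df["p_adj"], multipletests(praw, method="fdr_bh")[1], atol=1e-12
        )
        assert bool(df["significant"][0])

    def test_null_controls_false_positive_rate(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            vp = rng.normal(size=(10, 3))
            vc = rng.normal(size=(10, 3))
            hits += int(group_differences(vp, vc)["significant"].any())
        assert hits <= 10  # ~5% per family expected

    def test_power_on_strong_effect(self):
        rng = np.random.default_rng(2)
        vp = rng.normal(size=(20, 2)) + np.array([3.0, 0.0])
        vc = rng.normal(size=(20, 2))
        df = group_differences(vp, vc, test="kruskal_wallis")
        assert bool(df["significant"][0])
        assert not bool(df["significant"][1])

    def test_degenerate_network_isolated(self):
        vp = np.zeros((5, 2))
        vc = np.zeros((5, 2))
        vp[:, 1] = [1, 2, 3, 4, 5]
        vc[:, 1] = [2, 3, 4, 5, 6]
        df = group_differences(vp, vc)
        assert np.isnan(df["p_adj"][0])
        assert np.isfinite(df["p_adj"][1])

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            group_differences(np.random.rand(3, 1), np.random.rand(3, 1), test="anova")

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_differences(np.zeros((1, 2)), np.zeros((5, 2)))


class TestFullReport:
    @pytest.fixture(scope="class")
    def small_run(self):
        rng = np.random.default_rng(9)
        shape = (8, 8, 4)
        mask = np.ones(shape, bool)
        grid = VolumeGrid(mask.astype(float), mask)
        csf = np.zeros(shape, bool)
        csf[3:5, 3:5, 1:3] = True
        csf_grid = VolumeGrid(csf.astype(float), csf)
        from scipy.ndimage import gaussian_filter

        K, n = 2, 6
        theta = np.stack(
            [
                flatten(gaussian_filter(rng.normal(size=shape), 1.2), mask)
                for _ in range(K)
            ]
        )
        theta = (theta - theta.mean(axis=1, keepdims=True)) / theta.std(
            axis=1, keepdims=True
        )
        from toibn.volumes import ReferenceSet

        refs = ReferenceSet(theta, grid)
        stack = theta[None] + 0.3 * rng.normal(size=(n, K, grid.n_voxels))
        groups = ["patient"] * 3 + ["control"] * 3
        return refs, grid, csf_grid, stack, groups

    def test_tables_populated(self, small_run, tmp_path):
        refs, grid, csf_grid, stack, groups = small_run
        rep = full_report(
            stack, stack + 0.01, refs, grid, csf_grid, groups, out_dir=tmp_path
        )
        n, K = stack.shape[:2]
        assert len(rep.euler_diff) == 2 * n * K
        assert len(rep.mae) == 2 * n * K
        assert set(rep.group_test["method"]) == {"ols", "toibn"}
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "group_test.csv").exists()
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert set(summary["method"]) == {"ols", "toibn"}

    def test_identical_stacks_give_identical_metrics(self, small_run):
        refs, grid, csf_grid, stack, groups = small_run
        rep = full_report(stack, stack.copy(), refs, grid, csf_grid, groups)
        s = rep.summary()
        a = s[s["method"] == "ols"].drop(columns="method").set_index("network")
        b = s[s["method"] == "toibn"].drop(columns="method").set_index("network")
        pd.testing.assert_frame_equal(a, b)

    def test_subject_order_does_not_change_summary(self, small_run):
        refs, grid, csf_grid, stack, groups = small_run
        rep1 = full_report(stack, stack + 0.01, refs, grid, csf_grid, groups)
        perm = [2, 0, 1, 5, 3, 4]  # keeps group membership intact
        rep2 = full_report(
            stack[perm], stack[perm] + 0.01, refs, grid, csf_grid,
            [groups[i] for i in perm],
        )
        s1 = rep1.summary().set_index(["method", "network"]).sort_index()
        s2 = rep2.summary().set_index(["method", "network"]).sort_index()
        pd.testing.assert_frame_equal(s1, s2, atol=1e-10)

    def test_mismatched_stacks_rejected(self, small_run):
        refs, grid, csf_grid, stack, groups = small_run
        with pytest.raises(ValueError, match="aligned"):
            full_report(stack, stack[:3], refs, grid, csf_grid, groups)

    def test_figures_written(self, small_run, tmp_path):
        refs, grid, csf_grid, stack, groups = small_run
        full_report(
            stack, stack + 0.01, refs, grid, csf_grid, groups,
            out_dir=tmp_path, make_figures=True,
        )
        assert (tmp_path / "mae.png").exists()
        assert (tmp_path / "cnr.png").exists()
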