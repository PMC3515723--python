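import numpy as np
import pandas as pd
import pytest

from petconn import roi_signals as roi
from petconn import synthetic as syn

from conftest import random_stack, tiny_config


def make_volume(rng, shape=(6, 6, 6), affine=None, key=("p", "s", "rest", 1)):
    return roi.RCBFVolume(
        data=rng.normal(size=shape),
        affine=np.eye(4) if affine is None else affine,
        scan_key=key,
    )


class TestSmoothVolume:
    def test_fwhm_zero_is_identity(self):
        vol = make_volume(np.random.default_rng(0))
        out = roi.smooth_volume(vol, 0.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_sigma_closed_form(self):
        assert 12.0 / (2.0 * roi._FWHM_TO_SIGMA) == pytest.approx(2.5477, abs=5e-4)

    def test_negative_fwhm_error(self):
        vol = make_volume(np.random.default_rng(0))
        with pytest.raises(ValueError, match="fwhm"):
            roi.smooth_volume(vol, -1.0)

    def test_delta_spike_matches_sampled_gaussian(self):
        # independent oracle: separable normalized sampled-Gaussian kernel
        fwhm, vs = 6.0, 2.0
        sigma = fwhm / (vs * roi._FWHM_TO_SIGMA)
        n = 41
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        affine = np.diag([vs, vs, vs, 1.0])
        out = roi.smooth_data(data, affine, fwhm)

        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        expected = np.zeros((n, n, n))
        c = n // 2
        for i, ki in zip(x, k1):
            for j, kj in zip(x, k1):
                for k, kk in zip(x, k1):
                    expected[c + i, c + j, c + k] = ki * kj * kk
        assert np.abs(out - expected).max() / expected.max() < 1e-6

    def test_anisotropic_voxels_per_axis(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 20, 20))
        affine = np.diag([1.0, 2.0, 4.0, 1.0])
        out = roi.smooth_data(data, affine, 8.0)
        from scipy import ndimage

        sig = 8.0 / (np.array([1.0, 2.0, 4.0]) * roi._FWHM_TO_SIGMA)
        np.testing.assert_allclose(out, ndimage.gaussian_filter(data, sig))


class TestStackScans:
    def _manifest_and_volumes(self, n_participants=5, sessions=("s1",),
                              conditions=("a", "b", "c"), replicates=2, seed=0):
        rng = np.random.default_rng(seed)
        rows, volumes = [], {}
        for p in range(n_participants):
            for s in sessions:
                for c in conditions:
                    for r in range(1, replicates + 1):
                        key = (f"p{p}", s, c, r)
                        volumes[key] = make_volume(rng, key=key)
                        rows.append(dict(participant=f"p{p}", session=s,
                                         condition=c, replicate=r, path=""))
        return pd.DataFrame(rows), volumes

    def test_combined_grouping_row_count(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=10)
        stacks = roi.stack_scans(manifest, volumes, "session_combined")
        assert stacks["s1"].n_units == 30  # 3 conditions x 10 participants

    def test_replicates_averaged_by_default(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=1,
                                                       conditions=("a",))
        stack = roi.stack_scans(manifest, volumes, "session_condition")[("s1", "a")]
        expected = (volumes[("p0", "s1", "a", 1)].data
                    + volumes[("p0", "s1", "a", 2)].data) / 2
        np.testing.assert_allclose(stack.data[0], expected)

    def test_use_replicates_first(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=1,
                                                       conditions=("a",))
        stack = roi.stack_scans(manifest, volumes, "session_condition",
                                use_replicates="first")[("s1", "a")]
        np.testing.assert_array_equal(stack.data[0],
                                      volumes[("p0", "s1", "a", 1)].data)

    def test_missing_scan_drops_only_that_unit(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=4)
        drop = (manifest.participant == "p2") & (manifest.condition == "b")
        manifest = manifest[~drop]
        stacks = roi.stack_scans(manifest, volumes, "session_condition")
        assert stacks[("s1", "b")].n_units == 3
        assert stacks[("s1", "a")].n_units == 4
        assert "p2" not in set(stacks[("s1", "b")].units.participant)

    def test_grid_mismatch_error_names_scan(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=2,
                                                       conditions=("a",))
        bad = ("p1", "s1", "a", 2)
        volumes[bad] = roi.RCBFVolume(
            data=np.zeros((3, 3, 3)), affine=np.eye(4), scan_key=bad
        )
        with pytest.raises(ValueError, match=r"p1"):
            roi.stack_scans(manifest, volumes, "session_condition")

    def test_stack_unstack_round_trip_bitwise(self):
        manifest, volumes = self._manifest_and_volumes(n_participants=3,
                                                       replicates=1)
        stacks = roi.stack_scans(manifest, volumes, "session_combined",
                                 use_replicates="first")
        recovered = roi.unstack(stacks["s1"])
        for vol in recovered:
            orig = volumes[(*vol.scan_key, 1)]
            assert vol.data.tobytes() == orig.data.tobytes()


def full_mask(stack, name="m"):
    return roi.ROIMask(name=name, data=np.ones(stack.data.shape[1:], dtype=bool),
                       affine=stack.affine)


class TestEigenvariate:
    def test_rank_one_stack_recovers_loading_vector(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=8)
        v = np.abs(rng.normal(size=30)) + 0.1  # non-negative voxel loadings
        X = np.outer(u, v)
        e = roi._first_eigenvariate(X)
        expected = (u - u.mean()) / (u - u.mean()).std()
        np.testing.assert_allclose(e, expected, atol=1e-10)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        e = roi._first_eigenvariate(X)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc @ Xc.T)  # units x units Gram matrix
        lead = V[:, np.argmax(w)]
        cos = abs(e @ lead) / (np.linalg.norm(e) * np.linalg.norm(lead))
        assert cos > 1 - 1e-10

    def test_duplicating_voxels_is_invariant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 12))
        np.testing.assert_allclose(
            roi._first_eigenvariate(X),
            roi._first_eigenvariate(np.hstack([X, X])),
            atol=1e-10,
        )

    def test_constant_stack_errors_not_nan(self):
        X = np.ones((5, 9)) * 3.2
        with pytest.raises(ValueError, match="constant"):
            roi._first_eigenvariate(X)

    def test_two_unit_stack_is_plus_minus_one(self):
        rng = np.random.default_rng(5)
        stack = random_stack(rng, n_units=2)
        e = roi.extract_eigenvariate(stack, full_mask(stack))
        assert sorted(np.round(e, 12)) == [-1.0, 1.0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_standardized_output(self, seed):
        rng = np.random.default_rng(seed)
        stack = random_stack(rng, n_units=9)
        e = roi.extract_eigenvariate(stack, full_mask(stack))
        assert e.mean() == pytest.approx(0.0, abs=1e-9)
        assert e.var() == pytest.approx(1.0, abs=1e-9)

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 15))
        perm = rng.permutation(15)
        np.testing.assert_allclose(
            roi._first_eigenvariate(X), roi._first_eigenvariate(X[:, perm]),
            atol=1e-10,
        )

    def test_affine_translation_invariance(self):
        rng = np.random.default_rng(7)
        stack = random_stack(rng)
        shifted_aff = stack.affine.copy()
        shifted_aff[:3, 3] += 17.0
        shifted = roi.Stack(data=stack.data.copy(), units=stack.units,
                            affine=shifted_aff)
        np.testing.assert_array_equal(
            roi.extract_eigenvariate(stack, full_mask(stack)),
            roi.extract_eigenvariate(
                shifted,
                roi.ROIMask(name="m", data=np.ones(stack.data.shape[1:], bool),
                            affine=shifted_aff),
            ),
        )

    def test_sign_deterministic_across_runs(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 20))
        runs = [roi._first_eigenvariate(X.copy()) for _ in range(3)]
        for r in runs[1:]:
            np.testing.assert_array_equal(runs[0], r)

    def test_mask_grid_mismatch_error(self):
        rng = np.random.default_rng(9)
        stack = random_stack(rng)
        bad = roi.ROIMask(name="bad", data=np.ones((2, 2, 2), bool),
                          affine=np.eye(4))
        with pytest.raises(ValueError, match="bad"):
            roi.extract_eigenvariate(stack, bad)


class TestExtractGlobal:
    def test_recovers_injected_global_shift(self):
        # uniform per-unit shift g over all brain voxels, nothing else
        rng = np.random.default_rng(10)
        g = rng.normal(size=12)
        shape = (8, 8, 8)
        brain = np.zeros(shape, bool)
        brain[1:-1, 1:-1, 1:-1] = True
        data = np.zeros((12, *shape))
        data[:, brain] = g[:, None] + rng.normal(0, 1e-3, size=(12, brain.sum()))
        units = pd.DataFrame(dict(participant=[f"p{i}" for i in range(12)],
                                  session=["s"] * 12, condition=["rest"] * 12))
        stack = roi.Stack(data=data, units=units, affine=np.eye(4))
        cov = roi.extract_global(
            stack, roi.ROIMask(name="whole_brain", data=brain, affine=np.eye(4))
        )
        assert np.corrcoef(cov, g)[0, 1] > 0.999

    def test_whole_brain_equal_to_roi_gives_same_output(self):
        rng = np.random.default_rng(11)
        stack = random_stack(rng)
        mask = full_mask(stack, "same")
        np.testing.assert_array_equal(
            roi.extract_eigenvariate(stack, mask), roi.extract_global(stack, mask)
        )


class TestEigenvariateTable:
    def test_columns_and_completeness(self, tiny_cohort, tiny_tables):
        comb, cond, masks = tiny_tables
        region_names = [m.name for m in masks[:-1]]
        assert list(comb.columns) == roi.UNIT_COLUMNS + region_names + ["global"]
        assert not comb.isna().any().any()
        # every manifest unit present
        units = tiny_cohort.manifest.groupby(
            ["participant", "session", "condition"]
        ).ngroups
        assert len(cond) == units
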