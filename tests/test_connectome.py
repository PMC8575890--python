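"""Connectome construction: censoring, correlation metrics, run aggregation."""

import numpy as np
import pytest

from gcaconn._utils import devectorize, fisher_z, vectorize_matrix
from gcaconn.connectome import (
    RunTimeSeries,
    UnusableRunError,
    censor_frames,
    partial_connectome,
    pearson_connectome,
    subject_connectome,
)


def make_run(frames, fd=None, run_id=0):
    frames = np.asarray(frames, dtype=float)
    if fd is None:
        fd = np.full(frames.shape[0], 0.1)
    return RunTimeSeries(frames, fd, run_id=run_id, subject_id="s1")


class TestCensoring:
    def test_low_motion_run_unchanged(self, rng):
        run = make_run(rng.standard_normal((50, 4)))
        out = censor_frames(run, 0.5)
        np.testing.assert_array_equal(out.frames, run.frames)

    def test_all_high_motion_flags_unusable(self, rng):
        run = make_run(rng.standard_normal((50, 4)), fd=np.full(50, 0.9))
        with pytest.raises(UnusableRunError):
            censor_frames(run, 0.5)

    def test_selective_censoring_keeps_order(self, rng):
        frames = rng.standard_normal((3, 2))
        run = make_run(frames, fd=np.array([0.1, 0.6, 0.2]))
        out = censor_frames(run, 0.5, min_frames=1)
        np.testing.assert_array_equal(out.frames, frames[[0, 2]])

    def test_threshold_is_strict_and_positive(self, rng):
        run = make_run(rng.standard_normal((20, 2)), fd=np.full(20, 0.5))
        with pytest.raises(UnusableRunError):
            censor_frames(run, 0.5, min_frames=1)  # fd == threshold is censored
        with pytest.raises(ValueError):
            censor_frames(run, 0.0)


class TestPearson:
    def test_duplicated_column_gives_unit_correlation(self, rng):
        x = rng.standard_normal(100)
        run = make_run(np.column_stack([x, x, rng.standard_normal(100)]))
        mat = pearson_connectome(run)
        assert mat[0, 1] == pytest.approx(1.0)

    def test_negated_column(self, rng):
        x = rng.standard_normal(100)
        mat = pearson_connectome(make_run(np.column_stack([x, -x])))
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_is_small_at_large_t(self, rng):
        mat = pearson_connectome(make_run(rng.standard_normal((10_000, 5))))
        off = mat[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_matches_two_pass_oracle(self, rng):
        frames = rng.standard_normal((50, 8))
        mat = pearson_connectome(make_run(frames))
        # brute-force two-pass correlation
        oracle = np.eye(8)
        for i in range(8):
            for j in range(8):
                xi = frames[:, i] - frames[:, i].mean()
                xj = frames[:, j] - frames[:, j].mean()
                oracle[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
        assert np.abs(mat - oracle).max() < 1e-12

    def test_zero_variance_column_flagged(self, rng):
        frames = rng.standard_normal((30, 3))
        frames[:, 1] = 2.5
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mat = pearson_connectome(make_run(frames))
        assert np.isnan(mat[0, 1]) and np.isnan(mat[1, 2])
        assert mat[1, 1] == 1.0


class TestPartial:
    def test_diagonal_population_covariance_gives_near_zero(self, rng):
        mat = partial_connectome(make_run(rng.standard_normal((5000, 4))))
        off = mat[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_chain_indirect_connection_removed(self, rng):
        # X -> Y -> Z: Z depends on X only through Y
        n = 20_000
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        z = 0.8 * y + 0.6 * rng.standard_normal(n)
        run = make_run(np.column_stack([x, y, z]))
        pearson = pearson_connectome(run)
        partial = partial_connectome(run)
        assert pearson[0, 2] > 0.3          # marginal X-Z association
        assert abs(partial[0, 2]) < 0.03    # vanishes given Y

    def test_two_variables_reduce_to_shrunk_correlation(self, rng):
        from sklearn.covariance import LedoitWolf

        frames = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]])
        mat = partial_connectome(make_run(frames))
        cov = LedoitWolf().fit(frames).covariance_
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert mat[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_sparse_precision_structure_recovered(self, rng):
        # structural zeros in the precision matrix -> smaller |partial r|
        r = 10
        prec = np.eye(r)
        true_edges = [(0, 1), (1, 2), (3, 4), (5, 6), (7, 8)]
        for i, j in true_edges:
            prec[i, j] = prec[j, i] = 0.35
        cov = np.linalg.inv(prec)
        frames = rng.multivariate_normal(np.zeros(r), cov, size=5000)
        mat = np.abs(partial_connectome(make_run(frames)))
        mask = np.zeros((r, r), dtype=bool)
        for i, j in true_edges:
            mask[i, j] = mask[j, i] = True
        off = ~np.eye(r, dtype=bool)
        assert mat[mask].mean() > 3 * mat[off & ~mask].mean()

    def test_matches_nilearn_partial_correlation(self, rng):
        nilearn = pytest.importorskip("nilearn")
        from nilearn.connectome import ConnectivityMeasure

        frames = rng.standard_normal((120, 6)).cumsum(axis=0) * 0.1 \
            + rng.standard_normal((120, 6))
        ours = partial_connectome(make_run(frames))
        cm = ConnectivityMeasure(kind="partial correlation", standardize=False)
        theirs = cm.fit_transform([frames])[0]
        np.fill_diagonal(theirs, 1.0)
        assert np.abs(ours - theirs).max() < 1e-6


class TestFisherZ:
    def test_known_values_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)
        r = np.array([0.3, -0.3, 0.9, -0.9])
        np.testing.assert_allclose(fisher_z(r), -fisher_z(-r))

    def test_clipping_keeps_values_finite(self):
        assert np.isfinite(fisher_z(np.array([1.0, -1.0]))).all()

    def test_matrix_diagonal_untouched(self, rng):
        mat = np.corrcoef(rng.standard_normal((30, 4)), rowvar=False)
        z = fisher_z(mat)
        np.testing.assert_array_equal(np.diag(z), np.zeros(4))


class TestVectorization:
    @pytest.mark.parametrize("r", [2, 4, 9])
    def test_round_trip_exact(self, rng, r):
        mat = rng.standard_normal((r, r))
        mat = (mat + mat.T) / 2
        vec = vectorize_matrix(mat)
        assert vec.shape == (r * (r - 1) // 2,)
        back = devectorize(vec, r)
        off = ~np.eye(r, dtype=bool)
        np.testing.assert_array_equal(back[off], mat[off])


class TestSubjectAggregation:
    def test_identical_runs_average_to_single_run(self, rng):
        frames = rng.standard_normal((80, 4))
        runs = [make_run(frames, run_id=i) for i in range(4)]
        conn = subject_connectome(runs)
        single = fisher_z(pearson_connectome(make_run(frames)))
        np.testing.assert_allclose(conn.matrix, single, atol=1e-12)

    def test_feature_length(self, rng):
        conn = subject_connectome([make_run(rng.standard_normal((60, 4)))])
        assert conn.features.shape == (6,)

    def test_unusable_run_dropped_from_average(self, rng):
        good = [make_run(rng.standard_normal((80, 3)), run_id=i) for i in range(3)]
        bad = make_run(rng.standard_normal((80, 3)), fd=np.full(80, 0.9), run_id=3)
        conn = subject_connectome(good + [bad])
        assert conn.n_usable_runs == 3
        expected = np.mean(
            [fisher_z(pearson_connectome(r)) for r in good], axis=0
        )
        np.testing.assert_allclose(conn.matrix, expected, atol=1e-12)

    def test_all_runs_unusable_raises(self, rng):
        bad = [make_run(rng.standard_normal((20, 3)), fd=np.full(20, 2.0))]
        with pytest.raises(UnusableRunError, match="no usable runs"):
            subject_connectome(bad)

    def test_mean_fd_uses_precensoring_frames(self, rng):
        fd = np.concatenate([np.full(40, 0.1), np.full(40, 0.7)])
        conn = subject_connectome([make_run(rng.standard_normal((80, 3)), fd=fd)])
        assert conn.mean_fd == pytest.approx(0.4)


class TestEdgeSpaceProperties:
    """Property-based checks of the edge-space primitives."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(st.lists(st.floats(-0.999, 0.999), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_fisher_z_is_odd_and_monotone(values):
        arr = np.asarray(values)
        np.testing.assert_allclose(fisher_z(-arr), -fisher_z(arr), atol=1e-12)
        order = np.argsort(arr)
        assert (np.diff(fisher_z(arr[order])) >= 0).all()

    @staticmethod
    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_vectorize_round_trip_any_size(r, seed):
        mat = np.random.default_rng(seed).standard_normal((r, r))
        mat = (mat + mat.T) / 2
        off = ~np.eye(r, dtype=bool)
        back = devectorize(vectorize_matrix(mat), r)
        np.testing.assert_array_equal(back[off], mat[off])
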