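"""Multiplier estimation, MMI detection, metric matrices, and the MM loop."""

import numpy as np
import pytest
import sympy

from mmkmeans import (
    AlgoConfig,
    CentroidSet,
    DataMatrix,
    MixtureSpec,
    MultiplierEstimate,
    ari_ha,
    assign_points,
    build_metric_matrix,
    compute_mm_step,
    compute_multiplier,
    detect_mmi,
    generate_mixture,
    mm_eigenvalues,
    mse,
    pearson_r,
    run_mmkmeans,
    run_traditional,
)
from mmkmeans.core import RunTrace


def make_estimate(m, mse1, n=100):
    sse1 = mse1 * n
    return MultiplierEstimate(
        m=m, sse1=sse1, frob_sq=0.0, sigma_sq=np.zeros(1),
        mse_l_est=m * mse1, n=n,
    )


class TestComputeMultiplier:
    def test_rank_k_data_gives_zero_bound(self):
        """k distinct rows each repeated: X has rank <= k, so the top-k
        squared singular values absorb the whole Frobenius norm."""
        base = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 1.0]])
        X = np.vstack([base] * 5)
        dm = DataMatrix(ids=[f"r{i}" for i in range(10)], values=X)
        est = compute_multiplier(dm, k=2, sse1=7.0)
        assert est.m == pytest.approx(0.0, abs=1e-9)
        assert est.mse_l_est == pytest.approx(0.0, abs=1e-9)

    def test_k1_definition(self, rng):
        X = rng.normal(size=(8, 4))
        dm = DataMatrix(ids=[f"r{i}" for i in range(8)], values=X)
        sse1 = 100.0
        est = compute_multiplier(dm, k=1, sse1=sse1)
        s1_sq = np.linalg.svd(X, compute_uv=False)[0] ** 2
        frob = (X**2).sum()
        assert est.frob_sq == pytest.approx(frob, rel=1e-12)
        assert est.m == pytest.approx(max(0.0, frob - s1_sq) / sse1, rel=1e-9)

    def test_matches_svd_oracle_small_matrix(self):
        X = np.array(
            [[1.0, 2.0, 0.0], [3.0, 1.0, 1.0], [0.0, 4.0, 2.0],
             [2.0, 2.0, 2.0], [5.0, 0.0, 1.0], [1.0, 1.0, 3.0]]
        )
        dm = DataMatrix(ids=[f"r{i}" for i in range(6)], values=X)
        sse1 = float((X**2).sum())  # any positive scale
        est = compute_multiplier(dm, k=2, sse1=sse1)
        sv = np.linalg.svd(X, compute_uv=False)  # independent route
        expected_bound = (X**2).sum() - (sv[:2] ** 2).sum()
        assert est.m * sse1 == pytest.approx(expected_bound, abs=1e-9)

    def test_m_in_unit_interval_and_estimate_below_mse1(self, small_mixture):
        data, _ = small_mixture
        cfg = AlgoConfig(k=4, seed=0)
        _, _, trace = run_traditional(data, cfg)
        mse1 = trace.records[0].mse
        est = compute_multiplier(data, k=4, sse1=mse1 * data.n)
        assert 0.0 <= est.m <= 1.0
        assert est.mse_l_est <= mse1

    def test_k_beyond_rank_pads_zeros(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        dm = DataMatrix(ids=["a", "b", "c"], values=X)
        est = compute_multiplier(dm, k=3, sse1=5.0)
        assert est.sigma_sq[2] == 0.0
        assert est.m == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_sse_raises(self, tiny_matrix):
        with pytest.raises(ValueError):
            compute_multiplier(tiny_matrix, k=2, sse1=0.0)


class TestDetectMMI:
    def _trace(self, mses):
        t = RunTrace()
        for i, v in enumerate(mses, start=1):
            t.append(i, v, 1, 0, i)
        return t

    def test_estimate_equal_to_mse1_detects_immediately(self):
        est = make_estimate(m=1.0, mse1=10.0)
        cfg = AlgoConfig(k=3)
        state = detect_mmi(self._trace([10.0, 9.0]), est, cfg)
        assert state.mmi == 1

    def test_never_in_band_stays_unset(self):
        # m = 0 and an absolute epsilon smaller than every recorded MSE
        est = make_estimate(m=0.0, mse1=10.0)
        cfg = AlgoConfig(k=3, epsilon=0.001, epsilon_mode="absolute")
        state = detect_mmi(self._trace([10.0, 8.0, 6.0]), est, cfg)
        assert state.mmi is None

    def test_clamped_by_upper_bound(self):
        # band never entered, but MMI <= ceil(MSE_1 * k / MSE_l_est) = 6
        est = make_estimate(m=0.5, mse1=10.0)  # bound = ceil(10*3/5) = 6
        cfg = AlgoConfig(k=3, epsilon=0.0001, epsilon_mode="absolute")
        state = detect_mmi(self._trace([10.0] * 10), est, cfg)
        assert state.mmi == 6

    def test_offline_rescan_matches_online_detection(self):
        spec = MixtureSpec(n=2000, d=12, k_true=8, separation=3.0, noise_sd=1.0, seed=17)
        data, _ = generate_mixture(spec)
        cfg = AlgoConfig(k=8, seed=17)
        with pytest.warns(UserWarning):
            _, _, trace, mmi_state, _ = run_mmkmeans(data, cfg)
        est = compute_multiplier(data, k=8, sse1=trace.records[0].mse * data.n)
        offline = detect_mmi(trace, est, cfg)
        assert offline.mmi == mmi_state.mmi


class TestMetricMatrix:
    def _centroids(self, M):
        M = np.asarray(M, dtype=float)
        return CentroidSet(means=M, sizes=np.ones(M.shape[0], dtype=int))

    def test_identical_sets_have_unit_diagonal(self, rng):
        c = self._centroids(rng.normal(size=(3, 6)))
        mm = build_metric_matrix(c, c)
        np.testing.assert_allclose(np.diag(mm), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        c = self._centroids(rng.normal(size=(3, 5)))
        shifted = self._centroids(2.0 * c.means + 3.0)
        np.testing.assert_allclose(
            build_metric_matrix(c, shifted), build_metric_matrix(c, c), atol=1e-12
        )

    def test_entries_match_pairwise_pearson(self, rng):
        prev = self._centroids(rng.normal(size=(3, 4)))
        curr = self._centroids(rng.normal(size=(3, 4)))
        mm = build_metric_matrix(prev, curr)
        for i in range(3):
            for j in range(3):
                assert mm[i, j] == pytest.approx(
                    pearson_r(prev.means[i], curr.means[j]), abs=1e-12
                )

    def test_k_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            build_metric_matrix(
                self._centroids(rng.normal(size=(2, 4))),
                self._centroids(rng.normal(size=(3, 4))),
            )


class TestMMEigenvalues:
    def test_identity_matrix(self):
        np.testing.assert_allclose(mm_eigenvalues(np.eye(4)), np.ones(4))

    def test_2x2_closed_form(self):
        r = 0.6
        e = mm_eigenvalues(np.array([[1.0, r], [r, 1.0]]))
        np.testing.assert_allclose(e, [1 + r, 1 - r], atol=1e-12)

    def test_matches_characteristic_polynomial_roots(self, rng):
        A = rng.normal(size=(4, 4))
        sym = (A + A.T) / 2
        # independent oracle: exact characteristic polynomial via sympy
        coeffs = sympy.Matrix(sym).charpoly().all_coeffs()
        roots = np.sort(np.roots([float(c) for c in coeffs]).real)[::-1]
        np.testing.assert_allclose(mm_eigenvalues(sym), roots, atol=1e-9)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            mm_eigenvalues(np.ones((2, 3)))


class TestComputeMMStep:
    def _centroids(self, M):
        M = np.asarray(M, dtype=float)
        return CentroidSet(means=M, sizes=np.ones(M.shape[0], dtype=int))

    def test_bootstrap_freezes_nothing(self, rng):
        c = self._centroids(rng.normal(size=(3, 5)))
        rec = compute_mm_step(None, c, c, AlgoConfig(k=3))
        assert not rec.stable.any()
        assert rec.diff is None

    def test_converged_sets_stable_under_threshold_not_strict(self, rng):
        c = self._centroids(rng.normal(size=(3, 5)))
        boot = compute_mm_step(None, c, c, AlgoConfig(k=3))
        rec_thr = compute_mm_step(boot, c, c, AlgoConfig(k=3, stability_mode="threshold"))
        assert rec_thr.stable.all()
        np.testing.assert_allclose(rec_thr.diff, 0.0, atol=1e-12)
        rec_strict = compute_mm_step(
            boot, c, c, AlgoConfig(k=3, stability_mode="strict_interval")
        )
        assert not rec_strict.stable.any()

    def test_eigenvalues_sorted_descending(self, rng):
        prev = self._centroids(rng.normal(size=(4, 6)))
        curr = self._centroids(rng.normal(size=(4, 6)))
        rec = compute_mm_step(None, prev, curr, AlgoConfig(k=4))
        assert np.all(np.diff(rec.eigenvalues) <= 1e-12)


class TestRunMMKMeans:
    def test_disabled_mechanism_reduces_to_traditional(self, small_mixture):
        data, _ = small_mixture
        cfg_t = AlgoConfig(k=4, seed=8)
        cfg_m = AlgoConfig(k=4, seed=8, mmi_override=10_000)
        pt, ct, tt = run_traditional(data, cfg_t)
        with pytest.warns(UserWarning):
            pm, cm, tm, state, records = run_mmkmeans(data, cfg_m)
        assert pm == pt
        np.testing.assert_array_equal(tm.mse_values, tt.mse_values)
        np.testing.assert_array_equal(cm.means, ct.means)
        assert records == []

    def test_k_equals_n_terminates_immediately(self):
        dm = DataMatrix(
            ids=list("abc"), values=np.array([[0.0, 0], [5.0, 1], [9.0, 2]])
        )
        part, _, trace, _, _ = run_mmkmeans(dm, AlgoConfig(k=3, seed=0))
        assert trace.records[-1].mse == pytest.approx(0.0, abs=1e-12)
        assert len(trace) == 2

    def test_agreement_with_traditional_on_separable_mixture(self):
        spec = MixtureSpec(n=5000, d=50, k_true=10, separation=8.0, noise_sd=1.0, seed=1)
        data, _ = generate_mixture(spec)
        cfg = AlgoConfig(k=10, seed=1)
        pt, _, tt = run_traditional(data, cfg)
        with pytest.warns(UserWarning):
            pm, _, tm, _, _ = run_mmkmeans(data, cfg)
        assert ari_ha(pm, pt) >= 0.9
        assert tm.total_dist_evals <= tt.total_dist_evals

    def test_forced_mechanism_freezes_and_saves_evaluations(self):
        """With the mechanism forced on early, frozen clusters must shrink
        the per-iteration evaluation count below n*k."""
        spec = MixtureSpec(n=2000, d=20, k_true=8, separation=8.0, noise_sd=1.0, seed=7)
        data, _ = generate_mixture(spec)
        cfg = AlgoConfig(k=8, seed=7, mmi_override=2)
        with pytest.warns(UserWarning):
            part, cent, trace, state, records = run_mmkmeans(data, cfg)
        assert records, "mechanism never produced a stability record"
        per_iter = trace.per_iteration_dist_evals()
        # find iterations whose assignment ran with >= 1 frozen cluster
        saw_saving = False
        for idx, r in enumerate(trace.records):
            if r.stable_clusters > 0:
                assert per_iter[idx] < data.n * cfg.k
                saw_saving = True
        assert saw_saving

    def test_frozen_membership_audit_at_termination(self):
        """When the mechanism fires under its own MMI detection, re-running
        a full assignment at termination must move <1% of the points that
        belong to clusters frozen at termination."""
        import warnings as _w

        audited = 0
        for seed in range(1, 13):
            spec = MixtureSpec(n=5000, d=50, k_true=10, separation=8.0,
                               noise_sd=1.0, seed=seed)
            data, _ = generate_mixture(spec)
            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                part, cent, trace, state, records = run_mmkmeans(
                    data, AlgoConfig(k=10, seed=seed)
                )
            if not records:
                continue
            frozen = records[-1].stable
            in_frozen = frozen[part.labels]
            if not in_frozen.any():
                continue
            full_labels, _, _ = assign_points(
                data, cent, None, part.labels, "sq_euclidean"
            )
            moved = (full_labels[in_frozen] != part.labels[in_frozen]).mean()
            assert moved < 0.01
            audited += 1
        assert audited >= 1, "MMI never fired in the seed sweep"

    def test_negative_values_warn(self, small_mixture):
        data, _ = small_mixture
        assert (data.values < 0).any()
        with pytest.warns(UserWarning, match="negative"):
            run_mmkmeans(data, AlgoConfig(k=4, seed=0, mmi_override=10_000))

    def test_d1_rejected(self):
        dm = DataMatrix(ids=["a", "b"], values=[[0.0], [1.0]])
        with pytest.raises(ValueError):
            run_mmkmeans(dm, AlgoConfig(k=2))
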