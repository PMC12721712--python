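"""RSA statistics: correlation oracles, permutation/bootstrap behavior."""

import warnings

import numpy as np
import pytest
from scipy import stats

from sizersa.core import RDM, RDMStack, rdm_from_feature_vectors, vectorize_upper
from sizersa.hypotheses import FEATURES, build_hypothesis_rdms
from sizersa.inference import (
    RSATimecourse,
    bootstrap_peak_latency,
    cluster_permutation_test,
    model_hyp_partial_test,
    noise_ceiling,
    paired_latency_test,
    partial_spearman_rsa,
    rsa_timecourse,
    spearman_rsa,
    variance_partitioning,
)
from sizersa.core import RDMError
from sizersa.synth import sample_latent_features, simulate_model_features, late_layer_recipe

TIME_AXIS = -100.0 + 10.0 * np.arange(40)


def partial_corr_precision_oracle(x, y, controls):
    """Partial correlation via the inverse-correlation-matrix formula."""
    from scipy.stats import rankdata

    mat = np.column_stack([rankdata(x), rankdata(y)] + [rankdata(c) for c in controls])
    p = np.linalg.inv(np.corrcoef(mat.T))
    return -p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])


def stack_from_vectors(vectors, ids, time_axis):
    """(S, T, m) vectors -> RDMStack (symmetric fill)."""
    s, t, m = vectors.shape
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    values = np.zeros((s, t, n, n))
    for si in range(s):
        for ti in range(t):
            mvals = np.zeros((n, n))
            mvals[iu] = vectors[si, ti]
            values[si, ti] = mvals + mvals.T
    return RDMStack(values=values, ids=ids, time_axis=time_axis, kind="abs_difference")


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert spearman_rsa(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rsa(x, -x) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=(2, 40))
            oracle = stats.spearmanr(x, y).statistic
            assert spearman_rsa(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(spearman_rsa(np.ones(10), np.arange(10.0)))


class TestPartialSpearman:
    def test_empty_controls_reduces_to_spearman(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 30))
        assert partial_spearman_rsa(x, y) == spearman_rsa(x, y)

    def test_orthogonal_controls_leave_correlation(self):
        rng = np.random.default_rng(3)
        x = np.arange(60.0)
        y = x + rng.normal(size=60) * 1e-6
        c = rng.normal(size=60)
        full = spearman_rsa(x, y)
        part = partial_spearman_rsa(x, y, [c])
        assert part == pytest.approx(full, abs=0.05)

    def test_y_equal_to_control_gives_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert partial_spearman_rsa(x, y, [y]) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n_controls", [1, 2, 3])
    def test_matches_precision_matrix_oracle(self, n_controls):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x, y = rng.normal(size=(2, 50))
            controls = [rng.normal(size=50) for _ in range(n_controls)]
            got = partial_spearman_rsa(x, y, controls)
            oracle = partial_corr_precision_oracle(x, y, controls)
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_collinear_controls_named(self):
        rng = np.random.default_rng(6)
        x, y, c = rng.normal(size=(3, 30))
        with pytest.raises(RDMError, match=r"control\[0\].*control\[1\]"):
            partial_spearman_rsa(x, y, [c, 2 * c + 5])


class TestRSATimecourse:
    def test_shuffled_target_flat_near_zero(self, conditions20, hyps20):
        rng = np.random.default_rng(7)
        target = hyps20["real_world_size"]
        # neural stack that actually tracks the size RDM at every timepoint
        tv = vectorize_upper(target).values
        vecs = np.stack(
            [[tv + rng.normal(scale=tv.std(), size=tv.size) for _ in range(6)]
             for _ in range(2)]
        )
        stack = stack_from_vectors(np.abs(vecs), target.ids, 10.0 * np.arange(6))
        tc = rsa_timecourse(stack, target)
        assert tc.group_mean.min() > 0.2
        # breaking the condition correspondence destroys the correlation
        perm = rng.permutation(len(target.ids))
        shuffled = RDM(
            ids=target.ids, values=target.values[np.ix_(perm, perm)], kind=target.kind
        )
        tc2 = rsa_timecourse(stack, shuffled)
        assert abs(tc2.group_mean.mean()) < 0.1

    def test_duplicate_control_rejected(self, hyps20, conditions20):
        target = hyps20["real_world_size"]
        stack = stack_from_vectors(
            np.abs(np.random.default_rng(8).normal(size=(1, 3, 190))),
            target.ids,
            [0.0, 10.0, 20.0],
        )
        with pytest.raises(RDMError, match="duplicates the target"):
            rsa_timecourse(stack, target, [target])

    def test_id_mismatch_lists_differences(self, hyps20):
        stack = stack_from_vectors(
            np.abs(np.random.default_rng(9).normal(size=(1, 2, 6))),
            ("x1", "x2", "x3", "x4"),
            [0.0, 10.0],
        )
        with pytest.raises(RDMError, match="mismatch"):
            rsa_timecourse(stack, hyps20["real_world_size"])


class TestClusterPermutation:
    def test_injected_cluster_recovered(self):
        rng = np.random.default_rng(10)
        values = 0.05 * rng.normal(size=(10, 40))
        values[:, 17:25] += 0.4
        tc = RSATimecourse(values=values, time_axis=TIME_AXIS, target="x")
        res = cluster_permutation_test(tc, n_permutations=500, seed=1)
        sig = res.significant_clusters
        assert len(sig) == 1
        assert sig[0].start_ms >= TIME_AXIS[15] and sig[0].end_ms <= TIME_AXIS[26]
        assert res.mask[17:25].all()

    def test_p_floor_is_one_over_nplus1(self):
        rng = np.random.default_rng(11)
        values = 0.01 * rng.normal(size=(12, 40)) + 0.5
        tc = RSATimecourse(values=values, time_axis=TIME_AXIS, target="x")
        res = cluster_permutation_test(tc, n_permutations=200, seed=2)
        assert min(c.p_value for c in res.clusters) >= 1.0 / 201.0

    def test_zero_variance_timepoint_excluded_with_warning(self):
        rng = np.random.default_rng(12)
        values = 0.05 * rng.normal(size=(8, 20))
        values[:, 3] = 0.25  # exactly equal across subjects
        tc = RSATimecourse(values=values, time_axis=TIME_AXIS[:20], target="x")
        with pytest.warns(UserWarning, match="zero across-subject variance"):
            res = cluster_permutation_test(tc, n_permutations=100, seed=3)
        assert not res.mask[3]

    def test_requires_two_subjects(self):
        tc = RSATimecourse(
            values=np.zeros((1, 10)), time_axis=TIME_AXIS[:10], target="x"
        )
        with pytest.raises(RDMError):
            cluster_permutation_test(tc)


class TestBootstrapPeakLatency:
    def test_dominant_unique_peak_is_never_moved(self, hyps20):
        target = hyps20["real_world_size"]
        tv = vectorize_upper(target).values
        t = 8
        vecs = np.full((1, t, tv.size), 1.0)
        vecs += 0.01 * np.random.default_rng(13).random((1, t, tv.size))
        vecs[0, 5] = tv  # perfect correlation only at sample 5
        stack = stack_from_vectors(vecs, target.ids, 10.0 * np.arange(t))
        res = bootstrap_peak_latency(
            stack, target, window=(0.0, 70.0), n_bootstrap=50, seed=4
        )
        assert np.all(res.latencies == 50.0)
        assert res.group_mean == 50.0

    def test_tie_breaks_to_earliest_sample(self, hyps20):
        target = hyps20["real_world_size"]
        tv = vectorize_upper(target).values
        vecs = np.zeros((1, 4, tv.size))
        vecs[0, 1] = tv
        vecs[0, 3] = tv  # identical second peak
        stack = stack_from_vectors(vecs, target.ids, 10.0 * np.arange(4))
        res = bootstrap_peak_latency(
            stack, target, window=(0.0, 30.0), n_bootstrap=20, seed=5
        )
        assert np.all(res.latencies == 10.0)

    def test_window_outside_axis_rejected(self, hyps20):
        target = hyps20["real_world_size"]
        stack = stack_from_vectors(
            np.abs(np.random.default_rng(14).normal(size=(1, 3, 190))),
            target.ids,
            [0.0, 10.0, 20.0],
        )
        with pytest.raises(RDMError, match="window"):
            bootstrap_peak_latency(stack, target, window=(500.0, 600.0))


class TestPairedLatencyTest:
    def _result(self, means):
        from sizersa.inference import PeakLatencyResult

        means = np.asarray(means, dtype=float)
        return PeakLatencyResult(
            latencies=means[:, None],
            subject_means=means,
            group_mean=float(means.mean()),
            group_sem=0.0,
            n_bootstrap=1,
            search_window_ms=(0.0, 300.0),
        )

    def test_identical_inputs(self):
        a = self._result([100.0, 120.0, 140.0])
        t, df, p = paired_latency_test(a, a)
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_shift_degenerate(self):
        a = self._result([100.0, 120.0, 140.0])
        b = self._result([130.0, 150.0, 170.0])
        with pytest.warns(UserWarning, match="zero variance"):
            t, df, p = paired_latency_test(b, a)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(15)
        x = rng.normal(100, 10, size=10)
        y = rng.normal(110, 10, size=10)
        t, df, p = paired_latency_test(self._result(x), self._result(y))
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
        assert df == 9


class TestModelHypPartialTest:
    def test_identity_model_flags_only_size(self, conditions20, hyps20):
        res = model_hyp_partial_test(
            hyps20["real_world_size"], hyps20, n_shuffles=500, seed=6
        )
        assert res.observed["real_world_size"] == pytest.approx(1.0, abs=1e-9)
        assert res.significant["real_world_size"]
        assert abs(res.observed["retinal_size"]) < 1e-9
        assert abs(res.observed["real_world_depth"]) < 1e-9
        assert not res.significant["retinal_size"]
        assert not res.significant["real_world_depth"]

    def test_late_recipe_flags_size(self, conditions20, hyps20):
        x = simulate_model_features(conditions20, late_layer_recipe(), seed=17)
        res = model_hyp_partial_test(
            rdm_from_feature_vectors(conditions20.ids, x), hyps20, seed=7
        )
        assert res.significant["real_world_size"]

    def test_flag_definition_uses_critical_value(self, conditions20, hyps20):
        res = model_hyp_partial_test(
            hyps20["retinal_size"], hyps20, n_shuffles=300, seed=8
        )
        for f in FEATURES:
            assert res.significant[f] == (res.observed[f] > res.critical[f])
            assert res.null[f].shape == (300,)


class TestVariancePartitioning:
    def test_single_regressor_unique_equals_full(self):
        rng = np.random.default_rng(18)
        y = rng.normal(size=60)
        a = y + rng.normal(size=60)
        b = rng.normal(size=60)
        vp = variance_partitioning(y, {"a": a, "b": b})
        # unique(a) + unique(b) + shared(a,b) == full R2
        total = vp.unique("a") + vp.unique("b") + vp.shared("a", "b")
        assert total == pytest.approx(vp.r2_full, abs=1e-10)

    def test_orthogonal_regressors_zero_shared(self):
        # ranks of these patterns are exactly orthogonal by construction
        y = np.array([1.0, 2.0, 3.0, 4.0] * 8)
        a = np.tile([1.0, 2.0, 1.0, 2.0], 8)
        b = np.tile([1.0, 1.0, 2.0, 2.0], 8)
        vp = variance_partitioning(y, {"a": a, "b": b})
        assert vp.shared("a", "b") == pytest.approx(0.0, abs=1e-10)

    def test_three_regressors_match_subset_r2_oracle(self):
        from itertools import combinations
        from scipy.stats import rankdata

        rng = np.random.default_rng(19)
        y = rng.normal(size=80)
        regs = {k: rng.normal(size=80) + 0.5 * y for k in ("a", "b", "c")}
        vp = variance_partitioning(y, regs)

        # independent oracle: R2 from squared multiple correlation
        def oracle_r2(sub):
            mat = np.column_stack(
                [rankdata(y)] + [rankdata(regs[s]) for s in sub]
            )
            c = np.corrcoef(mat.T)
            return 1.0 - np.linalg.det(c) / np.linalg.det(c[1:, 1:])

        # inclusion-exclusion on the oracle R2s
        all_names = ("a", "b", "c")
        for k in range(1, 4):
            for sub in combinations(all_names, k):
                total = 0.0
                for kk in range(len(sub) + 1):
                    for t in combinations(sub, kk):
                        rest = tuple(x for x in all_names if x not in t)
                        total += (-1.0) ** kk * (oracle_r2(rest) if rest else 0.0)
                expected = (-1.0) ** (len(sub) + 1) * total
                assert vp.components[frozenset(sub)] == pytest.approx(
                    expected, abs=1e-10
                )
        assert sum(vp.components.values()) == pytest.approx(vp.r2_full, abs=1e-10)

    def test_collinear_regressors_rejected(self):
        y = np.random.default_rng(20).normal(size=30)
        a = np.arange(30.0)
        with pytest.raises(RDMError, match="collinear"):
            variance_partitioning(y, {"a": a, "b": 2 * a})


class TestNoiseCeiling:
    def test_identical_subjects_ceiling_one(self, hyps20):
        tv = vectorize_upper(hyps20["real_world_size"]).values
        vecs = np.tile(tv, (4, 3, 1))
        stack = stack_from_vectors(vecs, hyps20.real_world_size.ids, [0.0, 10.0, 20.0])
        lower, upper = noise_ceiling(stack)
        np.testing.assert_allclose(lower, 1.0, atol=1e-12)
        np.testing.assert_allclose(upper, 1.0, atol=1e-12)

    def test_independent_noise_near_zero_and_lower_below_upper(self, hyps20):
        rng = np.random.default_rng(21)
        vecs = np.abs(rng.normal(size=(6, 5, 190)))
        stack = stack_from_vectors(vecs, hyps20.real_world_size.ids, 10.0 * np.arange(5))
        lower, upper = noise_ceiling(stack)
        assert np.all(lower <= upper + 1e-9)
        # leave-one-out bound has no shared structure left at all; the upper
        # bound retains only the sqrt(1/S) self-correlation of the mean
        assert abs(lower.mean()) < 0.1
        assert upper.mean() < np.sqrt(1 / 6) + 0.1

    def test_ceiling_grows_with_subject_count(self, hyps20):
        tv = vectorize_upper(hyps20["real_world_size"]).values
        signal = (tv - tv.mean()) / tv.std()
        rng = np.random.default_rng(23)

        def mean_lower(s, reps=5):
            vals = []
            for _ in range(reps):
                vecs = signal + 2.0 * rng.normal(size=(s, 1, signal.size))
                stack = stack_from_vectors(
                    np.abs(vecs), hyps20.real_world_size.ids, [0.0]
                )
                vals.append(noise_ceiling(stack)[0][0])
            return np.mean(vals)

        vals = [mean_lower(s) for s in (3, 6, 12)]
        assert vals[0] < vals[1] < vals[2]

    def test_requires_three_subjects(self, hyps20):
        vecs = np.abs(np.random.default_rng(22).normal(size=(2, 2, 190)))
        stack = stack_from_vectors(vecs, hyps20.real_world_size.ids, [0.0, 10.0])
        with pytest.raises(RDMError, match="3 subjects"):
            noise_ceiling(stack)
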