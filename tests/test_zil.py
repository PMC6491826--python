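import math

import numpy as np
import pytest
from scipy import integrate, stats

from zilda import (
    CountTable,
    DivisorSpec,
    SampleMetadata,
    compute_ratios,
    fit_zil_em,
    fit_zil_em_state,
    run_differential,
    select_divisor,
    simulate_zil_vector,
    zil_density,
)
from zilda import test_feature as feature_ttest
from zilda.simulate import SimConfig, simulate_study
from zilda.zil import ZILError


class TestZilDensity:
    def test_pure_lognormal_component_closed_form(self):
        val = zil_density(1.0, (0.0, 0.0, 1.0), epsilon=0.01)
        assert val == pytest.approx(1.0 / math.sqrt(2 * math.pi), abs=1e-12)

    def test_pure_dropout_component_is_uniform(self):
        assert zil_density(0.05, (1.0, 0.0, 1.0), epsilon=0.1) == pytest.approx(10.0)
        assert zil_density(0.2, (1.0, 0.0, 1.0), epsilon=0.1) == pytest.approx(0.0)

    def test_density_integrates_to_one(self):
        # the uniform spike and the lognormal bulk are integrated separately
        # so quadrature resolves both scales
        p, mu, sigma, eps = 0.3, 1.0, 0.5, 0.01
        f = lambda r: zil_density(r, (p, mu, sigma), eps)
        spike, _ = integrate.quad(f, 1e-300, eps, limit=200)
        bulk, _ = integrate.quad(f, eps, np.inf, limit=200)
        assert spike + bulk == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ZILError):
            zil_density(0.0, (0.3, 0.0, 1.0), 0.01)


class TestFitZilEm:
    def test_no_zeros_collapses_to_lognormal_mle(self):
        rng = np.random.default_rng(0)
        r = np.exp(rng.normal(1.0, 0.5, 200))
        fit = fit_zil_em(r, epsilon=float(r.min()))
        y = np.log(r)
        assert fit.p == 0.0
        assert fit.mu == pytest.approx(y.mean(), abs=1e-12)
        assert fit.sigma == pytest.approx(y.std(), abs=1e-12)
        assert fit.converged

    def test_recovers_planted_parameters(self):
        errs = []
        for seed in range(20):
            v = simulate_zil_vector(500, 0.3, 1.0, 0.5, 0.01, seed)
            fit = fit_zil_em(v, epsilon=0.01)
            errs.append([abs(fit.p - 0.3), abs(fit.mu - 1.0), abs(fit.sigma - 0.5)])
        med = np.median(np.array(errs), axis=0)
        assert (med <= 0.08).all()

    def test_identical_positive_values_hit_sigma_floor(self):
        fit = fit_zil_em(np.array([2.0, 2.0, 2.0]), epsilon=0.5)
        assert fit.sigma == pytest.approx(1e-6)
        assert fit.converged

    def test_loglik_trace_monotone_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(0.0, 0.8)
            mu = rng.uniform(-2, 2)
            sigma = rng.uniform(0.2, 1.5)
            v = simulate_zil_vector(60, p, mu, sigma, 0.01, int(rng.integers(2**31)))
            if (v > 0).sum() < 3:
                continue
            fit = fit_zil_em(v, epsilon=float(v[v > 0].min()))
            assert (np.diff(fit.trace) >= -1e-10).all()

    def test_all_zero_and_too_few_positive_rejected(self):
        with pytest.raises(ZILError, match="zero"):
            fit_zil_em(np.zeros(10), epsilon=0.1)
        with pytest.raises(ZILError, match="3 positive"):
            fit_zil_em(np.array([0.0, 0.0, 1.0, 2.0]), epsilon=0.1)

    def test_positive_entries_have_zero_responsibility(self):
        v = simulate_zil_vector(100, 0.4, 0.0, 1.0, 0.01, 3)
        _, state = fit_zil_em_state(v, epsilon=float(v[v > 0].min()))
        assert (state.tau[v > 0] == 0.0).all()
        assert ((state.tau >= 0) & (state.tau <= 1)).all()


class TestTestFeature:
    def _fit(self, r):
        return fit_zil_em_state(r, epsilon=float(np.min(r[r > 0])))

    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(1)
        r = np.exp(rng.normal(0, 1, 30))
        pa, sa = self._fit(r)
        res = feature_ttest(pa, sa, pa, sa)
        assert res.t_stat == 0.0
        assert res.p_value == 1.0

    def test_matches_classical_welch_without_zeros(self):
        rng = np.random.default_rng(2)
        ra = np.exp(rng.normal(0.0, 1.0, 25))
        rb = np.exp(rng.normal(0.5, 1.3, 35))
        pa, sa = self._fit(ra)
        pb, sb = self._fit(rb)
        res = feature_ttest(pa, sa, pb, sb)
        t_ref, p_ref = stats.ttest_ind(np.log(rb), np.log(ra), equal_var=False)
        assert res.t_stat == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_large_offset_is_highly_significant(self):
        rng = np.random.default_rng(3)
        ra = np.exp(rng.normal(0.0, 0.5, 50))
        rb = np.exp(rng.normal(2.0, 0.5, 50))
        pa, sa = self._fit(ra)
        pb, sb = self._fit(rb)
        res = feature_ttest(pa, sa, pb, sb)
        assert res.p_value < 1e-6
        assert res.delta_mu == pytest.approx(2.0, abs=0.5)

    def test_null_p_values_are_uniform(self):
        """Without zeros the test is Welch's t, so null p-values are uniform."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(2000):
            ra = np.exp(rng.normal(0.0, 1.0, 40))
            rb = np.exp(rng.normal(0.0, 1.0, 40))
            pa, sa = self._fit(ra)
            pb, sb = self._fit(rb)
            pvals.append(feature_ttest(pa, sa, pb, sb).p_value)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05


class TestDivisorAndRatios:
    def test_single_all_positive_feature_is_forced_choice(self):
        t = CountTable(
            ["zf", "ref"],
            ["s1", "s2", "s3"],
            np.array([[0.0, 1.0, 2.0], [5.0, 5.0, 5.0]]),
        )
        spec = select_divisor(t)
        assert spec.feature_ids == ("ref",)

    def test_min_variance_matches_exhaustive_oracle(self, small_study):
        table, _, truth = small_study
        spec = select_divisor(table)
        allpos = (table.values > 0).all(axis=1)
        logrel = np.log(table.values[allpos] / table.values.sum(axis=0))
        oracle = np.array(table.feature_ids)[allpos][np.argmin(logrel.var(axis=1))]
        assert spec.feature_ids == (oracle,)
        assert spec.feature_ids == (truth.reference_id,)

    def test_no_all_positive_feature_errors(self):
        t = CountTable(
            ["a", "b"], ["s1", "s2"], np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        with pytest.raises(ZILError, match="positive in every sample"):
            select_divisor(t)

    def test_manual_divisor_with_zero_names_sample(self):
        t = CountTable(
            ["a", "b"], ["s1", "s2"], np.array([[1.0, 0.0], [1.0, 1.0]])
        )
        with pytest.raises(ZILError, match="s2"):
            select_divisor(t, strategy="manual", manual_features=["a"])

    def test_ratios_values_epsilon_and_self_ratio(self):
        t = CountTable(
            ["a", "b", "ref", "copy"],
            ["s1", "s2", "s3"],
            np.array(
                [
                    [4.0, 1.0, 0.0],
                    [0.0, 4.0, 1.0],
                    [2.0, 2.0, 2.0],
                    [2.0, 2.0, 2.0],  # equal to the divisor row
                ]
            ),
        )
        rt = compute_ratios(t, DivisorSpec(("ref",)))
        assert "ref" not in rt.feature_ids
        i_a = rt.feature_ids.index("a")
        np.testing.assert_allclose(rt.ratios[i_a], [2.0, 0.5, 0.0])
        i_copy = rt.feature_ids.index("copy")
        np.testing.assert_allclose(rt.ratios[i_copy], 1.0)
        assert rt.epsilon == pytest.approx(0.5)
        assert rt.zero_mask[i_a, 2]

    def test_divisor_zero_is_an_error(self):
        t = CountTable(["a", "d"], ["s1", "s2"], np.array([[1.0, 2.0], [1.0, 0.0]]))
        with pytest.raises(ZILError, match="zero in sample"):
            compute_ratios(t, DivisorSpec(("d",)))


class TestRunDifferential:
    def test_scale_equivariance(self, small_study):
        """Rescaling any sample column (sequencing depth) changes nothing."""
        table, metadata, _ = small_study
        scaled = CountTable(
            list(table.feature_ids), list(table.sample_ids), table.values.copy()
        )
        scaled.values[:, 0] *= 37.5
        scaled.values[:, -1] *= 0.04
        a = run_differential(table, metadata, "healthy", "crc").frame
        b = run_differential(scaled, metadata, "healthy", "crc").frame
        np.testing.assert_allclose(
            a[["p_value", "q_value", "delta_mu"]].to_numpy(),
            b[["p_value", "q_value", "delta_mu"]].to_numpy(),
            rtol=1e-9,
        )
        assert list(a["feature_id"]) == list(b["feature_id"])

    def test_recovers_planted_effects(self, small_study):
        table, metadata, truth = small_study
        diff = run_differential(table, metadata, "healthy", "crc")
        sig = set(diff.significant_ids())
        tp = len(sig & truth.differential_ids)
        assert tp / len(truth.differential_ids) >= 0.8
        assert len(sig - truth.differential_ids) / max(len(sig), 1) <= 0.2

    def test_too_small_group_rejected(self):
        cfg = SimConfig(
            seed=0,
            n_features=20,
            n_samples_per_group={"healthy": 5, "crc": 5},
            frac_differential=0.0,
        )
        table, metadata, _ = simulate_study(cfg)
        metadata = [m for m in metadata if m.group == "healthy"] + [
            m for m in metadata if m.group == "crc"
        ][:1]
        table = table.subset_samples([m.sample_id for m in metadata])
        with pytest.raises(ZILError, match="at least 3 samples"):
            run_differential(table, metadata, "healthy", "crc")

    def test_bh_adjustment_matches_textbook_step_up(self, small_study):
        table, metadata, _ = small_study
        diff = run_differential(table, metadata, "healthy", "crc")
        frame = diff.frame.sort_values("p_value").reset_index(drop=True)
        p = frame["p_value"].to_numpy()
        m = len(p)
        # textbook BH step-up computed independently
        adj = p * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        np.testing.assert_allclose(frame["q_value"].to_numpy(), adj, atol=1e-12)
        # monotone after step-up enforcement
        assert (np.diff(frame["q_value"].to_numpy()) >= -1e-12).all()


def test_bh_hand_computed_example():
    """BH on a fixed 10-value example reproduces the hand-worked procedure."""
    from statsmodels.stats.multitest import multipletests

    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.368])
    reject, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    expected_q = np.array(
        [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714286, 0.235555555555556, 0.235555555555556, 0.368]
    )
    np.testing.assert_allclose(q, expected_q, atol=1e-12)
    assert list(reject) == [True, True, False, False, False, False, False, False, False, False]
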