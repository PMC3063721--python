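"""Likelihood-ratio causality measure, deviance tests and FDR control."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ppgranger as pg
from ppgranger.granger import GrangerAnalysis
from ppgranger.simulate import NetworkSpec
from .test_glm import brute_force_loglike


class FakeFit:
    """Minimal stand-in exposing fitted history coefficients."""

    def __init__(self, gammas):
        self._g = {k: np.asarray(v, float) for k, v in gammas.items()}

    def gamma(self, source):
        return self._g[source]


class TestCausalSign:
    def test_excitatory_coefficients(self):
        assert pg.causal_sign(FakeFit({1: [1, 2, 2]}), 1, 0) == 1

    def test_inhibitory_coefficients(self):
        assert pg.causal_sign(FakeFit({1: [-0.8, -0.6, -0.3]}), 1, 0) == -1

    def test_self_interaction_ignores_first_window(self):
        # refractory forces the first window negative; omit it for self-pairs
        assert pg.causal_sign(FakeFit({0: [-2.0, 0.5, 0.4]}), 0, 0) == 1

    def test_single_window_self_uses_lone_coefficient(self):
        assert pg.causal_sign(FakeFit({0: [-1.5]}), 0, 0) == -1


class TestCausalityMeasure:
    def test_zero_ratio_gives_zero(self):
        assert pg.causality_measure(0.0, 1) == 0.0

    def test_signed_definition(self):
        assert pg.causality_measure(-10.0, -1) == -10.0
        assert pg.causality_measure(-3.5, 1) == 3.5

    def test_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            pg.causality_measure(0.1, 1)


class TestDevianceTest:
    def test_zero_statistic_gives_p_one(self):
        assert pg.deviance_test(0.0, 3) == 1.0

    def test_chi2_quantile(self):
        # chi-squared(3) upper 5% critical value is 7.815
        assert pg.deviance_test(-7.815 / 2, 3) == pytest.approx(0.05, abs=5e-4)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="negative deviance"):
            pg.deviance_test(0.5, 2)


class TestFdr:
    def test_all_ones_never_rejected(self):
        assert not pg.fdr_correct(np.ones((3, 3)), 0.05).any()

    def test_step_up_hand_example(self):
        # p=(0.01,0.02,0.03,0.04), m=4, q=0.05: largest i with
        # p(i) <= i*0.05/4 is i=4 (0.04 <= 0.05) -> reject all four
        mask = pg.fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert mask.all()

    def test_nan_entries_never_rejected(self):
        p = np.array([1e-6, np.nan, 0.5])
        mask = pg.fdr_correct(p, 0.05)
        assert mask[0] and not mask[1] and not mask[2]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_rejections_monotone_in_q(self, ps):
        p = np.asarray(ps)
        tight = pg.fdr_correct(p, 0.01)
        loose = pg.fdr_correct(p, 0.05)
        assert (loose | ~tight).all()  # tight rejections are subset of loose

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            pg.fdr_correct(np.ones(3), 1.5)


class TestLikelihoodRatio:
    def test_oracle_equivalence_on_small_instance(self, rng):
        counts = (rng.random((3, 400)) < 0.12).astype(np.int8)
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = pg.CIFGLM(binned, 0, hw).fit()
        red = GrangerAnalysis(binned, 2, 0.002)._fit_reduced(full, 2)
        llr = pg.log_likelihood_ratio(full, red)
        bf_full = brute_force_loglike(binned, 0, hw, full.params)
        bf_red = brute_force_loglike(binned, 0, hw, red.params, excluded=2)
        assert llr == pytest.approx(bf_red - bf_full, rel=1e-6, abs=1e-8)

    def test_not_nested_rejected(self, poisson_pair):
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = pg.CIFGLM(poisson_pair, 0, hw).fit()
        with pytest.raises(ValueError, match="nested|reduced"):
            pg.log_likelihood_ratio(full, full)

    def test_strong_coupling_far_in_tail(self, fig1_run):
        # within-sub-network excitation 1 -> 2 in the nine-neuron benchmark
        _, _, binned = fig1_run
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = pg.CIFGLM(binned, 1, hw).fit()
        red = GrangerAnalysis(binned, 2, 0.002)._fit_reduced(full, 0)
        llr = pg.log_likelihood_ratio(full, red)
        assert llr < 0
        from scipy import stats

        assert -2 * llr > stats.chi2(2).ppf(0.999)


class TestInferNetwork:
    def test_global_null_rarely_rejects(self):
        spec = NetworkSpec(n_neurons=3, edges=(), baseline_rate=18.0,
                           refractory=0.0)
        clean = 0
        for seed in range(8):
            binned = pg.bin_spikes(pg.simulate(spec, 10_000, seed=seed))
            res = pg.infer_network(binned, 2, 0.002, q=0.05)
            clean += res.n_significant() == 0
        # BH controls the familywise error under the global null at q
        assert clean >= 6

    def test_result_matrices_and_na_policy(self, fig1_run):
        spec, _, binned = fig1_run
        res = pg.GrangerAnalysis(binned, 3, 0.002, q=0.05).fit()
        assert res.deviance_diff[np.isfinite(res.deviance_diff)].min() >= 0
        finite = np.isfinite(res.p_values)
        assert ((res.p_values[finite] >= 0) & (res.p_values[finite] <= 1)).all()
        # connectivity zero exactly where FDR fails to reject
        rej = pg.fdr_correct(res.p_values, 0.05)
        conn = res.connectivity
        assert ((conn == 0) == (~rej & finite)).all()
        sign_ok = (conn == 0) | ~finite | (conn == np.sign(res.gamma_matrix))
        assert sign_ok.all()

    def test_csv_export_round_trip(self, fig1_run, tmp_path):
        import pandas as pd

        _, _, binned = fig1_run
        res = pg.GrangerAnalysis(binned, [2] * 9, 0.002).fit()
        paths = res.to_csv(tmp_path)
        conn = pd.read_csv(paths["connectivity"], index_col="trigger")
        assert conn.shape == (9, 9)
        assert set(np.unique(conn.values.astype(str))) <= {"-1", "0", "1", "NA"}
        gamma = pd.read_csv(paths["gamma"], index_col="trigger")
        np.testing.assert_allclose(gamma.values, res.gamma_matrix, atol=1e-12)
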