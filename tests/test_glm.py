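"""Conditional-intensity GLM: design, likelihood, fitting, order selection."""

import numpy as np
import pytest

import ppgranger as pg
from ppgranger.glm import FitData, build_design, log_likelihood
from ppgranger.simulate import Edge, NetworkSpec


def brute_force_loglike(binned, target, hw, params, excluded=None, first_bin=None):
    """Independent per-bin evaluation of the log-CIF and likelihood sum."""
    w = hw.window_bins(binned.delta)
    k0 = hw.R * w if first_bin is None else first_bin
    N, K = binned.counts.shape
    sources = [j for j in range(N) if j != excluded]
    total = 0.0
    for k in range(k0, K):
        eta = params[0]
        col = 1
        for j in sources:
            cnts = pg.window_counts(binned, j, k, hw)
            for r in range(hw.R):
                eta += params[col] * cnts[r]
                col += 1
        lam = np.exp(eta)
        total += binned.counts[target, k] * np.log(max(lam, 1e-12)) - lam
    return total


class TestDesign:
    def test_single_neuron_lag_one_design(self, rng):
        # N=1, R=1, W=delta: the history column is the train lagged one bin
        counts = (rng.random((1, 50)) < 0.3).astype(np.int8)
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        fd = build_design(binned, 0, pg.HistoryWindows(W=0.001, R=1))
        np.testing.assert_array_equal(fd.X[:, 1], counts[0, :-1])
        np.testing.assert_array_equal(fd.y, counts[0, 1:])

    def test_excluding_source_drops_its_columns(self, rng):
        counts = (rng.random((2, 60)) < 0.2).astype(np.int8)
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = build_design(binned, 0, hw)
        red = build_design(binned, 0, hw, excluded=0)
        assert full.X.shape[1] == 1 + 2 * 2
        assert red.X.shape[1] == 1 + 1 * 2
        # remaining numeric content unchanged
        np.testing.assert_array_equal(red.X[:, 1:], full.X[:, 3:])

    def test_excluding_zero_row_source_changes_nothing_numeric(self):
        counts = np.zeros((2, 40), dtype=int)
        counts[0, ::7] = 1
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = build_design(binned, 0, hw)
        red = build_design(binned, 0, hw, excluded=1)
        np.testing.assert_array_equal(red.X, full.X[:, :3])

    def test_bad_excluded_index(self, poisson_pair):
        with pytest.raises(IndexError):
            build_design(poisson_pair, 0, pg.HistoryWindows(W=0.002, R=1),
                         excluded=5)


class TestLogLikelihood:
    def test_closed_form_constant_intensity(self):
        # all-zero response, lambda*delta = 0.018 over 100,000 bins
        fd = FitData(y=np.zeros(100_000), X=np.ones((100_000, 1)), target=0,
                     hw=None, excluded=None)
        llf = log_likelihood([np.log(0.018)], fd)
        assert llf == pytest.approx(-1800.0, rel=1e-12)

    def test_matches_brute_force_per_bin_loop(self, rng):
        counts = (rng.random((2, 80)) < 0.25).astype(np.int8)
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        hw = pg.HistoryWindows(W=0.002, R=2)
        fd = build_design(binned, 1, hw)
        params = rng.normal(0, 0.3, fd.n_params)
        params[0] = -2.0
        got = log_likelihood(params, fd)
        expect = brute_force_loglike(binned, 1, hw, params)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_shape_mismatch_rejected(self, poisson_pair):
        fd = build_design(poisson_pair, 0, pg.HistoryWindows(W=0.002, R=2))
        with pytest.raises(ValueError, match="does not match"):
            log_likelihood([0.0], fd)


class TestFitting:
    def test_baseline_only_mle_is_mean_rate(self, poisson_pair):
        res = pg.CIFGLM(poisson_pair, 0, None).fit()
        assert np.exp(res.beta0) == pytest.approx(
            poisson_pair.counts[0].mean(), rel=1e-8)

    def test_baseline_only_matches_saturated_in_mean_poisson(self, poisson_pair):
        # per-bin loop with lambda*delta = empirical mean
        y = poisson_pair.counts[0].astype(float)
        lam = y.mean()
        expect = float(np.sum(y * np.log(lam) - lam))
        res = pg.CIFGLM(poisson_pair, 0, None).fit()
        assert res.llf == pytest.approx(expect, rel=1e-10)

    def test_silent_target_rejected(self):
        counts = np.zeros((2, 50), dtype=int)
        counts[1, ::5] = 1
        binned = pg.BinnedEnsemble(counts, delta=0.001)
        with pytest.raises(ValueError, match="degenerate response"):
            pg.CIFGLM(binned, 0, pg.HistoryWindows(W=0.002, R=1))

    def test_agrees_with_statsmodels_glm(self, fig1_run):
        import statsmodels.api as sm

        _, _, binned = fig1_run
        hw = pg.HistoryWindows(W=0.002, R=2)
        model = pg.CIFGLM(binned, 3, hw)
        res = model.fit()
        ref = sm.GLM(model.data.y, model.data.X,
                     family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params, ref.params, atol=1e-7)
        assert res.llf == pytest.approx(ref.llf, rel=1e-10)

    def test_parameter_recovery_within_three_se(self):
        # generate from a window-structured log-linear model (per-bin lags
        # constant within each 2-ms window) so the fitted GLM is correctly
        # specified, then check 3-sigma coverage of the true coefficients
        true = {(1, 1): [0.8, 0.8, 1.2, 1.2],   # window coefs (0.8, 1.2)
                (2, 2): [-0.5, -0.5, -0.9, -0.9]}
        spec = NetworkSpec(
            n_neurons=2, baseline_rate=18.0, refractory=0.0,
            edges=tuple(Edge(s, t, tuple(c)) for (s, t), c in true.items()),
        )
        hw = pg.HistoryWindows(W=0.002, R=2)
        hits = total = 0
        for seed in range(5):
            ens = pg.simulate(spec, 60_000, seed=seed)
            binned = pg.bin_spikes(ens)
            for target, truth in [(0, [0.8, 1.2, 0.0, 0.0]),
                                  (1, [0.0, 0.0, -0.5, -0.9])]:
                res = pg.CIFGLM(binned, target, hw).fit()
                se = res.bse[1:]
                est = res.params[1:]
                hits += int(np.sum(np.abs(est - truth) <= 3 * se))
                total += len(truth)
        assert hits / total >= 0.9

    def test_reduced_refit_never_beats_full(self, fig1_run):
        _, _, binned = fig1_run
        hw = pg.HistoryWindows(W=0.002, R=2)
        full = pg.CIFGLM(binned, 0, hw).fit()
        for j in (0, 4, 8):
            red = pg.CIFGLM(binned, 0, hw, excluded=j).fit()
            assert red.llf <= full.llf + 1e-6 * abs(full.llf)

    def test_serialisation_round_trip_fields(self, poisson_pair, tmp_path):
        import json

        res = pg.CIFGLM(poisson_pair, 0, pg.HistoryWindows(W=0.002, R=2)).fit()
        path = tmp_path / "model.json"
        res.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["target"] == 0 and doc["R"] == 2
        np.testing.assert_allclose(doc["params"], res.params)


class TestOrderSelection:
    def test_single_candidate_returned(self, poisson_pair):
        r, table = pg.select_order_aic(poisson_pair, 0, 0.002, [3])
        assert r == 3 and set(table) == {3}

    def test_aic_formula(self, poisson_pair):
        res = pg.CIFGLM(poisson_pair, 0, pg.HistoryWindows(W=0.002, R=2)).fit()
        assert res.aic == pytest.approx(-2 * res.llf + 2 * 5)

    def test_selection_consistency_for_true_order_two(self):
        # strong self-history spanning exactly two 2-ms windows
        spec = NetworkSpec(
            n_neurons=1, baseline_rate=18.0, refractory=0.0,
            edges=(Edge(1, 1, (1.2, 1.2, -1.5, -1.5)),),
        )
        chosen = []
        for seed in range(6):
            binned = pg.bin_spikes(pg.simulate(spec, 40_000, seed=seed))
            chosen.append(pg.select_order_aic(binned, 0, 0.002, range(1, 5))[0])
        assert np.bincount(chosen).argmax() == 2
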