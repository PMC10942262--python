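"""Validation statistics, consistency tests and descriptive analytics."""

import numpy as np
import pytest
from scipy import stats

from wormflow.connectome import ConnectomeGraph, PresynapticSet
from wormflow.evaluation import (benjamini_hochberg,
                                 bootstrap_permutation_test,
                                 correlation_matrix, correlation_mse,
                                 ensemble_grid, fourier_power,
                                 lagged_crosscorrelation,
                                 mean_log_likelihood, period_average,
                                 qualify, split_thirds, weight_consistency,
                                 CrossValidationResult)
from wormflow.gkdr import GkdrProjection
from wormflow.gmm_predictor import (GmmJointModel, ModelHyper, NeuronModel,
                                    build_design_matrix, fit_neuron_model)
from wormflow.preprocess import ActivityMatrix


def _std_normal_model(kprime=4):
    """Model whose conditional is N(0, 1) regardless of input."""
    B = np.zeros((kprime, 1))
    B[-1, 0] = 1.0
    gmm = GmmJointModel([1.0], np.zeros((1, 2)), np.stack([np.eye(2)]))
    return NeuronModel("T", PresynapticSet("T", ["T"], "direct"),
                       GkdrProjection(B, np.ones(kprime), 1.0, 1.0, 1e-4),
                       gmm, kprime, 1, 1, 0, 1)


class TestSplitThirds:
    @pytest.mark.parametrize("T,sizes", [
        (6000, (2000, 2000, 2000)),
        (7, (3, 2, 2)),
        (8, (3, 3, 2)),
    ])
    def test_sizes(self, T, sizes):
        parts = split_thirds(T)
        assert tuple(len(p) for p in parts) == sizes

    def test_partition(self):
        parts = split_thirds(100)
        flat = [i for p in parts for i in p]
        assert flat == list(range(100))


class TestMeanLogLikelihood:
    def test_standard_normal_closed_form(self):
        model = _std_normal_model()
        X = np.random.default_rng(0).standard_normal((50, 4))
        y = np.zeros(50)
        assert mean_log_likelihood(model, X, y) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_sharper_predictor_scores_higher(self):
        kprime = 4
        B = np.zeros((kprime, 1)); B[-1, 0] = 1.0
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, kprime))
        scores = []
        for v in (1.0, 0.01):
            gmm = GmmJointModel([1.0], np.zeros((1, 2)),
                                np.array([[[1.0, 1 - v / 2], [1 - v / 2,
                                           1.0]]]))
            m = NeuronModel("T", PresynapticSet("T", ["T"], "direct"),
                            GkdrProjection(B, np.ones(kprime), 1, 1, 1e-4),
                            gmm, kprime, 1, 1, 0, 1)
            # y equal to the conditional mean => only variance matters
            U = X @ B
            y = (1 - v / 2) * U[:, 0]
            scores.append(mean_log_likelihood(m, X, y))
        assert scores[1] > scores[0]

    def test_matches_direct_density_evaluation(self, toy_gmm2):
        from wormflow.gmm_predictor import conditional
        kprime = 3
        B = np.zeros((2 * kprime, 2))
        B[2, 0] = 1.0
        B[5, 1] = 1.0
        m = NeuronModel("T", PresynapticSet("T", ["T", "P"], "direct"),
                        GkdrProjection(B, np.ones(6), 1, 1, 1e-4),
                        toy_gmm2, kprime, 1, 1, 0, 1)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        expected = np.mean([
            np.log(conditional(toy_gmm2, x @ B).pdf(yy))
            for x, yy in zip(X, y)])
        assert mean_log_likelihood(m, X, y) == pytest.approx(
            expected, abs=1e-10)


def _fit_on_slices(seed, null=True, T=480):
    """Fit on the first third of a toy recording; return model + eval data."""
    rng = np.random.default_rng(seed)
    pres = [np.convolve(rng.standard_normal(T + 20), np.ones(5) / 5,
                        "same")[:T] for _ in range(3)]
    if null:
        tgt = rng.standard_normal(T)
    else:
        tgt = np.roll(pres[0], 2) + 0.1 * rng.standard_normal(T)
    values = np.vstack(pres + [tgt])
    names = ["P0", "P1", "P2", "TGT"]
    g = ConnectomeGraph()
    for p in names[:3]:
        g.add_edge(p, "TGT", "chemical", 1)
    hyper = ModelHyper(K=2, kappa=2, kprime=4, tauprime=1, stride=1,
                       offset=0, dt=1, link_mode="direct",
                       use_stimulus=False)
    thirds = split_thirds(T)
    tr, ev = thirds[0], thirds[1]
    ones = np.ones(4, bool)
    act_tr = ActivityMatrix("s", names, values[:, tr.start:tr.stop],
                            ones, ones)
    act_ev = ActivityMatrix("s", names, values[:, ev.start:ev.stop],
                            ones, ones)
    model = fit_neuron_model(act_tr, g, "TGT", hyper, seed)
    X, y, _, _ = build_design_matrix(act_ev, model.pset, hyper)
    return model, X, y


class TestBootstrap:
    def test_informative_presynapse_detected(self):
        model, X, y = _fit_on_slices(100, null=False)
        p, _, _, _ = bootstrap_permutation_test(model, X, y, 100, 1)
        assert p < 0.01

    def test_null_p_not_extreme(self):
        ps = []
        for seed in range(8):
            model, X, y = _fit_on_slices(seed, null=True)
            p, _, _, _ = bootstrap_permutation_test(model, X, y, 100,
                                                    seed + 1)
            ps.append(p)
        # under the null the scores are exchangeable: no mass pile-up at 0
        assert min(ps) > 1e-4 or np.median(ps) > 0.1

    def test_seeded_reproducibility(self):
        model, X, y = _fit_on_slices(7, null=True)
        a = bootstrap_permutation_test(model, X, y, 50, 3)
        b = bootstrap_permutation_test(model, X, y, 50, 3)
        assert a[0] == b[0] and np.array_equal(a[3], b[3])

    def test_self_history_untouched(self):
        """Permutations with only self-input leave the score unchanged."""
        model = _std_normal_model()
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        p, _, obs, null = bootstrap_permutation_test(model, X, y, 20, 0)
        assert np.allclose(null, obs)       # nothing to permute
        assert p == 1.0 or p == 0.0


class TestWeightConsistency:
    def test_all_positive_weights(self):
        p, sign = weight_consistency(np.ones(15))
        # complete separation of 15 vs 15 under the normal approximation
        n1 = n2 = 15
        U = n1 * n2
        z = (U - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        expected = 2 * stats.norm.sf(z)
        assert sign == 1.0
        assert p == pytest.approx(expected, rel=1e-6)

    def test_symmetric_weights_not_significant(self):
        p, _ = weight_consistency(np.array([1.0, -1.0, 2.0, -2.0]))
        assert p == pytest.approx(1.0)

    def test_all_zero(self):
        p, sign = weight_consistency(np.zeros(6))
        assert p == 1.0 and sign == 0.0

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            weight_consistency(np.array([1.0]))


class TestBH:
    def test_hand_worked_example(self):
        reject = benjamini_hochberg([0.001, 0.02, 0.8], fdr=0.005)
        np.testing.assert_array_equal(reject, [True, False, False])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            fdr = 0.05
            # brute-force BH: largest k with p_(k) <= k/m * fdr
            order = np.argsort(p)
            m = p.size
            thresh = (np.arange(1, m + 1) / m) * fdr
            passed = np.where(p[order] <= thresh)[0]
            expected = np.zeros(m, bool)
            if passed.size:
                expected[order[: passed.max() + 1]] = True
            np.testing.assert_array_equal(
                benjamini_hochberg(p, fdr), expected)


class TestEnsemble:
    def test_grid_cardinality(self):
        grid = ensemble_grid()
        assert len(grid) == 45
        assert len({(K, o) for K, o, _ in grid}) == 15

    def test_qualification_rules(self):
        pv = np.ones((3, 3))
        pv[0, :] = 0.001                      # train third 0 passes both
        pv[1, 1] = 0.001                      # train third 1: own third only
        res = CrossValidationResult("T", np.zeros((3, 3)), pv)
        np.testing.assert_array_equal(res.qualified(), [True, False, False])
        combos = qualify({(3, 0): res})
        assert combos == [(3, 0, 0)]

    def test_all_insignificant(self):
        res = CrossValidationResult("T", np.zeros((3, 3)), np.ones((3, 3)))
        assert not res.qualified().any()


class TestAnalytics:
    def test_correlation_mse_identity_and_flip(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((4, 200))
        C = correlation_matrix(A)
        assert correlation_mse(C, C) == 0.0
        C2 = C.copy()
        C2[0, 1] = -C[0, 1]
        C2[1, 0] = -C[1, 0]
        n_off = 4 * 3
        assert correlation_mse(C2, C) == pytest.approx(
            2 * (2 * C[0, 1]) ** 2 / n_off)

    def test_constant_neuron_reported_missing(self):
        A = np.vstack([np.ones(50), np.arange(50.0)])
        C = correlation_matrix(A)
        assert np.isnan(C[0]).all()
        assert C[1, 1] == pytest.approx(1.0)

    def test_ar1_pair_correlation(self):
        rho = 0.8
        rng = np.random.default_rng(7)
        n = 20000
        z = rng.standard_normal(n)
        a = z + 0.5 * rng.standard_normal(n)
        b = z + 0.5 * rng.standard_normal(n)
        true_r = 1 / (1 + 0.25)
        C = correlation_matrix(np.vstack([a, b]))
        assert C[0, 1] == pytest.approx(true_r, abs=0.02)
        del rho

    def test_lagged_crosscorrelation_shift(self):
        rng = np.random.default_rng(8)
        base = np.convolve(rng.standard_normal(1020), np.ones(3) / 3,
                           "same")
        a = base[7:1007]
        b = base[:1000]                      # b(t) = a(t - 7)
        lag, corr = lagged_crosscorrelation(np.vstack([a, b]), 15)
        assert lag[0, 1] == 7
        assert corr[0, 1] > 0.9
        assert lag[0, 0] == 0 and corr[0, 0] == pytest.approx(1.0)

    def test_period_average_recovers_cycle(self):
        t = np.arange(600)
        x = np.sin(2 * np.pi * t / 60)
        folded = period_average(x[None, :], 60)
        np.testing.assert_allclose(folded[0], np.sin(2 * np.pi *
                                                     np.arange(60) / 60),
                                   atol=1e-12)

    def test_period_average_noise_shrinks_by_sqrt_m(self):
        rng = np.random.default_rng(9)
        m, period = 64, 50
        x = rng.standard_normal((1, m * period))
        folded = period_average(x, period)
        assert folded.std() == pytest.approx(1 / np.sqrt(m), rel=0.2)

    def test_incommensurate_period_averages_out(self):
        t = np.arange(6000)
        x = np.sin(2 * np.pi * t / 73)
        folded = period_average(x[None, :], 60)
        assert np.abs(folded).max() < 0.2

    def test_fourier_power_concentrates_at_bin(self):
        t = np.arange(1200)
        f = 10 / 1200                         # exact DFT bin
        x = 2.0 * np.sin(2 * np.pi * f * t)
        p_target = fourier_power(x[None, :], f)[0]
        p_next = fourier_power(x[None, :], f + 3 / 1200)[0]
        assert p_target / max(p_next, 1e-12) > 100

    def test_parseval_normalization(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(257)
        T = x.size
        F = np.fft.rfft(x)
        power = np.abs(F) ** 2 / T
        power[1:] *= 2                        # odd length: no Nyquist bin
        assert power.sum() == pytest.approx(np.sum(x ** 2))

    def test_constant_series_zero_power(self):
        x = np.full((1, 100), 3.0)
        assert fourier_power(x, 0.1)[0] == pytest.approx(0.0, abs=1e-18)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fourier_power(np.zeros((1, 50)), 0.7)
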