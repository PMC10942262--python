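"""Free-run mechanics, stimulus generation and virtual optogenetics."""

import numpy as np
import pytest

from wormflow.connectome import PresynapticSet
from wormflow.gkdr import GkdrProjection
from wormflow.gmm_predictor import (BrainModel, GmmJointModel, ModelHyper,
                                    NeuronModel)
from wormflow.simulator import (OptoExperiment, SimulationTrace,
                                StimulusProtocol, free_run,
                                make_salt_stimulus, opto_waveform,
                                quantify_opto_response,
                                virtual_optogenetics)


def _model(target, explanatory, rho=0.5, kprime=3, mean_y=0.0):
    """Linear-Gaussian neuron model: E(y|U) = rho * newest lag of the
    first explanatory neuron (plus mean_y)."""
    d = len(explanatory) * kprime
    B = np.zeros((d, 1))
    B[kprime - 1, 0] = 1.0
    gmm = GmmJointModel([1.0], np.array([[0.0, mean_y]]),
                        np.array([[[1.0, rho], [rho, 1.0]]]))
    pset = PresynapticSet(target, list(explanatory), "direct") \
        if target in explanatory else None
    if pset is None:
        raise ValueError
    proj = GkdrProjection(B, np.ones(d), 1.0, 1.0, 1e-4)
    return NeuronModel(target, pset, proj, gmm, kprime, tauprime=1,
                       stride=1, offset=0, dt=1, residual_sd=0.3)


def _brain(models):
    return BrainModel("s", {m.target: m for m in models}, ModelHyper(),
                      sorted({m.target for m in models}))


class TestStimulus:
    def test_period_and_mean(self):
        p = StimulusProtocol(half_period=30.0)
        s = make_salt_stimulus(p, 240, step_seconds=1.0)
        np.testing.assert_array_equal(s[:60], s[60:120])
        assert set(s) == {25.0, 50.0}
        assert s[:60].mean() == pytest.approx((50 + 25) / 2)

    def test_infinite_half_period_constant(self):
        p = StimulusProtocol(half_period=np.inf)
        assert len(set(make_salt_stimulus(p, 500, 1.0))) == 1

    def test_none_protocol(self):
        assert not make_salt_stimulus(
            StimulusProtocol(kind="none"), 10).any()


class TestFreeRun:
    def test_zero_mean_conditional_fixed_point(self):
        # every conditional is N(0, v): deterministic mode settles at 0
        mA = _model("A", ["A"])
        mB = _model("B", ["B", "A"])
        brain = _brain([mA, mB])
        init = {"A": np.ones(4), "B": -np.ones(4)}
        tr = free_run(brain, init, 10, "deterministic")
        # after one step the self-history dependence decays by rho each step
        assert np.abs(tr.simulated()[:, -1]).max() < 0.5 ** 6

    def test_seed_contract(self):
        brain = _brain([_model("A", ["A"])])
        init = {"A": np.zeros(4)}
        t1 = free_run(brain, init, 20, "probabilistic", seed=3)
        t2 = free_run(brain, init, 20, "probabilistic", seed=3)
        t3 = free_run(brain, init, 20, "probabilistic", seed=4)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert not np.array_equal(t1.values, t3.values)

    def test_initial_window_preserved(self):
        brain = _brain([_model("A", ["A"])])
        init = {"A": np.array([0.3, -0.2, 0.9, 0.1])}
        tr = free_run(brain, init, 5, "deterministic")
        np.testing.assert_array_equal(tr.values[0, :4], init["A"])

    def test_synchronous_update(self):
        """B's first simulated value depends on A's history, not on A's
        simultaneously computed next value."""
        mA = _model("A", ["A"], mean_y=5.0)   # A jumps to 5 at first step
        # B reads the newest lag of A with slope 0.9
        kprime = 3
        d = 2 * kprime
        Bmat = np.zeros((d, 1))
        Bmat[d - 1, 0] = 1.0                  # newest lag of A (2nd block)
        gmm = GmmJointModel([1.0], np.zeros((1, 2)),
                            np.array([[[1.0, 0.9], [0.9, 1.0]]]))
        mB = NeuronModel("B", PresynapticSet("B", ["B", "A"], "direct"),
                         GkdrProjection(Bmat, np.ones(d), 1.0, 1.0, 1e-4),
                         gmm, kprime, 1, 1, 0, 1, residual_sd=0.1)
        brain = _brain([mA, mB])
        init = {"A": np.zeros(4), "B": np.zeros(4)}
        tr = free_run(brain, init, 2, "deterministic")
        names = tr.neuron_names
        a, b = tr.simulated()[names.index("A")], tr.simulated()[names.index("B")]
        assert a[0] == pytest.approx(5.0)
        assert b[0] == pytest.approx(0.0)     # same-step A value unseen
        assert b[1] == pytest.approx(0.9 * 5.0)  # previous-step A value used

    def test_clamp_never_overwritten(self):
        brain = _brain([_model("A", ["A"]), _model("B", ["B", "A"])])
        init = {"A": np.zeros(4), "B": np.zeros(4)}
        wave = np.linspace(1, 2, 15)
        tr = free_run(brain, init, 15, "probabilistic", seed=0,
                      clamp={"A": wave})
        np.testing.assert_array_equal(
            tr.simulated()[tr.neuron_names.index("A")], wave)

    def test_missing_init_neuron_reported(self):
        brain = _brain([_model("B", ["B", "A"])])
        with pytest.raises(ValueError, match="A"):
            free_run(brain, {"B": np.zeros(4)}, 3, "deterministic")

    def test_short_history_rejected(self):
        brain = _brain([_model("A", ["A"], kprime=5)])
        with pytest.raises(ValueError, match="history too short"):
            free_run(brain, {"A": np.zeros(3)}, 3, "deterministic")

    def test_det_noise_sustains_fluctuations(self):
        brain = _brain([_model("A", ["A"])])
        init = {"A": np.zeros(4)}
        tr = free_run(brain, init, 300, "det_noise", seed=2)
        assert tr.simulated()[0, 100:].var() > 0.01


class TestOptoWaveform:
    def test_zero_at_onset_and_peak_two(self):
        t = np.linspace(0, 400, 200001)
        y = opto_waveform(t, 3.0, 20.0)
        assert y[0] == 0.0
        assert y.max() == pytest.approx(2.0, abs=1e-6)

    def test_argmax_closed_form(self):
        tau1, tau2 = 3.0, 20.0
        t_star = np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)
        assert t_star == pytest.approx(6.6957, abs=1e-4)
        t = np.linspace(0, 60, 600001)
        y = opto_waveform(t, tau1, tau2)
        assert t[np.argmax(y)] == pytest.approx(t_star, abs=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            opto_waveform(np.array([1.0]), 20.0, 3.0)


class TestVirtualOptogenetics:
    @pytest.fixture()
    def opto_setup(self):
        # S drives R positively (R reads S's newest lag with slope 0.8)
        mS = _model("S", ["S"])
        d = 2 * 3
        B = np.zeros((d, 1))
        B[d - 1, 0] = 1.0                     # newest lag of S (2nd neuron)
        gmm = GmmJointModel([1.0], np.zeros((1, 2)),
                            np.array([[[1.0, 0.8], [0.8, 1.0]]]))
        pset = PresynapticSet("R", ["R", "S"], "direct")
        proj = GkdrProjection(B, np.ones(d), 1.0, 1.0, 1e-4)
        mR = NeuronModel("R", pset, proj, gmm, 3, 1, 1, 0, 1,
                         residual_sd=0.1)
        brain = _brain([mS, mR])
        init = {"S": np.zeros(12), "R": np.zeros(12)}
        return brain, init

    def test_clamped_trace_equals_waveform(self, opto_setup):
        brain, init = opto_setup
        exp = virtual_optogenetics(brain, init, "S", [6, 10], repeats=2,
                                   seed=0, steps=20)
        wave = opto_waveform(np.arange(20.0))
        i = exp.neuron_names.index("S")
        for tr in exp.stimulated:
            np.testing.assert_allclose(tr.simulated()[i], wave)
        for tr in exp.control:
            np.testing.assert_array_equal(tr.simulated()[i], 0.0)

    def test_downstream_positive_response(self, opto_setup):
        brain, init = opto_setup
        exp = virtual_optogenetics(brain, init, "S", [6], repeats=6,
                                   seed=1, steps=40)
        resp = quantify_opto_response(exp, window=30)
        assert resp["R"] > 0.3
        assert resp["S"] > 0          # the waveform itself is positive

    def test_identical_traces_give_zero_response(self, opto_setup):
        brain, init = opto_setup
        exp = virtual_optogenetics(brain, init, "S", [6], repeats=2,
                                   seed=2, steps=30)
        exp.control = exp.stimulated
        resp = quantify_opto_response(exp, window=20)
        assert all(v == 0 for v in resp.values())

    def test_window_mean_arithmetic(self):
        tr_s = SimulationTrace(np.array([[0.0, 1.0, 3.0]]), ["A"],
                               "probabilistic", 0, n_init=1)
        tr_c = SimulationTrace(np.array([[0.0, 0.0, 1.0]]), ["A"],
                               "probabilistic", 0, n_init=1)
        exp = OptoExperiment("A", [1], 1, 3.0, 20.0, 2.0, 2, ["A"],
                             [tr_s], [tr_c])
        resp = quantify_opto_response(exp, window=2)
        assert resp["A"] == pytest.approx((1 + 3) / 2 - (0 + 1) / 2)

    def test_onset_outside_coverage_rejected(self, opto_setup):
        brain, init = opto_setup
        with pytest.raises(ValueError):
            virtual_optogenetics(brain, init, "S", [200], repeats=1, seed=0)
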