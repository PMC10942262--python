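"""Free-run simulation and virtual optogenetics.

A fitted :class:`~wormflow.gmm_predictor.BrainModel` is run forward in
closed loop: at each step every neuron's next value is generated from
the *current* state (synchronous update) by sampling its conditional
mixture (probabilistic mode), by the conditional expectation
(deterministic mode), or by the expectation plus i.i.d. Gaussian noise
(det_noise mode — the noise-ablation comparison).  The stimulus channel
is driven by the square-wave salt protocol.

Virtual optogenetics clamps one modeled neuron to a calibrated
double-exponential activation y = A(-exp(-t/tau1) + exp(-t/tau2)) with
max(y) = 2, or to zero in paired control runs, and quantifies each
neuron's mean response over a post-onset window, stimulated minus
control.

The simulation advances on the thinned time grid (one step = ``stride``
raw time points), so embedding lags must land on that grid: tau' must
be divisible by the stride (true for the defaults tau'=10, stride=5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .connectome import STIM
from .gmm_predictor import (BrainModel, conditional, conditional_expectation,
                            sample_conditional)

__all__ = [
    "StimulusProtocol", "SimulationTrace", "OptoExperiment",
    "make_salt_stimulus", "free_run", "opto_waveform", "opto_amplitude",
    "virtual_optogenetics", "quantify_opto_response",
]


@dataclass
class StimulusProtocol:
    """Square-wave salt stimulus (concentrations in mM)."""

    kind: str = "square"          # "square" | "none"
    high: float = 50.0
    low: float = 25.0
    half_period: float = 30.0     # seconds
    step_seconds: float = 0.25    # sampling interval of the series

    @property
    def period(self) -> float:
        return 2.0 * self.half_period


def make_salt_stimulus(protocol: StimulusProtocol, n_steps: int,
                       step_seconds: float | None = None) -> np.ndarray:
    """Sampled stimulus series; starts high, switches every half period.

    The series is z-scale-free (raw concentrations); callers who feed it
    to models should standardise consistently with training.
    """
    if protocol.kind == "none":
        return np.zeros(n_steps)
    dt = step_seconds if step_seconds is not None else protocol.step_seconds
    t = np.arange(n_steps) * dt
    phase = np.floor(t / protocol.half_period).astype(int) % 2
    return np.where(phase == 0, protocol.high, protocol.low).astype(float)


@dataclass
class SimulationTrace:
    """Free-run output on the thinned time grid."""

    values: np.ndarray            # neurons x (init + steps)
    neuron_names: list[str]
    mode: str
    seed: int
    n_init: int                   # number of initial (provided) steps
    stimulus: np.ndarray | None = None

    def simulated(self) -> np.ndarray:
        """Only the simulated part (initial window removed)."""
        return self.values[:, self.n_init:]


def _lag_steps(model) -> int:
    if model.tauprime % model.stride != 0:
        raise ValueError("tau' must be divisible by the stride for free-run")
    return model.tauprime // model.stride


def _embedded_row(state: dict[str, np.ndarray], model, t: int) -> np.ndarray:
    """Embedded input row for one target at thinned time t (newest)."""
    step = _lag_steps(model)
    k = model.kprime
    row = np.empty(len(model.pset.explanatory) * k)
    for p, neuron in enumerate(model.pset.explanatory):
        series = state[neuron]
        idx = t - (k - 1 - np.arange(k)) * step
        row[p * k: (p + 1) * k] = series[idx]
    return row


def free_run(brain: BrainModel, init: dict[str, np.ndarray], steps: int,
             mode: str = "probabilistic", noise_sd=None,
             stimulus: np.ndarray | None = None, seed: int = 0,
             clamp: dict[str, np.ndarray] | None = None) -> SimulationTrace:
    """Closed-loop simulation of the whole fitted network.

    init : per-neuron history on the thinned grid, all of equal length
        >= (k'-1) * tau'/stride + 1.  Must cover every modeled neuron
        and every explanatory neuron.
    stimulus : STIM channel values on the thinned grid covering
        init + steps (required if any model uses STIM).
    noise_sd : for ``det_noise``; scalar, or None to use each model's
        training residual sd.
    clamp : optional per-neuron override series (length ``steps``); a
        clamped neuron's value is written verbatim each step and its
        model prediction skipped.
    """
    if mode not in ("probabilistic", "deterministic", "det_noise"):
        raise ValueError(f"unknown mode {mode!r}")
    models = brain.neuron_models
    needed = set(models)
    for m in models.values():
        needed |= set(m.pset.explanatory) - {STIM}
    missing = sorted(needed - set(init))
    if missing:
        raise ValueError(f"initial history missing neurons: {missing}")
    n_init = len(next(iter(init.values())))
    hist_need = max((m.kprime - 1) * _lag_steps(m) + 1
                    for m in models.values())
    if n_init < hist_need:
        raise ValueError(f"initial history too short: need {hist_need} "
                         f"thinned steps, got {n_init}")
    uses_stim = any(STIM in m.pset.explanatory for m in models.values())
    if uses_stim:
        if stimulus is None:
            raise ValueError("stimulus series required (models use STIM)")
        if len(stimulus) < n_init + steps:
            raise ValueError("stimulus must cover init + steps")
    rng = np.random.default_rng(seed)
    clamp = clamp or {}
    total = n_init + steps
    state = {name: np.concatenate([np.asarray(h, float),
                                   np.zeros(steps)])
             for name, h in init.items()}
    if uses_stim:
        state[STIM] = np.asarray(stimulus, float)[:total].copy()
    order = sorted(models)
    for s in range(steps):
        t = n_init + s
        nxt: dict[str, float] = {}
        for name in order:
            if name in clamp:
                nxt[name] = float(clamp[name][s])
                continue
            model = models[name]
            # predictions at t use state up to t-1 (dt thinned steps back)
            x = _embedded_row(state, model, t - model.dt)
            U = x @ model.projection.B
            if mode == "probabilistic":
                cond = conditional(model.gmm, U)
                nxt[name] = sample_conditional(cond, rng)
            else:
                val = conditional_expectation(model.gmm, U)
                if mode == "det_noise":
                    sd = (model.residual_sd if noise_sd is None
                          else float(noise_sd))
                    val += sd * rng.standard_normal()
                nxt[name] = val
        # unmodeled-but-needed neurons hold their last value
        for name in state:
            if name != STIM and name not in nxt:
                nxt[name] = state[name][t - 1]
        for name, v in nxt.items():
            state[name][t] = v
    names = [n for n in order]
    extra = sorted(set(state) - set(order) - {STIM})
    names += extra
    values = np.vstack([state[n] for n in names])
    return SimulationTrace(values, names, mode, seed, n_init,
                           stimulus=(np.asarray(stimulus, float)[:total]
                                     if uses_stim else None))


def opto_amplitude(tau1: float = 3.0, tau2: float = 20.0,
                   peak: float = 2.0) -> float:
    """Amplitude A such that max_t A(-e^(-t/tau1)+e^(-t/tau2)) = peak."""
    return _opto_amplitude_cached(float(tau1), float(tau2), float(peak))


@lru_cache(maxsize=64)
def _opto_amplitude_cached(tau1: float, tau2: float, peak: float) -> float:
    if not 0 < tau1 < tau2:
        raise ValueError("need tau2 > tau1 > 0")
    res = minimize_scalar(
        lambda t: -(-np.exp(-t / tau1) + np.exp(-t / tau2)),
        bounds=(0.0, 20.0 * tau2), method="bounded",
        options={"xatol": 1e-12})
    return peak / (-res.fun)


def opto_waveform(t_since_onset, tau1: float = 3.0, tau2: float = 20.0,
                  peak: float = 2.0) -> np.ndarray:
    """Double-exponential activation mimicking an optogenetic response.

    y(t) = A(-exp(-t/tau1) + exp(-t/tau2)); A calibrated so the maximum
    over t >= 0 equals ``peak``; y(0) = 0.
    """
    if not 0 < tau1 < tau2:
        raise ValueError("need tau2 > tau1 > 0 (waveform nonpositive otherwise)")
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_onset must be nonnegative")
    A = opto_amplitude(tau1, tau2, peak)
    return A * (-np.exp(-t / tau1) + np.exp(-t / tau2))


@dataclass
class OptoExperiment:
    """Paired stimulated/control free-runs for one driven neuron."""

    neuron: str
    stim_starts: list[int]            # onsets, thinned steps into init
    repeats: int
    tau1: float
    tau2: float
    peak: float
    steps: int
    neuron_names: list[str]
    stimulated: list[SimulationTrace] = field(default_factory=list)
    control: list[SimulationTrace] = field(default_factory=list)


def virtual_optogenetics(brain: BrainModel, real_init: dict[str, np.ndarray],
                         neuron: str, stim_starts, repeats: int = 10,
                         seed: int = 0, *, steps: int = 100,
                         tau1: float = 3.0, tau2: float = 20.0,
                         peak: float = 2.0,
                         stimulus: np.ndarray | None = None
                         ) -> OptoExperiment:
    """Clamp ``neuron`` to the activation waveform; run paired controls.

    For each onset (an index into the real history) and each repeat, the
    simulation starts from the real activity up to the onset; the driven
    neuron follows the waveform (stimulated) or zero (control) while all
    other neurons evolve by probabilistic free-run.  Stimulated and
    control runs of a pair share the same seed.
    """
    if neuron not in brain.neuron_models:
        raise ValueError(f"{neuron} is not a modeled neuron")
    n_init_full = len(next(iter(real_init.values())))
    hist_need = max((m.kprime - 1) * _lag_steps(m) + 1
                    for m in brain.neuron_models.values())
    stim_starts = list(stim_starts)
    for s0 in stim_starts:
        if not hist_need <= s0 <= n_init_full:
            raise ValueError(
                f"stimulation start {s0} outside usable init coverage "
                f"[{hist_need}, {n_init_full}]")
    wave = opto_waveform(np.arange(steps, dtype=float), tau1, tau2, peak)
    exp = OptoExperiment(neuron, stim_starts, repeats, tau1, tau2, peak,
                         steps, [])
    pair_seed = seed
    for s0 in stim_starts:
        init = {name: h[:s0] for name, h in real_init.items()}
        for _ in range(repeats):
            tr_stim = free_run(brain, init, steps, "probabilistic",
                               stimulus=stimulus, seed=pair_seed,
                               clamp={neuron: wave})
            tr_ctrl = free_run(brain, init, steps, "probabilistic",
                               stimulus=stimulus, seed=pair_seed,
                               clamp={neuron: np.zeros(steps)})
            exp.stimulated.append(tr_stim)
            exp.control.append(tr_ctrl)
            pair_seed += 1
    exp.neuron_names = exp.stimulated[0].neuron_names
    return exp


def quantify_opto_response(exp: OptoExperiment,
                           window: int = 80) -> dict[str, float]:
    """Mean post-onset activity, stimulated minus control, per neuron.

    Averages each neuron over the first ``window`` simulated steps after
    onset, then over repeats and onsets, separately for stimulated and
    control runs; returns the difference.
    """
    if exp.steps < window:
        raise ValueError("simulated steps shorter than the response window")

    def avg(traces):
        acc = np.zeros(len(exp.neuron_names))
        for tr in traces:
            acc += tr.simulated()[:, :window].mean(axis=1)
        return acc / len(traces)

    diff = avg(exp.stimulated) - avg(exp.control)
    return dict(zip(exp.neuron_names, diff))
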