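"""Simulation loops shared by the estimators.

These are deliberately plain Python loops over numpy state: the dynamics
are a short recurrence that cannot be vectorized over time, and at the
network sizes studied (30--400 excitatory units) each step is a handful
of small dense operations.  All loops route weight changes through
:func:`rmsorn.plasticity.plasticity_step` so the tested rule composition
is the one actually executed.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .network import (
    HEAVISIDE,
    OutputLayer,
    RecurrentLayer,
    step_output,
    step_recurrent,
)
from .plasticity import PlasticityConfig, plasticity_step
from .reward import (
    ModulationState,
    reward_detector,
    reward_generation,
    reward_supervised,
)
from .tasks import LabeledStream, generation_performance, performance

__all__ = ["TrainingProtocol", "PhaseResult"]


@dataclass
class TrainingProtocol:
    """Phase lengths and evaluation cadence of the two-phase protocol.

    Defaults follow the reference protocol: 20,000 training steps per
    phase, a 500-step validation after every 100 steps (200 candidate
    networks per phase, the best of which proceeds), and a 10,000-step
    test.  The supervised comparison networks snapshot every
    ``snapshot_interval`` steps instead (20 candidates by default).
    """

    phase_steps: int = 20_000
    validation_interval: int = 100
    validation_steps: int = 500
    test_steps: int = 10_000
    snapshot_interval: int = 1_000

    @property
    def n_snapshots(self) -> int:
        return self.phase_steps // self.validation_interval


@dataclass
class PhaseResult:
    """Best-on-validation network found during one training phase."""

    recurrent: RecurrentLayer
    output: OutputLayer
    best_validation: float
    history: list = field(default_factory=list)
    traces: dict | None = None


def _prediction(output: OutputLayer) -> int:
    if output.activation_mode == HEAVISIDE:
        return int(output.o[0])
    return int(np.argmax(output.o))


def _flip_output(output: OutputLayer, rng: np.random.Generator) -> None:
    """Bit-flip noise: deactivate the winner, activate another unit at
    random (for a single-unit readout, invert the bit)."""
    o = output.o
    if output.n_outputs == 1:
        o[0] = 1.0 - o[0]
        return
    w = int(np.argmax(o))
    o[w] = 0.0
    j = int(rng.integers(output.n_outputs - 1))
    o[j if j < w else j + 1] = 1.0


def evaluate_stream(recurrent: RecurrentLayer, output: OutputLayer,
                    enc: np.ndarray, inputs: np.ndarray) -> np.ndarray:
    """Frozen forward pass; returns the prediction at every step.

    Mutates the passed layers (callers hand in copies when the training
    state must survive).
    """
    preds = np.empty(len(inputs), dtype=np.int64)
    for t, s in enumerate(inputs):
        step_recurrent(recurrent, enc[s])
        step_output(output, recurrent.x)
        preds[t] = _prediction(output)
    return preds


def harvest_states(recurrent: RecurrentLayer, enc: np.ndarray,
                   inputs: np.ndarray) -> np.ndarray:
    """Frozen recurrent pass collecting the excitatory state after each
    input -- the regressor matrix for the supervised readout."""
    states = np.empty((len(inputs), recurrent.n_excitatory))
    for t, s in enumerate(inputs):
        step_recurrent(recurrent, enc[s])
        states[t] = recurrent.x
    return states


def train_phase(
    recurrent: RecurrentLayer,
    output: OutputLayer,
    enc: np.ndarray,
    stream: LabeledStream,
    config: PlasticityConfig,
    mod: ModulationState,
    wrong_reward: float,
    phase: int,
    protocol: TrainingProtocol,
    val_stream: LabeledStream | None,
    *,
    scatter_rng: np.random.Generator | None = None,
    noise_prob: float = 0.0,
    noise_rng: np.random.Generator | None = None,
    force_modulation: float | None = None,
    reward_mode: str = "match",
    collect_traces: bool = False,
    track_thresholds: int = 0,
) -> PhaseResult:
    """One reward-modulated training phase over a supervised stream.

    Every ``validation_interval`` steps the current network is cloned and
    scored on the fixed validation stream; the best-scoring clone is the
    phase's result.  ``force_modulation`` overrides the rewarding strategy
    with a constant factor (used for unmodulated calibration runs);
    ``reward_mode`` is ``"match"`` (reward any correct symbol) or
    ``"detector"`` (hit / false-alarm reward for a single-unit readout);
    ``track_thresholds`` keeps the last that many per-step copies of the
    readout thresholds.
    """
    reward_fn = reward_detector if reward_mode == "detector" else reward_supervised
    steps = min(protocol.phase_steps, len(stream))
    inputs, targets, excluded = stream.inputs, stream.targets, stream.excluded
    best: PhaseResult | None = None
    history: list[float] = []
    traces = {"reward": np.zeros(steps), "rate": np.zeros(steps)} if collect_traces else None
    t_o_trace: deque | None = deque(maxlen=track_thresholds) if track_thresholds else None

    for t in range(steps):
        x_prev = recurrent.x
        step_recurrent(recurrent, enc[inputs[t]])
        step_output(output, recurrent.x)
        if noise_prob > 0.0 and noise_rng is not None and noise_rng.random() < noise_prob:
            _flip_output(output, noise_rng)
        pred = _prediction(output)

        if force_modulation is not None:
            m_o = force_modulation
            r = np.nan
        elif excluded[t]:
            m_o = 0.0  # no learning signal on unpredictable positions
            r = 0.0
        else:
            r = reward_fn(pred, targets[t], wrong_reward)
            m_o = mod.modulation(r)

        plasticity_step(recurrent, output, config, m_o, x_prev, recurrent.x,
                        output.o, phase, scatter_rng=scatter_rng)

        if traces is not None:
            traces["reward"][t] = r
            traces["rate"][t] = recurrent.x.mean()
        if t_o_trace is not None:
            t_o_trace.append(output.T_O.copy())

        if val_stream is not None and (t + 1) % protocol.validation_interval == 0:
            preds = evaluate_stream(recurrent.copy(), output.copy(), enc,
                                    val_stream.inputs)
            perf = performance(preds, val_stream.targets, val_stream.excluded)
            history.append(perf)
            if best is None or perf > best.best_validation:
                best = PhaseResult(recurrent.copy(), output.copy(), perf)

    if best is None:  # no validation points: return the final network
        best = PhaseResult(recurrent.copy(), output.copy(), float("nan"))
    best.history = history
    best.traces = traces
    if t_o_trace is not None:
        best.traces = best.traces or {}
        best.traces["T_O"] = np.array(t_o_trace)
    return best


def generate(recurrent: RecurrentLayer, output: OutputLayer, enc: np.ndarray,
             n_steps: int) -> np.ndarray:
    """Frozen closed-loop generation: the output symbol is fed back as the
    next input.  Mutates the passed layers."""
    out_syms = np.empty(n_steps, dtype=np.int64)
    u = enc[int(np.argmax(output.o))] if output.o.any() else np.zeros_like(recurrent.x)
    for t in range(n_steps):
        step_recurrent(recurrent, u)
        step_output(output, recurrent.x)
        sym = int(np.argmax(output.o))
        out_syms[t] = sym
        u = enc[sym]
    return out_syms


def generation_phase(
    recurrent: RecurrentLayer,
    output: OutputLayer,
    enc: np.ndarray,
    target_words,
    n: int,
    config: PlasticityConfig,
    mod: ModulationState,
    phase: int,
    protocol: TrainingProtocol,
    *,
    repeat_punishment: float | None = None,
    punish_repeats: bool = True,
    scatter_rng: np.random.Generator | None = None,
    noise_prob: float = 0.0,
    noise_rng: np.random.Generator | None = None,
    collect_outputs: bool = False,
) -> PhaseResult:
    """Reward-modulated training of the closed generation loop.

    The network receives no input stream: its own output is fed back, and
    the per-step reward is the fractional suffix/prefix match against the
    target words.  Validation clones the network and scores a free-run of
    ``validation_steps`` symbols by target-word coverage.
    """
    tail: deque = deque(maxlen=n)
    best: PhaseResult | None = None
    history: list[float] = []
    outputs = np.empty(protocol.phase_steps, dtype=np.int64) if collect_outputs else None
    u = np.zeros_like(recurrent.x)

    for t in range(protocol.phase_steps):
        x_prev = recurrent.x
        step_recurrent(recurrent, u)
        step_output(output, recurrent.x)
        if noise_prob > 0.0 and noise_rng is not None and noise_rng.random() < noise_prob:
            _flip_output(output, noise_rng)
        sym = int(np.argmax(output.o))
        tail.append(sym)
        if outputs is not None:
            outputs[t] = sym
        r = reward_generation(tail, target_words, n,
                              repeat_punishment=repeat_punishment,
                              punish_repeats=punish_repeats)
        m_o = mod.modulation(r)
        plasticity_step(recurrent, output, config, m_o, x_prev, recurrent.x,
                        output.o, phase, scatter_rng=scatter_rng)
        u = enc[sym]

        if (t + 1) % protocol.validation_interval == 0:
            sample = generate(recurrent.copy(), output.copy(), enc,
                              protocol.validation_steps)
            perf = generation_performance(sample, target_words)
            history.append(perf)
            if best is None or perf > best.best_validation:
                best = PhaseResult(recurrent.copy(), output.copy(), perf)

    if best is None:
        best = PhaseResult(recurrent.copy(), output.copy(), float("nan"))
    best.history = history
    if outputs is not None:
        best.traces = {"outputs": outputs}
    return best
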