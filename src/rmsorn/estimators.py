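"""Trainable models: the reward-modulated network, the supervised SORN
and static comparison networks, and the protocol-level helpers
(random-update control, noise-exploration variant, grid search).

The estimators follow scikit-learn conventions (``get_params`` /
``set_params``, ``fit`` returning ``self``, fitted attributes with a
trailing underscore).  ``X`` is a one-dimensional symbol sequence (task
alphabet symbols or integer indices), ``y`` the aligned target sequence;
an optional boolean ``excluded`` mask removes unpredictable positions
from both the reward and the score, exactly as the task generators
define them.  The module-level ``train_*`` functions are thin wrappers
that draw the streams from a task generator and run the protocol
end to end.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, clone

from .engine import (
    PhaseResult,
    TrainingProtocol,
    evaluate_stream,
    generate,
    generation_phase,
    harvest_states,
    train_phase,
)
from .network import SymbolEncoder, init_network
from .plasticity import PlasticityConfig
from .reward import ModulationState
from .tasks import (
    LabeledStream,
    TaskSpec,
    counting_performance,
    generation_performance,
    make_task,
    performance,
)

__all__ = [
    "RMSornClassifier",
    "RMSornGenerator",
    "SornClassifier",
    "StaticClassifier",
    "train_rmsorn",
    "train_sorn_baseline",
    "make_static_baseline",
    "train_random_baseline",
    "noise_exploration_mode",
    "calibrate_output_thresholds",
    "grid_search",
    "shuffle_weights",
]


def _seed_ints(random_state, count):
    ss = np.random.SeedSequence(0 if random_state is None else random_state)
    return [np.random.default_rng(c) for c in ss.spawn(count)]


def _as_indices(seq, alphabet):
    """Map a symbol sequence to integer indices (ints pass through)."""
    arr = np.asarray(seq)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    index = {s: i for i, s in enumerate(alphabet)}
    return np.array([index[s] for s in seq], dtype=np.int64)


class _TaskMixin:
    """Shared task/stream plumbing for the sequence estimators."""

    def _task_spec(self) -> TaskSpec:
        if isinstance(self.task, TaskSpec):
            return self.task
        return make_task(self.task, self.n)

    def _protocol(self) -> TrainingProtocol:
        return TrainingProtocol(
            phase_steps=self.phase_steps,
            validation_interval=self.validation_interval,
            validation_steps=self.validation_steps,
        )

    def _streams(self, task, X, y, excluded, final, X_val, y_val, excluded_val):
        """Assemble training and validation LabeledStreams from arrays.

        Without explicit validation data, the last ``validation_steps``
        positions of the training sequence are held out.
        """
        X_idx = _as_indices(X, task.alphabet)
        y_idx = np.asarray(y, dtype=np.int64) if task.n_outputs == 1 \
            else _as_indices(y, task.alphabet)
        if len(X_idx) != len(y_idx):
            raise ValueError("X and y differ in length")
        excl = np.zeros(len(X_idx), dtype=bool) if excluded is None \
            else np.asarray(excluded, dtype=bool)
        fin = None if final is None else np.asarray(final, dtype=bool)
        if X_val is None:
            cut = len(X_idx) - self.validation_steps
            if cut <= 0:
                raise ValueError("sequence too short to hold out validation data")
            val = LabeledStream(X_idx[cut:], y_idx[cut:], excl[cut:], task.alphabet)
            train = LabeledStream(X_idx[:cut], y_idx[:cut], excl[:cut],
                                  task.alphabet, None if fin is None else fin[:cut])
        else:
            Xv = _as_indices(X_val, task.alphabet)
            yv = np.asarray(y_val, dtype=np.int64) if task.n_outputs == 1 \
                else _as_indices(y_val, task.alphabet)
            ev = np.zeros(len(Xv), dtype=bool) if excluded_val is None \
                else np.asarray(excluded_val, dtype=bool)
            val = LabeledStream(Xv, yv, ev, task.alphabet)
            train = LabeledStream(X_idx, y_idx, excl, task.alphabet, fin)
        return train, val

    def _init_net(self, task, rng_net, rng_enc):
        rec, out = init_network(self.n_excitatory, task.n_outputs,
                                self.sparsity, rng=rng_net, t_max=self.t_max)
        enc = SymbolEncoder(task.alphabet, self.n_excitatory,
                            self.units_per_symbol, rng=rng_enc)
        return rec, out, enc


class RMSornClassifier(_TaskMixin, BaseEstimator):
    """Reward-modulated self-organizing network for supervised symbol tasks.

    The recurrent reservoir self-organizes through STDP, synaptic
    normalization and intrinsic plasticity; the plastic readout learns
    through STDP gated by a scalar reward-derived modulation factor.
    Intrinsic plasticity -- not noise -- drives the exploration of output
    mappings.  Training runs in two phases of ``phase_steps`` steps: all
    plasticity on, then the recurrent layer frozen while the readout is
    fine-tuned; within each phase the network is validated every
    ``validation_interval`` steps and the best candidate proceeds.

    Parameters
    ----------
    task : str or TaskSpec
        Task the alphabet / readout geometry is taken from.
    n : int, optional
        Task difficulty (word size, delay, window ...), when ``task`` is a name.
    strategy, k : reward-modulation strategy ("m0" raw reward, "mk"
        reward-prediction error with window ``k``).
    wrong_reward : {0, -1}
        Reward for an incorrect output symbol; -1 turns errors into
        Anti-STDP punishment.
    modulate_recurrent : bool
        Share the readout modulation with the recurrent STDP (``m_r = m_o``)
        instead of running it unmodulated.
    noise_prob, t_o_init, ip_output : noise-exploration variant -- bit-flip
        noise on the winner with frozen, pre-calibrated readout thresholds
        instead of readout intrinsic plasticity.
    random_updates : bool
        Scatter the values of every reward-modulated STDP update over
        random eligible synapses (the 'lucky guessing' control network).
    """

    def __init__(self, task="counting", n=None, n_excitatory=100,
                 sparsity=0.10, units_per_symbol=None, t_max=1.0,
                 eta_stdp=0.004, eta_ip=0.01, mu_ip=0.1,
                 strategy="mk", k=10, wrong_reward=0.0, reward_mode="auto",
                 modulate_recurrent=False, sn_output=True, ip_output=True,
                 noise_prob=0.0, t_o_init=None, random_updates=False,
                 phase_steps=20_000, validation_interval=100,
                 validation_steps=500, random_state=None):
        self.task = task
        self.n = n
        self.n_excitatory = n_excitatory
        self.sparsity = sparsity
        self.units_per_symbol = units_per_symbol
        self.t_max = t_max
        self.eta_stdp = eta_stdp
        self.eta_ip = eta_ip
        self.mu_ip = mu_ip
        self.strategy = strategy
        self.k = k
        self.wrong_reward = wrong_reward
        self.reward_mode = reward_mode
        self.modulate_recurrent = modulate_recurrent
        self.sn_output = sn_output
        self.ip_output = ip_output
        self.noise_prob = noise_prob
        self.t_o_init = t_o_init
        self.random_updates = random_updates
        self.phase_steps = phase_steps
        self.validation_interval = validation_interval
        self.validation_steps = validation_steps
        self.random_state = random_state

    def _config(self, task):
        return PlasticityConfig(
            eta_ip=self.eta_ip, eta_stdp=self.eta_stdp,
            mu_ip_recurrent=self.mu_ip, mu_ip_output=task.mu_ip_output,
            modulate_recurrent=self.modulate_recurrent,
            sn_output=self.sn_output, ip_output=self.ip_output,
        )

    def fit(self, X, y, excluded=None, final=None,
            X_val=None, y_val=None, excluded_val=None):
        if not 0.0 <= self.noise_prob <= 1.0:
            raise ValueError("noise_prob must lie in [0, 1]")
        task = self._task_spec()
        protocol = self._protocol()
        rng_net, rng_enc, rng_train, rng_scatter = _seed_ints(self.random_state, 4)
        rec, out, enc = self._init_net(task, rng_net, rng_enc)
        if self.t_o_init is not None:
            out.T_O = np.array(self.t_o_init, dtype=float)
        train, val = self._streams(task, X, y, excluded, final,
                                   X_val, y_val, excluded_val)
        config = self._config(task)
        scatter = rng_scatter if self.random_updates else None
        noise_rng = rng_train if self.noise_prob > 0 else None
        if self.reward_mode == "auto":
            reward_mode = "detector" if task.n_outputs == 1 else "match"
        else:
            reward_mode = self.reward_mode

        phase1 = train_phase(rec, out, enc.matrix, train, config,
                             ModulationState(self.strategy, self.k),
                             self.wrong_reward, 1, protocol, val,
                             scatter_rng=scatter, noise_prob=self.noise_prob,
                             noise_rng=noise_rng, reward_mode=reward_mode)
        phase2 = train_phase(phase1.recurrent.copy(), phase1.output.copy(),
                             enc.matrix, train, config,
                             ModulationState(self.strategy, self.k),
                             self.wrong_reward, 2, protocol, val,
                             scatter_rng=scatter, noise_prob=self.noise_prob,
                             noise_rng=noise_rng, reward_mode=reward_mode)
        # phase 2 fine-tunes the readout; fall back to the phase-1 winner
        # if fine-tuning never improved on it
        best = phase2 if phase2.best_validation >= phase1.best_validation else phase1
        self.task_ = task
        self.encoder_ = enc
        self.recurrent_ = best.recurrent
        self.output_ = best.output
        self.best_validation_ = best.best_validation
        self.validation_history_ = {"phase1": phase1.history,
                                    "phase2": phase2.history}
        self.classes_ = np.array(task.alphabet) if task.n_outputs > 1 \
            else np.array([0, 1])
        return self

    def _predict_indices(self, X):
        if not hasattr(self, "recurrent_"):
            raise AttributeError("estimator is not fitted")
        idx = _as_indices(X, self.task_.alphabet)
        rec, out = self.recurrent_.copy(), self.output_.copy()
        rec.x[:] = 0.0
        rec.y[:] = 0.0
        return evaluate_stream(rec, out, self.encoder_.matrix, idx)

    def predict(self, X):
        """Predicted output symbols (labels 0/1 for a single-unit readout).

        Evaluation is frozen and deterministic, starting from a silent
        reservoir state.
        """
        preds = self._predict_indices(X)
        if self.task_.n_outputs == 1:
            return preds
        return np.array(self.task_.alphabet)[preds]

    def score(self, X, y, excluded=None):
        """Match fraction over non-excluded positions."""
        task = self.task_
        y_idx = np.asarray(y, dtype=np.int64) if task.n_outputs == 1 \
            else _as_indices(y, task.alphabet)
        return performance(self._predict_indices(X), y_idx, excluded)


class RMSornGenerator(_TaskMixin, BaseEstimator):
    """Reward-modulated network trained to free-run a motion word.

    There is no input: the winner-takes-all output is fed back into the
    reservoir, and each step is rewarded by the fraction of a target word
    (``1 2 .. n`` or ``n .. 2 1``) completed at that step.  ``fit``
    ignores ``X``/``y`` and exists for interface compatibility.
    """

    def __init__(self, n=8, n_excitatory=100, sparsity=0.10,
                 units_per_symbol=None, t_max=1.0,
                 eta_stdp=0.004, eta_ip=0.01, mu_ip=0.1,
                 strategy="mk", k=5, generation_punishment=None,
                 punish_repeats=True, modulate_recurrent=False,
                 sn_output=True, ip_output=True, noise_prob=0.0,
                 t_o_init=None, phase_steps=20_000, validation_interval=100,
                 validation_steps=500, random_state=None):
        self.n = n
        self.n_excitatory = n_excitatory
        self.sparsity = sparsity
        self.units_per_symbol = units_per_symbol
        self.t_max = t_max
        self.eta_stdp = eta_stdp
        self.eta_ip = eta_ip
        self.mu_ip = mu_ip
        self.strategy = strategy
        self.k = k
        self.generation_punishment = generation_punishment
        self.punish_repeats = punish_repeats
        self.modulate_recurrent = modulate_recurrent
        self.sn_output = sn_output
        self.ip_output = ip_output
        self.noise_prob = noise_prob
        self.t_o_init = t_o_init
        self.phase_steps = phase_steps
        self.validation_interval = validation_interval
        self.validation_steps = validation_steps
        self.random_state = random_state

    @property
    def task(self):  # noqa: D401 - _TaskMixin hook
        return make_task("motion_generation", self.n)

    def fit(self, X=None, y=None):
        if not 0.0 <= self.noise_prob <= 1.0:
            raise ValueError("noise_prob must lie in [0, 1]")
        task = self._task_spec()
        protocol = self._protocol()
        rng_net, rng_enc, rng_train = _seed_ints(self.random_state, 3)
        rec, out, enc = self._init_net(task, rng_net, rng_enc)
        if self.t_o_init is not None:
            out.T_O = np.array(self.t_o_init, dtype=float)
        config = PlasticityConfig(
            eta_ip=self.eta_ip, eta_stdp=self.eta_stdp,
            mu_ip_recurrent=self.mu_ip, mu_ip_output=task.mu_ip_output,
            modulate_recurrent=self.modulate_recurrent,
            sn_output=self.sn_output, ip_output=self.ip_output,
        )
        noise_rng = rng_train if self.noise_prob > 0 else None
        kw = dict(repeat_punishment=self.generation_punishment,
                  punish_repeats=self.punish_repeats,
                  noise_prob=self.noise_prob, noise_rng=noise_rng,
                  collect_outputs=True)
        phase1 = generation_phase(rec, out, enc.matrix, task.target_words,
                                  task.n, config,
                                  ModulationState(self.strategy, self.k),
                                  1, protocol, **kw)
        phase2 = generation_phase(phase1.recurrent.copy(), phase1.output.copy(),
                                  enc.matrix, task.target_words, task.n, config,
                                  ModulationState(self.strategy, self.k),
                                  2, protocol, **kw)
        best = phase2 if phase2.best_validation >= phase1.best_validation else phase1
        self.task_ = task
        self.encoder_ = enc
        self.recurrent_ = best.recurrent
        self.output_ = best.output
        self.best_validation_ = best.best_validation
        self.validation_history_ = {"phase1": phase1.history,
                                    "phase2": phase2.history}
        self.training_outputs_ = {"phase1": phase1.traces["outputs"],
                                  "phase2": phase2.traces["outputs"]}
        return self

    def sample(self, n_steps: int) -> np.ndarray:
        """Free-run the fitted network for ``n_steps`` symbols
        (deterministic, starting from the selected snapshot's state)."""
        if not hasattr(self, "recurrent_"):
            raise AttributeError("estimator is not fitted")
        return generate(self.recurrent_.copy(), self.output_.copy(),
                        self.encoder_.matrix, n_steps)

    def score(self, n_steps: int = 10_000) -> float:
        """Target-word coverage of a fresh ``n_steps``-symbol free run."""
        return generation_performance(self.sample(n_steps),
                                      self.task_.target_words)


def _fit_readout_nnls(states, y_idx, n_outputs, excluded=None):
    """Non-negative least squares readout fit, one output unit at a time.

    Non-negativity mirrors the positivity constraint on the plastic
    weights, keeping the supervised comparison on equal footing.
    """
    if excluded is not None:
        keep = ~np.asarray(excluded, dtype=bool)
        states, y_idx = states[keep], y_idx[keep]
    W = np.empty((n_outputs, states.shape[1]))
    for i in range(n_outputs):
        b = (y_idx == i).astype(float) if n_outputs > 1 else y_idx.astype(float)
        W[i], _ = nnls(states, b)
    return W


def _readout_predict(W, states, n_outputs):
    drive = states @ W.T
    if n_outputs == 1:
        return (drive[:, 0] >= 0.5).astype(np.int64)
    return np.argmax(drive, axis=1).astype(np.int64)


class SornClassifier(_TaskMixin, BaseEstimator):
    """Supervised comparison network: plastic reservoir, regression readout.

    The reservoir runs unmodulated STDP + SN + IP over the training
    stream; every ``snapshot_interval`` steps the weights are frozen into
    a candidate.  Each candidate re-processes the training stream with
    frozen weights, its readout is fit by non-negative least squares
    against one-hot targets, and the candidate with the best validation
    performance is kept.
    """

    def __init__(self, task="counting", n=None, n_excitatory=100,
                 sparsity=0.10, units_per_symbol=None, t_max=1.0,
                 eta_stdp=0.004, eta_ip=0.01, mu_ip=0.1,
                 phase_steps=20_000, snapshot_interval=1_000,
                 validation_steps=500, harvest_steps=None, random_state=None):
        self.task = task
        self.n = n
        self.n_excitatory = n_excitatory
        self.sparsity = sparsity
        self.units_per_symbol = units_per_symbol
        self.t_max = t_max
        self.eta_stdp = eta_stdp
        self.eta_ip = eta_ip
        self.mu_ip = mu_ip
        self.phase_steps = phase_steps
        self.snapshot_interval = snapshot_interval
        self.validation_steps = validation_steps
        self.harvest_steps = harvest_steps
        self.random_state = random_state

    # _TaskMixin hook: SORN has no RM validation cadence
    @property
    def validation_interval(self):
        return self.snapshot_interval

    def fit(self, X, y, excluded=None, final=None,
            X_val=None, y_val=None, excluded_val=None):
        task = self._task_spec()
        rng_net, rng_enc = _seed_ints(self.random_state, 2)
        rec, out, enc = self._init_net(task, rng_net, rng_enc)
        train, val = self._streams(task, X, y, excluded, final,
                                   X_val, y_val, excluded_val)
        config = PlasticityConfig(
            eta_ip=self.eta_ip, eta_stdp=self.eta_stdp,
            mu_ip_recurrent=self.mu_ip, mu_ip_output=task.mu_ip_output,
            sn_output=False, ip_output=False,
        )
        steps = min(self.phase_steps, len(train))
        snapshots = []
        mod = ModulationState("m0", 1)
        proto = TrainingProtocol(phase_steps=self.snapshot_interval,
                                 validation_interval=self.snapshot_interval + 1)
        offset = 0
        while offset < steps:
            chunk = LabeledStream(train.inputs[offset:offset + self.snapshot_interval],
                                  train.targets[offset:offset + self.snapshot_interval],
                                  train.excluded[offset:offset + self.snapshot_interval],
                                  task.alphabet)
            train_phase(rec, out, enc.matrix, chunk, config, mod, 0.0, 1,
                        proto, None, force_modulation=0.0)
            snapshots.append(rec.copy())
            offset += self.snapshot_interval

        harvest_len = self.harvest_steps or steps
        best = (None, None, -np.inf)
        for snap in snapshots:
            frozen = snap.copy()
            frozen.x[:] = 0.0
            frozen.y[:] = 0.0
            states = harvest_states(frozen, enc.matrix,
                                    train.inputs[:harvest_len])
            W = _fit_readout_nnls(states, train.targets[:harvest_len],
                                  task.n_outputs, train.excluded[:harvest_len])
            vstates = harvest_states(snap.copy(), enc.matrix, val.inputs)
            preds = _readout_predict(W, vstates, task.n_outputs)
            perf = performance(preds, val.targets, val.excluded)
            if perf > best[2]:
                best = (snap, W, perf)

        self.task_ = task
        self.encoder_ = enc
        self.recurrent_ = best[0]
        self.readout_ = best[1]
        self.best_validation_ = best[2]
        self.n_candidates_ = len(snapshots)
        return self

    def _predict_indices(self, X):
        if not hasattr(self, "recurrent_"):
            raise AttributeError("estimator is not fitted")
        idx = _as_indices(X, self.task_.alphabet)
        rec = self.recurrent_.copy()
        rec.x[:] = 0.0
        rec.y[:] = 0.0
        states = harvest_states(rec, self.encoder_.matrix, idx)
        return _readout_predict(self.readout_, states, self.task_.n_outputs)

    def predict(self, X):
        preds = self._predict_indices(X)
        if self.task_.n_outputs == 1:
            return preds
        return np.array(self.task_.alphabet)[preds]

    def score(self, X, y, excluded=None):
        task = self.task_
        y_idx = np.asarray(y, dtype=np.int64) if task.n_outputs == 1 \
            else _as_indices(y, task.alphabet)
        return performance(self._predict_indices(X), y_idx, excluded)


def shuffle_weights(W, mask, rng=None, permutation=None):
    """Permute the weight values across the eligibility-mask positions.

    The weight multiset is preserved exactly; row sums generally change
    (no re-normalization -- the result is a non-plastic network)."""
    vals = W[mask]
    if permutation is None:
        permutation = rng.permutation(vals.size)
    out = np.zeros_like(W)
    out[mask] = vals[permutation]
    return out


class StaticClassifier(BaseEstimator):
    """Non-plastic control: the best SORN's weights, shuffled.

    Each of ``n_shuffles`` candidates permutes the recurrent weight values
    across the eligibility mask (thresholds kept), refits the NNLS readout
    and is validated; the best candidate is kept.
    """

    def __init__(self, source=None, n_shuffles=20, harvest_steps=None,
                 random_state=None):
        self.source = source
        self.n_shuffles = n_shuffles
        self.harvest_steps = harvest_steps
        self.random_state = random_state

    def fit(self, X, y, excluded=None, final=None,
            X_val=None, y_val=None, excluded_val=None):
        src = self.source
        if src is None or not hasattr(src, "recurrent_"):
            raise ValueError("source must be a fitted SornClassifier")
        task = src.task_
        rng = np.random.default_rng(self.random_state)
        train, val = src._streams(task, X, y, excluded, final,
                                  X_val, y_val, excluded_val)
        harvest_len = self.harvest_steps or len(train)
        best = (None, None, -np.inf)
        for _ in range(self.n_shuffles):
            rec = src.recurrent_.copy()
            rec.W_EE = shuffle_weights(rec.W_EE, rec.mask, rng)
            rec.x[:] = 0.0
            rec.y[:] = 0.0
            states = harvest_states(rec.copy(), src.encoder_.matrix,
                                    train.inputs[:harvest_len])
            W = _fit_readout_nnls(states, train.targets[:harvest_len],
                                  task.n_outputs, train.excluded[:harvest_len])
            vstates = harvest_states(rec.copy(), src.encoder_.matrix, val.inputs)
            preds = _readout_predict(W, vstates, task.n_outputs)
            perf = performance(preds, val.targets, val.excluded)
            if perf > best[2]:
                best = (rec, W, perf)
        self.task_ = task
        self.encoder_ = src.encoder_
        self.recurrent_ = best[0]
        self.readout_ = best[1]
        self.best_validation_ = best[2]
        return self

    _predict_indices = SornClassifier._predict_indices
    predict = SornClassifier.predict
    score = SornClassifier.score


# ---------------------------------------------------------------------------
# protocol-level wrappers

def _task_streams(task: TaskSpec, protocol: TrainingProtocol, seed):
    """Draw one data set (training / validation / test streams)."""
    s_train, s_val, s_test = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    train = task.sample(protocol.phase_steps, int(s_train))
    val = task.sample(protocol.validation_steps, int(s_val))
    test = task.sample(protocol.test_steps, int(s_test))
    return train, val, test


def _score_result(est, task, test) -> dict:
    result = {"performance": est.score(test.inputs, test.targets, test.excluded),
              "best_validation": est.best_validation_}
    if test.final is not None:
        preds = est._predict_indices(test.inputs)
        result["counting_performance"] = counting_performance(
            preds, test.targets, test.final)
    return result


def train_rmsorn(task, n=None, n_excitatory=100, protocol=None,
                 seed=0, **params):
    """Run the full two-phase reward-modulated protocol on one data set.

    Returns a dict with the fitted estimator, test ``performance`` and
    (for counting-style tasks) ``counting_performance``.  ``seed`` covers
    both the data set and the network; pass ``data_seed`` / ``net_seed``
    in ``params`` to split them as in the 10-data-sets x 10-networks
    evaluation design.
    """
    data_seed = params.pop("data_seed", None)
    net_seed = params.pop("net_seed", None)
    if data_seed is None or net_seed is None:
        d, n_ = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
        data_seed = int(d) if data_seed is None else data_seed
        net_seed = int(n_) if net_seed is None else net_seed
    protocol = protocol or TrainingProtocol()
    spec = task if isinstance(task, TaskSpec) else make_task(task, n)

    if not spec.has_input:
        est = RMSornGenerator(
            n=spec.n, n_excitatory=n_excitatory,
            phase_steps=protocol.phase_steps,
            validation_interval=protocol.validation_interval,
            validation_steps=protocol.validation_steps,
            random_state=net_seed, **params)
        est.fit()
        return {"estimator": est,
                "performance": est.score(protocol.test_steps),
                "best_validation": est.best_validation_}

    train, val, test = _task_streams(spec, protocol, data_seed)
    est = RMSornClassifier(
        task=spec, n_excitatory=n_excitatory,
        phase_steps=protocol.phase_steps,
        validation_interval=protocol.validation_interval,
        validation_steps=protocol.validation_steps,
        random_state=net_seed, **params)
    est.fit(train.inputs, train.targets, excluded=train.excluded,
            final=train.final, X_val=val.inputs, y_val=val.targets,
            excluded_val=val.excluded)
    out = _score_result(est, spec, test)
    out["estimator"] = est
    return out


def train_sorn_baseline(task, n=None, n_excitatory=100, protocol=None,
                        seed=0, **params):
    """Train the supervised SORN comparison network on one data set."""
    data_seed = params.pop("data_seed", None)
    net_seed = params.pop("net_seed", None)
    if data_seed is None or net_seed is None:
        d, n_ = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
        data_seed = int(d) if data_seed is None else data_seed
        net_seed = int(n_) if net_seed is None else net_seed
    protocol = protocol or TrainingProtocol()
    spec = task if isinstance(task, TaskSpec) else make_task(task, n)
    train, val, test = _task_streams(spec, protocol, data_seed)
    est = SornClassifier(
        task=spec, n_excitatory=n_excitatory,
        phase_steps=protocol.phase_steps,
        snapshot_interval=protocol.snapshot_interval,
        validation_steps=protocol.validation_steps,
        random_state=net_seed, **params)
    est.fit(train.inputs, train.targets, excluded=train.excluded,
            final=train.final, X_val=val.inputs, y_val=val.targets,
            excluded_val=val.excluded)
    out = _score_result(est, spec, test)
    out["estimator"] = est
    out["_streams"] = (train, val, test)
    return out


def make_static_baseline(sorn_result, n_shuffles=20, seed=0, harvest_steps=None):
    """Shuffled-weight control derived from a fitted SORN run
    (the dict returned by :func:`train_sorn_baseline`)."""
    est = sorn_result["estimator"]
    train, val, test = sorn_result["_streams"]
    static = StaticClassifier(source=est, n_shuffles=n_shuffles,
                              harvest_steps=harvest_steps, random_state=seed)
    static.fit(train.inputs, train.targets, excluded=train.excluded,
               X_val=val.inputs, y_val=val.targets, excluded_val=val.excluded)
    out = _score_result(static, est.task_, test)
    out["estimator"] = static
    return out


def train_random_baseline(task, n=None, n_excitatory=100, protocol=None,
                          seed=0, **params):
    """'Lucky guessing' control: identical to the reward-modulated run,
    but every STDP update is scattered over random eligible synapses."""
    params["random_updates"] = True
    return train_rmsorn(task, n=n, n_excitatory=n_excitatory,
                        protocol=protocol, seed=seed, **params)


def calibrate_output_thresholds(clf: RMSornClassifier, X, y, excluded=None,
                                calibration_steps=20_000, average_last=1_000):
    """Readout thresholds for the noise-exploration variant.

    Runs a preliminary pass with *unmodulated* plasticity (modulation
    pinned to 1) and returns the per-unit mean of the readout thresholds
    over the last ``average_last`` steps -- the level intrinsic
    plasticity would settle at.
    """
    task = clf._task_spec()
    rng_net, rng_enc, _, _ = _seed_ints(clf.random_state, 4)
    rec, out, enc = clf._init_net(task, rng_net, rng_enc)
    train, _ = clf._streams(task, X, y, excluded, None, None, None, None)
    protocol = TrainingProtocol(phase_steps=calibration_steps,
                                validation_interval=calibration_steps + 1)
    res = train_phase(rec, out, enc.matrix, train, clf._config(task),
                      ModulationState("m0", 1), 0.0, 1, protocol, None,
                      force_modulation=1.0, track_thresholds=average_last)
    return res.traces["T_O"].mean(axis=0)


def noise_exploration_mode(clf: RMSornClassifier, X, y, excluded=None,
                           noise_prob=0.05, **calib_kw) -> RMSornClassifier:
    """Configure the noise-for-exploration variant of a classifier.

    Disables readout intrinsic plasticity, freezes the readout thresholds
    to values calibrated from a preliminary unmodulated run of the *same*
    network, and flips the winning output with probability ``noise_prob``
    during training.  Returns an unfitted, configured clone.
    """
    if not 0.0 <= noise_prob <= 1.0:
        raise ValueError("noise_prob must lie in [0, 1]")
    t_o = calibrate_output_thresholds(clf, X, y, excluded, **calib_kw)
    noisy = clone(clf)
    noisy.set_params(ip_output=False, noise_prob=noise_prob, t_o_init=t_o)
    return noisy


def grid_search(task, grid: dict, n=None, n_excitatory=100, protocol=None,
                runs_per_cell=3, seed=0, **base_params):
    """Exhaustive reward-strategy search, as used to pick per-task settings.

    ``grid`` maps estimator parameter names (``strategy``, ``k``,
    ``wrong_reward``, ``mu_ip`` ...) to candidate values.  Each cell is
    scored by its mean best-validation performance over ``runs_per_cell``
    runs with distinct seeds; ties break toward the simpler strategy
    (``m0``), then the smaller window.
    """
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[p] for p in names)):
        cell = dict(zip(names, values))
        perfs = [
            train_rmsorn(task, n=n, n_excitatory=n_excitatory,
                         protocol=protocol, seed=seed + 7919 * r,
                         **{**base_params, **cell})["best_validation"]
            for r in range(runs_per_cell)
        ]
        rows.append({**cell, "mean_validation": float(np.mean(perfs))})
    table = pd.DataFrame(rows)

    def sort_key(row):
        return (-row["mean_validation"],
                0 if row.get("strategy", "m0") == "m0" else 1,
                row.get("k", 0))

    best = min(rows, key=sort_key)
    best_params = {p: best[p] for p in names}
    return best_params, table
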