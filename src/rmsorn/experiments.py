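"""Experiment registry: replicated runs, aggregation and analysis.

The evaluation design replicates every condition over independent data
sets and independent networks (10 x 10 by default; 100 networks for the
input-free generation task) and reports mean and standard deviation of
the test performance.  All outputs are reproducible from the
configuration and base seed alone, and row ordering is deterministic so
repeated runs produce byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .defaults import default_params
from .engine import TrainingProtocol, harvest_states
from .estimators import (
    make_static_baseline,
    train_random_baseline,
    train_rmsorn,
    train_sorn_baseline,
)
from .tasks import make_task

#: settings meaningful for the non-reward-modulated comparison models
_RESERVOIR_KEYS = ("mu_ip", "eta_ip", "eta_stdp", "units_per_symbol",
                   "sparsity", "t_max")

__all__ = ["ExperimentConfig", "run_experiment", "summarize",
           "save_results", "selectivity_analysis", "exploration_trace"]

VARIANTS = ("rmsorn", "sorn", "static", "random")


@dataclass
class ExperimentConfig:
    """One experimental condition (task x difficulty x size x variant)."""

    task: str = "counting"
    n: int | None = None
    n_excitatory: int = 100
    variant: str = "rmsorn"
    n_datasets: int = 10
    n_networks: int = 10
    seed: int = 0
    n_shuffles: int = 20
    params: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.task == "motion_generation":
            # no input data: replicate over networks only
            self.n_datasets = 1
            if self.n_networks == 10:
                self.n_networks = 100


def _run_one(cfg: ExperimentConfig, protocol, data_seed, net_seed):
    if cfg.task == "motion_generation" and cfg.variant != "rmsorn":
        raise ValueError("the input-free generation task has no supervised "
                         "comparison variant")
    params = {**default_params(cfg.task), **cfg.params}
    if cfg.variant in ("sorn", "static"):
        params = {k: v for k, v in params.items() if k in _RESERVOIR_KEYS}
    kw = dict(n=cfg.n, n_excitatory=cfg.n_excitatory, protocol=protocol,
              data_seed=data_seed, net_seed=net_seed, **params)
    if cfg.variant == "rmsorn":
        return train_rmsorn(cfg.task, **kw)
    if cfg.variant == "random":
        return train_random_baseline(cfg.task, **kw)
    sorn = train_sorn_baseline(cfg.task, **kw)
    if cfg.variant == "sorn":
        return sorn
    return make_static_baseline(sorn, n_shuffles=cfg.n_shuffles, seed=net_seed)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute all replicate runs of a condition; returns one row per run.

    Failed runs are collected and reported together rather than aborting
    the remaining replicates.
    """
    protocol = TrainingProtocol(**config.protocol)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 * config.n_datasets * config.n_networks) % (2 ** 31)
    rows, failures = [], []
    i = 0
    for d in range(config.n_datasets):
        for k in range(config.n_networks):
            data_seed, net_seed = int(seeds[i]), int(seeds[i + 1])
            i += 2
            try:
                res = _run_one(config, protocol, data_seed, net_seed)
            except Exception as exc:  # pragma: no cover - partial failure path
                failures.append((data_seed, net_seed, repr(exc)))
                continue
            row = {"task": config.task, "n": config.n,
                   "N": config.n_excitatory, "variant": config.variant,
                   "dataset": d, "network": k,
                   "data_seed": data_seed, "net_seed": net_seed,
                   "performance": res["performance"]}
            if "counting_performance" in res:
                row["counting_performance"] = res["counting_performance"]
            rows.append(row)
    if failures:
        raise RuntimeError(f"{len(failures)} runs failed: {failures}")
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> dict:
    """Mean/sd summary of an experiment table."""
    out = {"runs": int(len(table)),
           "mean": float(table["performance"].mean()),
           "sd": float(table["performance"].std(ddof=1)) if len(table) > 1 else 0.0}
    if "counting_performance" in table:
        out["counting_mean"] = float(table["counting_performance"].mean())
        out["counting_sd"] = (float(table["counting_performance"].std(ddof=1))
                              if len(table) > 1 else 0.0)
    return out


def save_results(table: pd.DataFrame, csv_path, json_path=None,
                 config: ExperimentConfig | None = None) -> None:
    """Write the per-run CSV and an optional JSON summary (byte-stable)."""
    table = table.sort_values(list(table.columns)).reset_index(drop=True)
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {"summary": summarize(table)}
        if config is not None:
            payload["config"] = asdict(config)
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def exploration_trace(outputs, target_words, window: int = 100,
                      min_len: int = 2, max_len: int | None = None) -> np.ndarray:
    """Exploration during generation training: per window of ``window``
    steps, the number of unique output subsequences (lengths ``min_len``
    to ``max_len``) that are not part of any target word.

    Exploration is highest early in training and decays as the output
    settles on the target words -- but never reaches zero.
    """
    outputs = np.asarray(outputs)
    if max_len is None:
        max_len = max(len(w) for w in target_words)
    target_subs = set()
    for w in target_words:
        w = tuple(w)
        for L in range(min_len, max_len + 1):
            for i in range(len(w) - L + 1):
                target_subs.add(w[i:i + L])
    counts = []
    for start in range(0, len(outputs) - window + 1, window):
        chunk = tuple(outputs[start:start + window])
        uniq = set()
        for L in range(min_len, max_len + 1):
            for i in range(window - L + 1):
                sub = chunk[i:i + L]
                if sub not in target_subs:
                    uniq.add(sub)
        counts.append(len(uniq))
    return np.asarray(counts)


def selectivity_analysis(estimator, probe_steps: int = 10_000,
                         seed: int = 0) -> pd.DataFrame:
    """Per-neuron spike probability conditioned on two-symbol contexts.

    Runs the fitted reservoir frozen on a fresh probe stream and, for
    every two-symbol input sequence that occurs, estimates each
    excitatory neuron's firing probability by counting spikes.  Rows are
    contexts (e.g. ``"12"``), columns neurons.
    """
    task = estimator.task_
    stream = make_task(task.name, task.n).sample(probe_steps, seed)
    rec = estimator.recurrent_.copy()
    rec.x[:] = 0.0
    rec.y[:] = 0.0
    states = harvest_states(rec, estimator.encoder_.matrix, stream.inputs)
    contexts = {}
    for t in range(1, len(stream.inputs)):
        key = task.alphabet[stream.inputs[t - 1]] + task.alphabet[stream.inputs[t]]
        counts, total = contexts.setdefault(
            key, [np.zeros(rec.n_excitatory), 0])
        counts += states[t]
        contexts[key][1] = total + 1
    rows = {key: counts / total for key, (counts, total) in contexts.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.columns = [f"neuron_{i}" for i in range(rec.n_excitatory)]
    return table
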