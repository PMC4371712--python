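"""Reward computation and reward-to-modulation strategies.

Supervised tasks deliver reward 1 for a correct output symbol and either
0 or -1 (a task-level choice) for a wrong one; positions whose target is
unpredictable by construction carry no learning signal at all.  The
sequence-generation task, which has no target stream, rewards the length
of the longest suffix of the recent output that forms a prefix of a
target word, as a fraction ``L / n`` of the word length -- the full
reward of 1 arrives at the step emitting a word's last symbol.

Two strategies convert rewards into the STDP modulation factor:

* ``M0``: ``m(t) = r(t)`` -- modulate by the raw reward.
* ``Mk``: ``m(t) = r(t) - rbar(t, k)`` with ``rbar`` the moving average of
  the previous ``k`` rewards -- a simple reward-prediction-error estimate
  (constant reward streams drive ``m`` to zero).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "ModulationState",
    "reward_supervised",
    "reward_detector",
    "reward_generation",
    "modulation",
]

#: Moving-average windows explored in the original experiments; other
#: positive windows are accepted with a warning.
TESTED_WINDOWS = (1, 5, 10, 20)


def reward_supervised(predicted, target, wrong_reward: float = 0.0,
                      excluded: bool = False) -> float:
    """Reward for one supervised step: 1 on a match, ``wrong_reward``
    (0 or -1) on a mismatch, 0 on an excluded (unpredictable) position."""
    if excluded:
        return 0.0
    return 1.0 if predicted == target else float(wrong_reward)


def reward_detector(predicted: int, target: int, wrong_reward: float = -1.0,
                    excluded: bool = False) -> float:
    """Reward for a single-unit detector (Heaviside readout).

    Only an emitted detection is an *event*: a hit earns 1, a false
    alarm earns ``wrong_reward``, and both a correct rejection and a
    miss earn 0.  Staying silent is the expected default, not an
    achievement -- and a miss already produces no readout STDP (the
    update is gated by the output), so punishing it would only invert
    the recurrent STDP that is building the target representation.
    Under direct modulation this confines plasticity to the steps around
    detections, letting the recurrent layer represent parts of the
    target word exclusively.
    """
    if excluded:
        return 0.0
    if predicted == 1:
        return 1.0 if target == 1 else float(wrong_reward)
    return 0.0


def reward_generation(output_tail, target_words, n: int,
                      repeat_punishment: float | None = None,
                      punish_repeats: bool = True) -> float:
    """Per-step reward for the generation task.

    ``output_tail`` holds the most recent ``n`` output symbols.  The
    reward is ``L / n`` where ``L`` is the length of the longest suffix of
    the tail that equals a prefix of any target word; any other sequence
    earns nothing.  A tail ending in a doubled word-initial symbol (e.g.
    "...11" for a word starting "1") would otherwise collect ``1/n``
    forever, so it is punished (default ``-1/n``) to rule out trivial
    repetition.
    """
    words = [tuple(w) for w in target_words]
    if not words:
        raise ValueError("target word list is empty")
    tail = tuple(output_tail)
    if punish_repeats and len(tail) >= 2 and tail[-1] == tail[-2]:
        if any(tail[-1] == w[0] for w in words):
            return -1.0 / n if repeat_punishment is None else float(repeat_punishment)
    best = 0
    for w in words:
        for length in range(min(n, len(tail), len(w)), best, -1):
            if tail[-length:] == w[:length]:
                best = length
                break
    return best / n


@dataclass
class ModulationState:
    """Running state of a reward-modulation strategy.

    Tracks the bounded history of recent rewards and produces the output
    modulation factor ``m_o``; the recurrent factor is either 1 or
    ``m_o`` and is chosen by the plasticity configuration, not here.
    """

    strategy: str = "m0"
    k: int = 1
    history: deque = field(init=False)

    def __post_init__(self):
        self.strategy = self.strategy.lower()
        if self.strategy not in ("m0", "mk"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.k < 1:
            raise ValueError("window k must be >= 1")
        if self.strategy == "mk" and self.k not in TESTED_WINDOWS:
            warnings.warn(
                f"window k={self.k} is outside the originally tested set "
                f"{TESTED_WINDOWS}", stacklevel=2,
            )
        self.history = deque(maxlen=self.k)

    def modulation(self, r: float) -> float:
        """Modulation factor for reward ``r``; updates the history after.

        Under ``Mk`` the moving average uses however many rewards exist
        while the history is still shorter than ``k`` (0 at the start).
        """
        if self.strategy == "m0":
            m = float(r)
        else:
            rbar = float(np.mean(self.history)) if self.history else 0.0
            m = float(r) - rbar
        self.history.append(float(r))
        return m

    def reset(self) -> None:
        self.history.clear()


def modulation(state: ModulationState, r: float) -> float:
    """Functional wrapper around :meth:`ModulationState.modulation`."""
    return state.modulation(r)
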