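"""Benchmark tasks: seeded stream generators, target rules, exclusion
rules and performance measures.

Eight tasks probe prediction, recall, non-linear computation, pattern
recognition and sequence generation:

``counting``
    Random alternations of the words ``a b..b c`` and ``e d..d f`` with
    ``n + 2`` letters per word; predict the next letter.  Predicting the
    *last* letter requires counting the b's/d's.
``motion_prediction``
    Random renewal sequences of ``1 2 .. n`` and ``n .. 2 1`` (an object
    sweeping across a line of sensors); predict the next symbol.
``occluder``
    Alternations of ``12345678``, ``87654321``, ``19999998`` and
    ``89999991`` -- the motion task with an occluder (symbol 9) hiding
    the object's position.
``memory_capacity``
    A uniform random stream over 6 symbols; reproduce the symbol from
    ``n`` steps back.
``markov85``
    A 6-state first-order Markov chain with cyclic transitions of
    probability 0.85 (all others 0.03); recall (negative shift) or
    predict (positive shift) the state ``|n|`` steps away.
``parity``
    A random bit stream; output the parity of the current and the
    ``n - 1`` previous bits.
``motion_generation``
    No input: generate either motion word from feedback alone.
``pattern_recognition``
    Alternations of ``1234``, ``4321``, ``4213``, ``2431``; a single
    output unit must be 1 exactly during letters of ``1234``.

For prediction-style tasks, ``targets[t]`` is the symbol the network
must produce after having consumed ``inputs[0..t]``; positions whose
target is unpredictable by construction (word-initial letters, the first
steps of a delay window) are flagged in ``excluded`` and ignored both by
the reward and by the performance measures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "TaskSpec",
    "LabeledStream",
    "make_task",
    "TASK_NAMES",
    "gen_counting",
    "gen_motion",
    "gen_occluder",
    "gen_memory",
    "gen_markov85",
    "gen_parity",
    "gen_pattern_words",
    "performance",
    "counting_performance",
    "generation_performance",
]


@dataclass
class LabeledStream:
    """A symbol stream with aligned targets and exclusion mask.

    ``inputs`` and ``targets`` are integer indices into ``alphabet``
    (for pattern recognition, ``targets`` holds the 0/1 labels instead).
    ``final`` marks positions whose target is a word-final letter
    (counting-style tasks only).
    """

    inputs: np.ndarray
    targets: np.ndarray | None
    excluded: np.ndarray
    alphabet: tuple
    final: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def input_symbols(self):
        return [self.alphabet[i] for i in self.inputs]


@dataclass
class TaskSpec:
    """Static description of a task instance.

    ``mu_ip_output`` holds the expected occurrence probability of each
    output unit's symbol -- the per-unit target firing rate handed to the
    readout's intrinsic plasticity.  ``n_outputs`` equals the alphabet
    size for winner-takes-all prediction tasks, 1 for the Heaviside
    pattern detector.
    """

    name: str
    n: int
    alphabet: tuple
    n_outputs: int
    mu_ip_output: np.ndarray
    target_words: tuple | None = None
    has_input: bool = True
    generator: Callable | None = field(default=None, repr=False)

    def sample(self, length: int, seed=None) -> LabeledStream:
        if self.generator is None:
            raise ValueError(f"task {self.name!r} has no input stream")
        return self.generator(length, seed)


# ---------------------------------------------------------------------------
# word-alternation machinery

def _word_stream(words, length, rng):
    """Uniform i.i.d. word choices concatenated to ``length + 1`` symbols.

    Returns (symbol indices, position-in-word, word id), each of length
    ``length + 1`` so that one-step-ahead targets exist for all ``length``
    stream positions.
    """
    words = [np.asarray(w, dtype=np.int64) for w in words]
    word_len = len(words[0])
    if any(len(w) != word_len for w in words):
        raise ValueError("words must share a common length")
    total = length + 1
    n_words = -(-total // word_len) + 1
    choice = rng.integers(0, len(words), size=n_words)
    inputs = np.concatenate([words[c] for c in choice])[:total]
    pos = np.tile(np.arange(word_len), n_words)[:total]
    wid = np.repeat(choice, word_len)[:total]
    return inputs, pos, wid


def _word_frequencies(words, n_symbols):
    """Symbol occurrence probabilities under uniform word alternation."""
    counts = np.zeros(n_symbols)
    for w in words:
        for s in w:
            counts[s] += 1
    return counts / counts.sum()


def _prediction_stream(words, alphabet, length, seed, excluded_word_pos=(0,),
                       final_pos=None):
    rng = np.random.default_rng(seed)
    inputs, pos, _ = _word_stream(words, length, rng)
    targets = inputs[1:]
    next_pos = pos[1:]
    excluded = np.isin(next_pos, excluded_word_pos)
    final = None
    if final_pos is not None:
        final = next_pos == final_pos
    return LabeledStream(inputs=inputs[:length], targets=targets,
                         excluded=excluded, alphabet=tuple(alphabet),
                         final=final)


# ---------------------------------------------------------------------------
# generators

COUNTING_ALPHABET = ("a", "b", "c", "d", "e", "f")


def _counting_words(n):
    a, b, c, d, e, f = range(6)
    return [np.r_[[a], np.full(n, b), [c]], np.r_[[e], np.full(n, d), [f]]]


def gen_counting(n: int, length: int, seed=None) -> LabeledStream:
    """Counting task: words ``a b^n c`` / ``e d^n f``, predict next letter.

    The first letter of each word is unpredictable and excluded; the
    ``final`` mask marks positions whose target is the word-final c/f --
    the letters that require counting.
    """
    if n < 1:
        raise ValueError("word parameter n must be >= 1")
    if length < n + 2:
        raise ValueError("stream shorter than a single word")
    return _prediction_stream(_counting_words(n), COUNTING_ALPHABET, length,
                              seed, excluded_word_pos=(0,), final_pos=n + 1)


def _motion_words(n):
    asc = np.arange(n)
    return [asc, asc[::-1]]


def gen_motion(n: int, length: int, seed=None) -> LabeledStream:
    """Motion prediction: renewal sequences of ``12..n`` and ``n..21``."""
    if n < 2:
        raise ValueError("need at least 2 symbols")
    alphabet = tuple(str(i) for i in range(1, n + 1))
    return _prediction_stream(_motion_words(n), alphabet, length, seed,
                              excluded_word_pos=(0,))


OCCLUDER_WORDS = ("12345678", "87654321", "19999998", "89999991")
OCCLUDER_ALPHABET = tuple(str(i) for i in range(1, 10))


def gen_occluder(length: int, seed=None) -> LabeledStream:
    """Occluder task: the four 8-letter motion/occluder words.

    Because two words share each first letter, the *second* letter of a
    word is also unpredictable; both are excluded.
    """
    words = [[int(c) - 1 for c in w] for w in OCCLUDER_WORDS]
    return _prediction_stream(words, OCCLUDER_ALPHABET, length, seed,
                              excluded_word_pos=(0, 1))


MEMORY_ALPHABET = tuple(str(i) for i in range(1, 7))


def gen_memory(n: int, length: int, seed=None) -> LabeledStream:
    """Memory capacity: uniform 6-symbol stream, reproduce input(t - n)."""
    if n < 0:
        raise ValueError("delay must be non-negative")
    rng = np.random.default_rng(seed)
    inputs = rng.integers(0, 6, size=length)
    targets = np.empty(length, dtype=np.int64)
    targets[n:] = inputs[: length - n] if n else inputs
    targets[:n] = inputs[0]
    excluded = np.zeros(length, dtype=bool)
    excluded[:n] = True
    return LabeledStream(inputs=inputs, targets=targets, excluded=excluded,
                         alphabet=MEMORY_ALPHABET)


#: Cyclic transition probability of the 6-state chain; the remaining mass
#: is spread evenly over the other five states (0.03 each).
MARKOV85_P = 0.85


def markov85_matrix() -> np.ndarray:
    P = np.full((6, 6), (1.0 - MARKOV85_P) / 5)
    for i in range(6):
        P[i, (i + 1) % 6] = MARKOV85_P
    return P


def gen_markov85(n: int, length: int, seed=None) -> LabeledStream:
    """Markov-85: 6-state chain; signed shift ``n`` (< 0 recall, > 0
    prediction, 0 identity).  Out-of-range boundary positions excluded."""
    rng = np.random.default_rng(seed)
    inputs = np.empty(length, dtype=np.int64)
    state = int(rng.integers(0, 6))
    inputs[0] = state
    jump = rng.random(length)
    alt = rng.integers(0, 5, size=length)
    for t in range(1, length):
        succ = (state + 1) % 6
        if jump[t] < MARKOV85_P:
            state = succ
        else:
            # uniform over the five non-cyclic successors (incl. staying put)
            a = int(alt[t])
            state = a if a < succ else a + 1
        inputs[t] = state
    targets = np.empty(length, dtype=np.int64)
    excluded = np.zeros(length, dtype=bool)
    shifted = np.arange(length) + n
    valid = (shifted >= 0) & (shifted < length)
    targets[valid] = inputs[shifted[valid]]
    targets[~valid] = inputs[0]
    excluded[~valid] = True
    return LabeledStream(inputs=inputs, targets=targets, excluded=excluded,
                         alphabet=MEMORY_ALPHABET)


PARITY_ALPHABET = ("0", "1")


def gen_parity(n: int, length: int, seed=None) -> LabeledStream:
    """Parity of the current and ``n - 1`` previous bits (XOR window)."""
    if n < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=length)
    csum = np.concatenate([[0], np.cumsum(bits)])
    win = csum[np.minimum(np.arange(length) + 1, length)] - \
        csum[np.maximum(np.arange(length) + 1 - n, 0)]
    targets = (win % 2).astype(np.int64)
    excluded = np.zeros(length, dtype=bool)
    excluded[: n - 1] = True
    return LabeledStream(inputs=bits.astype(np.int64), targets=targets,
                         excluded=excluded, alphabet=PARITY_ALPHABET)


PATTERN_WORDS = ("1234", "4321", "4213", "2431")
PATTERN_ALPHABET = ("1", "2", "3", "4")


def gen_pattern_words(length: int, seed=None) -> LabeledStream:
    """Pattern recognition: label 1 for every letter of the word 1234.

    Labels follow the generated word identity, flipping exactly at word
    boundaries; no position is excluded (labels are fully determined by
    the history including the current letter).
    """
    rng = np.random.default_rng(seed)
    words = [[int(c) - 1 for c in w] for w in PATTERN_WORDS]
    inputs, _, wid = _word_stream(words, length - 1, rng)
    inputs, wid = inputs[:length], wid[:length]
    targets = (wid == 0).astype(np.int64)
    return LabeledStream(inputs=inputs, targets=targets,
                         excluded=np.zeros(length, dtype=bool),
                         alphabet=PATTERN_ALPHABET)


# ---------------------------------------------------------------------------
# performance measures

def _check_lengths(predictions, targets):
    predictions = np.asarray(predictions)
    targets = np.asarray(targets)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets differ in length")
    if predictions.size == 0:
        raise ValueError("empty stream")
    return predictions, targets


def performance(predictions, targets, excluded=None) -> float:
    """Fraction of matching symbols over all non-excluded positions."""
    predictions, targets = _check_lengths(predictions, targets)
    if excluded is None:
        valid = np.ones(predictions.shape, dtype=bool)
    else:
        valid = ~np.asarray(excluded, dtype=bool)
    if not valid.any():
        raise ValueError("no non-excluded positions to score")
    return float(np.mean(predictions[valid] == targets[valid]))


def counting_performance(predictions, targets, final_mask) -> float:
    """Accuracy restricted to word-final targets (the c/f predictions)."""
    predictions, targets = _check_lengths(predictions, targets)
    final_mask = np.asarray(final_mask, dtype=bool)
    if not final_mask.any():
        raise ValueError("no word-final positions in the stream")
    return float(np.mean(predictions[final_mask] == targets[final_mask]))


def generation_performance(outputs, target_words) -> float:
    """Fraction of output positions covered by a complete occurrence of a
    target word (stricter than prefix credit, monotone in quality)."""
    outputs = np.asarray(outputs)
    if outputs.size == 0:
        raise ValueError("empty output sequence")
    covered = np.zeros(outputs.size, dtype=bool)
    for w in target_words:
        w = np.asarray(w)
        L = len(w)
        for i in range(outputs.size - L + 1):
            if np.array_equal(outputs[i:i + L], w):
                covered[i:i + L] = True
    return float(covered.mean())


# ---------------------------------------------------------------------------
# task registry

TASK_NAMES = (
    "counting",
    "motion_prediction",
    "occluder",
    "memory_capacity",
    "markov85",
    "parity",
    "motion_generation",
    "pattern_recognition",
)


def make_task(name: str, n: int | None = None) -> TaskSpec:
    """Build a :class:`TaskSpec` for ``name`` with difficulty ``n``.

    ``n`` is the word size (counting), symbol count (motion tasks), delay
    (memory), signed shift (markov85) or window (parity); the occluder
    and pattern-recognition tasks have it fixed by their word sets.
    """
    if name == "counting":
        n = 4 if n is None else n
        words = _counting_words(n)
        return TaskSpec(
            name=name, n=n, alphabet=COUNTING_ALPHABET, n_outputs=6,
            mu_ip_output=_word_frequencies(words, 6),
            generator=lambda length, seed=None: gen_counting(n, length, seed),
        )
    if name == "motion_prediction":
        n = 4 if n is None else n
        alphabet = tuple(str(i) for i in range(1, n + 1))
        return TaskSpec(
            name=name, n=n, alphabet=alphabet, n_outputs=n,
            mu_ip_output=np.full(n, 1.0 / n),
            generator=lambda length, seed=None: gen_motion(n, length, seed),
        )
    if name == "occluder":
        words = [[int(c) - 1 for c in w] for w in OCCLUDER_WORDS]
        return TaskSpec(
            name=name, n=8, alphabet=OCCLUDER_ALPHABET, n_outputs=9,
            mu_ip_output=_word_frequencies(words, 9),
            generator=lambda length, seed=None: gen_occluder(length, seed),
        )
    if name == "memory_capacity":
        n = 1 if n is None else n
        return TaskSpec(
            name=name, n=n, alphabet=MEMORY_ALPHABET, n_outputs=6,
            mu_ip_output=np.full(6, 1.0 / 6),
            generator=lambda length, seed=None: gen_memory(n, length, seed),
        )
    if name == "markov85":
        n = -1 if n is None else n
        return TaskSpec(
            name=name, n=n, alphabet=MEMORY_ALPHABET, n_outputs=6,
            mu_ip_output=np.full(6, 1.0 / 6),
            generator=lambda length, seed=None: gen_markov85(n, length, seed),
        )
    if name == "parity":
        n = 2 if n is None else n
        return TaskSpec(
            name=name, n=n, alphabet=PARITY_ALPHABET, n_outputs=2,
            mu_ip_output=np.array([0.5, 0.5]),
            generator=lambda length, seed=None: gen_parity(n, length, seed),
        )
    if name == "motion_generation":
        n = 4 if n is None else n
        alphabet = tuple(str(i) for i in range(1, n + 1))
        words = _motion_words(n)
        return TaskSpec(
            name=name, n=n, alphabet=alphabet, n_outputs=n,
            mu_ip_output=np.full(n, 1.0 / n),
            target_words=tuple(tuple(w) for w in words), has_input=False,
        )
    if name == "pattern_recognition":
        return TaskSpec(
            name=name, n=4, alphabet=PATTERN_ALPHABET, n_outputs=1,
            mu_ip_output=np.array([0.25]),
            target_words=((0, 1, 2, 3),),
            generator=lambda length, seed=None: gen_pattern_words(length, seed),
        )
    raise ValueError(f"unknown task {name!r}; choose from {TASK_NAMES}")
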