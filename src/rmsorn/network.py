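"""Two-layer binary threshold network: layers, state update, input encoding.

The model is a recurrent reservoir of ``N_E`` excitatory and
``N_I = N_E / 5`` inhibitory binary units, read out by a second layer of
binary units driven by the excitatory population only.  Excitatory-to-
excitatory connectivity is sparse (5--10 %) with a fixed support -- the
*eligibility mask* -- and no self-connections; excitatory/inhibitory
connectivity is dense.  All weights are non-negative at all times.

State update (:math:`\\Theta` is the elementwise Heaviside step with the
convention :math:`\\Theta(v) = 1 \\iff v \\ge 0`):

.. math::

    x(t+1) &= \\Theta(W^{EE} x(t) - W^{EI} y(t) + u(t) - T^E) \\\\
    y(t+1) &= \\Theta(W^{IE} x(t) - T^I) \\\\
    o      &= a(W^{OE} x - T^O)

where ``a`` is winner-takes-all (WTA) for multi-unit readouts and the
Heaviside step for a single readout unit.  External input ``u`` enters
additively with weight 1: each symbol of the task alphabet activates a
fixed, seeded subset of the excitatory units (:class:`SymbolEncoder`).
"""
from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np

__all__ = [
    "WTA",
    "HEAVISIDE",
    "heaviside",
    "RecurrentLayer",
    "OutputLayer",
    "SymbolEncoder",
    "init_network",
    "step_recurrent",
    "step_output",
    "save_snapshot",
    "load_snapshot",
]

#: Output activation modes.
WTA = "wta"
HEAVISIDE = "heaviside"

#: Boundary convention of the step function: Theta(0) = 1.  Applied
#: consistently to recurrent, inhibitory and output units.
THETA_AT_ZERO = 1.0


def heaviside(v: np.ndarray) -> np.ndarray:
    """Elementwise binary threshold, ``Theta(v) = 1 iff v >= 0``."""
    return (np.asarray(v) >= 0.0).astype(np.float64)


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    """Scale each row with positive sum to sum 1 (rows of zeros are kept)."""
    s = W.sum(axis=1)
    nz = s > 0
    W[nz] /= s[nz, None]
    return W


@dataclass
class RecurrentLayer:
    """Plastic recurrent reservoir (excitatory + inhibitory populations).

    Attributes
    ----------
    W_EE : (N_E, N_E) array
        Excitatory->excitatory weights, non-negative, zero outside ``mask``.
    W_EI : (N_E, N_I) array
        Inhibitory->excitatory weights (dense, static).
    W_IE : (N_I, N_E) array
        Excitatory->inhibitory weights (dense, static).
    mask : (N_E, N_E) bool array
        Eligibility mask: the fixed support of ``W_EE``.  Weights may decay
        to zero but connections never form outside the mask.
    T_E, T_I : arrays
        Firing thresholds; ``T_E`` is plastic under intrinsic plasticity.
    x, y : binary arrays
        Current excitatory / inhibitory state.
    """

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    mask: np.ndarray
    T_E: np.ndarray
    T_I: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def n_excitatory(self) -> int:
        return self.W_EE.shape[0]

    @property
    def n_inhibitory(self) -> int:
        return self.W_IE.shape[0]

    def copy(self) -> "RecurrentLayer":
        return RecurrentLayer(
            W_EE=self.W_EE.copy(),
            W_EI=self.W_EI.copy(),
            W_IE=self.W_IE.copy(),
            mask=self.mask,  # immutable by contract
            T_E=self.T_E.copy(),
            T_I=self.T_I.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
        )


@dataclass
class OutputLayer:
    """Readout layer of binary units driven by the excitatory reservoir."""

    W_OE: np.ndarray
    T_O: np.ndarray
    o: np.ndarray
    activation_mode: str = WTA

    @property
    def n_outputs(self) -> int:
        return self.W_OE.shape[0]

    def copy(self) -> "OutputLayer":
        return OutputLayer(
            W_OE=self.W_OE.copy(),
            T_O=self.T_O.copy(),
            o=self.o.copy(),
            activation_mode=self.activation_mode,
        )


def init_network(
    n_excitatory: int,
    n_outputs: int,
    sparsity: float = 0.10,
    seed: int | None = None,
    *,
    t_max: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[RecurrentLayer, OutputLayer]:
    """Build a seeded network.

    The eligibility mask holds ``floor(sparsity * N_E * (N_E - 1))``
    off-diagonal entries chosen uniformly at random.  Weights are drawn as
    the magnitude of standard-normal deviates on their support and every
    row is immediately scaled to sum 1, which both guarantees positivity
    and puts the weights at the fixed point of synaptic normalization.
    Thresholds are drawn uniformly from ``[0, t_max]``; intrinsic
    plasticity rapidly adapts ``T_E`` and ``T_O``, so only the scale of
    the static ``T_I`` matters.

    Identical ``seed`` (or generator state) yields a bit-identical network.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError(f"sparsity must lie in [0, 1], got {sparsity}")
    if n_excitatory < 5:
        raise ValueError("need at least 5 excitatory units to form the inhibitory pool")
    if n_outputs < 1:
        raise ValueError("need at least one output unit")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_e = int(n_excitatory)
    n_i = int(round(n_e / 5))

    # Eligibility mask over off-diagonal entries.
    n_edges = int(math.floor(sparsity * n_e * (n_e - 1)))
    off_diag = np.flatnonzero(~np.eye(n_e, dtype=bool))
    chosen = rng.choice(off_diag, size=n_edges, replace=False)
    mask = np.zeros((n_e, n_e), dtype=bool)
    mask.flat[chosen] = True
    mask.flags.writeable = False

    W_EE = np.zeros((n_e, n_e))
    W_EE[mask] = np.abs(rng.standard_normal(n_edges))
    _normalize_rows(W_EE)

    W_EI = _normalize_rows(np.abs(rng.standard_normal((n_e, n_i))))
    W_IE = _normalize_rows(np.abs(rng.standard_normal((n_i, n_e))))

    T_E = rng.uniform(0.0, t_max, size=n_e)
    T_I = rng.uniform(0.0, t_max, size=n_i)

    recurrent = RecurrentLayer(
        W_EE=W_EE, W_EI=W_EI, W_IE=W_IE, mask=mask, T_E=T_E, T_I=T_I,
        x=np.zeros(n_e), y=np.zeros(n_i),
    )

    W_OE = _normalize_rows(np.abs(rng.standard_normal((n_outputs, n_e))))
    T_O = rng.uniform(0.0, t_max, size=n_outputs)
    output = OutputLayer(
        W_OE=W_OE, T_O=T_O, o=np.zeros(n_outputs),
        activation_mode=HEAVISIDE if n_outputs == 1 else WTA,
    )
    return recurrent, output


def step_recurrent(layer: RecurrentLayer, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Advance the recurrent layer by one step given external input ``u``.

    Both populations update from the *previous* excitatory state.  The
    layer is mutated in place; the new ``(x, y)`` is returned.
    """
    if u.shape != layer.x.shape:
        raise ValueError(f"input has shape {u.shape}, expected {layer.x.shape}")
    x_old = layer.x
    drive = layer.W_EE @ x_old - layer.W_EI @ layer.y + u - layer.T_E
    layer.x = (drive >= 0.0).astype(np.float64)
    layer.y = (layer.W_IE @ x_old - layer.T_I >= 0.0).astype(np.float64)
    return layer.x, layer.y


def step_output(layer: OutputLayer, x: np.ndarray) -> np.ndarray:
    """Update the readout from excitatory state ``x``.

    In WTA mode exactly one unit -- the one with maximal net drive -- is
    set to 1; ties go to the lowest index, keeping trajectories fully
    deterministic.  In Heaviside mode (single unit) the output is the
    thresholded drive.
    """
    if x.shape[0] != layer.W_OE.shape[1]:
        raise ValueError("state length does not match readout weights")
    drive = layer.W_OE @ x - layer.T_O
    if layer.activation_mode == WTA:
        o = np.zeros_like(layer.T_O)
        o[int(np.argmax(drive))] = 1.0
    elif layer.activation_mode == HEAVISIDE:
        o = (drive >= 0.0).astype(np.float64)
    else:  # pragma: no cover - guarded at construction
        raise ValueError(f"unknown activation mode {layer.activation_mode!r}")
    layer.o = o
    return o


class SymbolEncoder:
    """Fixed, seeded mapping from alphabet symbols to binary input vectors.

    Each symbol activates a disjoint subset of the excitatory units
    (default size ``ceil(0.05 * n_units)`` per symbol).  If the alphabet
    is too large for disjoint subsets of that size, the subset size is
    reduced to ``n_units // len(alphabet)`` with a warning.
    """

    def __init__(
        self,
        alphabet,
        n_units: int,
        units_per_symbol: int | None = None,
        seed: int | None = None,
        *,
        rng: np.random.Generator | None = None,
    ):
        self.alphabet = tuple(alphabet)
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        n_sym = len(self.alphabet)
        if n_sym > n_units:
            raise ValueError("alphabet larger than the excitatory population")
        if units_per_symbol is None:
            units_per_symbol = math.ceil(0.05 * n_units)
        if units_per_symbol * n_sym > n_units:
            units_per_symbol = max(1, n_units // n_sym)
            warnings.warn(
                "reduced input subset size to keep per-symbol subsets disjoint",
                stacklevel=2,
            )
        self.units_per_symbol = units_per_symbol
        if rng is None:
            rng = np.random.default_rng(seed)
        perm = rng.permutation(n_units)
        self.matrix = np.zeros((n_sym, n_units))
        for i in range(n_sym):
            self.matrix[i, perm[i * units_per_symbol:(i + 1) * units_per_symbol]] = 1.0
        self.matrix.flags.writeable = False
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    def index(self, symbol) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.alphabet}") from None

    def encode(self, symbol) -> np.ndarray:
        """Binary input vector for ``symbol`` (a fresh writable copy)."""
        return self.matrix[self.index(symbol)].copy()


def save_snapshot(path, recurrent: RecurrentLayer, output: OutputLayer,
                  *, seed: int | None = None, step: int = 0) -> None:
    """Serialize a network to a single ``.npz`` archive of named arrays.

    The archive holds every weight matrix, threshold vector, the state,
    the eligibility mask, the seed and the step counter; the round-trip
    through :func:`load_snapshot` is bit-exact.
    """
    np.savez(
        path,
        W_EE=recurrent.W_EE, W_EI=recurrent.W_EI, W_IE=recurrent.W_IE,
        mask=recurrent.mask, T_E=recurrent.T_E, T_I=recurrent.T_I,
        x=recurrent.x, y=recurrent.y,
        W_OE=output.W_OE, T_O=output.T_O, o=output.o,
        activation_mode=np.array(output.activation_mode),
        seed=np.array(-1 if seed is None else seed),
        step=np.array(step),
    )


def load_snapshot(path) -> tuple[RecurrentLayer, OutputLayer, dict]:
    """Restore a network from :func:`save_snapshot`; returns metadata too."""
    with np.load(path) as z:
        mask = z["mask"]
        mask.flags.writeable = False
        recurrent = RecurrentLayer(
            W_EE=z["W_EE"], W_EI=z["W_EI"], W_IE=z["W_IE"], mask=mask,
            T_E=z["T_E"], T_I=z["T_I"], x=z["x"], y=z["y"],
        )
        output = OutputLayer(
            W_OE=z["W_OE"], T_O=z["T_O"], o=z["o"],
            activation_mode=str(z["activation_mode"]),
        )
        seed = int(z["seed"])
        meta = {"seed": None if seed == -1 else seed, "step": int(z["step"])}
    return recurrent, output, meta
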