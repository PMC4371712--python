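"""Plasticity rules: intrinsic plasticity, reward-modulated STDP, synaptic
normalization, and the per-step orchestration.

Three rules act on the network every simulation step:

* **Intrinsic plasticity (IP)** nudges each unit's threshold so that its
  long-run firing rate converges to a target ``mu_IP``:
  ``dT_i = eta_IP * (activity_i - mu_IP_i)``.
* **Reward-modulated STDP** changes weights according to pre/post spike
  timing, scaled by a modulation factor ``m`` derived from reward.  On the
  recurrent weights the rule is antisymmetric
  (``dw_ij = m_r * eta * (x_j(t-1) x_i(t) - x_j(t) x_i(t-1))``); on the
  readout weights it is purely Hebbian on the driving state
  (``dw_ij = m_o * eta * x_j(t-1) o_i(t)``).  Negative modulation inverts
  the rule (Anti-STDP); zero modulation suppresses it.
* **Synaptic normalization (SN)** rescales each unit's incoming weights to
  sum to 1, preserving relative strengths and introducing synaptic
  competition.

Within a step the order is STDP -> clip at zero -> SN -> IP: normalization
must restore the sum-1 constraint immediately after the weight change, and
IP acts on thresholds independently of the weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import OutputLayer, RecurrentLayer

__all__ = [
    "PlasticityConfig",
    "ip_update",
    "stdp_recurrent",
    "stdp_output",
    "synaptic_normalize",
    "plasticity_step",
]


@dataclass
class PlasticityConfig:
    """Learning rates, target rates and rule switches.

    ``mu_ip_output`` holds one target rate per output unit and is normally
    set to the expected occurrence probability of the symbol the unit
    represents.  ``modulate_recurrent`` selects whether the recurrent STDP
    shares the readout's modulation factor (``m_r = m_o``) or runs
    unmodulated (``m_r = 1``).  ``sn_output`` / ``ip_output`` exist for the
    normalization-ablation and noise-exploration variants.
    """

    eta_ip: float = 0.01
    eta_stdp: float = 0.004
    mu_ip_recurrent: float = 0.1
    mu_ip_output: np.ndarray = field(default_factory=lambda: np.array([0.5]))
    modulate_recurrent: bool = False
    sn_output: bool = True
    ip_output: bool = True

    def __post_init__(self):
        if self.eta_ip <= 0 or self.eta_stdp <= 0:
            raise ValueError("learning rates must be strictly positive")
        if not 0.0 < self.mu_ip_recurrent < 1.0:
            raise ValueError("mu_ip_recurrent must lie in (0, 1)")
        self.mu_ip_output = np.atleast_1d(np.asarray(self.mu_ip_output, dtype=float))
        if np.any(self.mu_ip_output <= 0) or np.any(self.mu_ip_output >= 1):
            raise ValueError("per-output target rates must lie in (0, 1)")


def ip_update(T: np.ndarray, activity: np.ndarray, eta_ip: float,
              mu_ip: float | np.ndarray) -> np.ndarray:
    """Intrinsic-plasticity threshold update (in place).

    Raises the threshold of units that just fired and lowers it for silent
    ones; the fixed point of the induced dynamics is a mean firing rate of
    ``mu_ip`` per unit.
    """
    if T.shape != np.shape(activity):
        raise ValueError("threshold and activity shapes differ")
    T += eta_ip * (activity - mu_ip)
    return T


def stdp_recurrent(x_prev: np.ndarray, x_curr: np.ndarray, m_r: float,
                   eta_stdp: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Modulated STDP weight delta for the recurrent excitatory weights.

    ``dw_ij = m_r * eta * (x_j(t-1) x_i(t) - x_j(t) x_i(t-1))``: causal
    firing (j before i) strengthens ``w_ij``, anti-causal firing weakens
    it, and negative modulation inverts both (Anti-STDP).  The delta is
    restricted to the eligibility ``mask`` when given; applying it and
    clipping at zero is the caller's job.
    """
    delta = m_r * eta_stdp * (np.outer(x_curr, x_prev) - np.outer(x_prev, x_curr))
    if mask is not None:
        delta *= mask
    return delta


def stdp_output(x_pre: np.ndarray, o_curr: np.ndarray, m_o: float,
                eta_stdp: float) -> np.ndarray:
    """Modulated STDP delta for the readout weights.

    ``dw_ij = m_o * eta * x_j(t-1) o_i(t)`` where ``x(t-1)`` is the
    excitatory state that drove the output ``o(t)``.  There is no
    anti-causal term: the rule is purely potentiating for positive
    modulation and purely depressing for negative modulation.
    """
    return m_o * eta_stdp * np.outer(o_curr, x_pre)


def synaptic_normalize(W: np.ndarray) -> np.ndarray:
    """Scale each row of ``W`` (a unit's incoming weights) to sum to 1.

    Rows summing to zero are left unchanged -- a unit whose incoming
    weights all decayed to zero simply stays silent; the update remains
    well-defined.  Operates in place and returns ``W``.
    """
    if np.any(W < 0):
        raise ValueError("negative weights reached synaptic normalization")
    s = W.sum(axis=1)
    nz = s > 0
    W[nz] /= s[nz, None]
    return W


def _scatter_delta(delta: np.ndarray, eligible_flat: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Reassign the multiset of nonzero update values to random eligible
    positions (the 'random' comparison network's update rule)."""
    vals = delta[delta != 0.0]
    out = np.zeros_like(delta)
    if vals.size:
        pos = rng.choice(eligible_flat, size=vals.size, replace=False)
        out.flat[pos] = vals
    return out


def plasticity_step(
    recurrent: RecurrentLayer,
    output: OutputLayer,
    config: PlasticityConfig,
    m_o: float,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    o_curr: np.ndarray,
    phase: int = 1,
    *,
    scatter_rng: np.random.Generator | None = None,
) -> None:
    """Apply one full plasticity step after state propagation.

    Order: (1) STDP on ``W_EE`` (phase 1 only), (2) STDP on ``W_OE``,
    (3) clip at zero and synaptically normalize ``W_EE`` and (if enabled)
    ``W_OE``, (4) IP on ``T_E`` (phase 1 only) and (if enabled) ``T_O``.
    In phase 2 the recurrent layer is entirely frozen (no STDP, SN or IP),
    fine-tuning only the readout.

    ``x_prev``/``x_curr`` are the excitatory states before/after the step;
    ``o_curr`` is the output that ``x_curr`` drove.  When ``scatter_rng``
    is given, the values of every *reward-modulated* update are
    redistributed over random eligible positions before application (the
    'random' control network); an unmodulated recurrent rule
    (``m_r = 1``) is not reward information and is applied as is.
    """
    if phase not in (1, 2):
        raise ValueError(f"unknown phase {phase}")

    recurrent_plastic = phase == 1
    if recurrent_plastic:
        m_r = m_o if config.modulate_recurrent else 1.0
        if m_r != 0.0:
            d = stdp_recurrent(x_prev, x_curr, m_r, config.eta_stdp, recurrent.mask)
            if scatter_rng is not None and config.modulate_recurrent:
                d = _scatter_delta(d, np.flatnonzero(recurrent.mask), scatter_rng)
            recurrent.W_EE += d
            np.maximum(recurrent.W_EE, 0.0, out=recurrent.W_EE)

    if m_o != 0.0:
        d = stdp_output(x_curr, o_curr, m_o, config.eta_stdp)
        if scatter_rng is not None:
            d = _scatter_delta(d, np.arange(output.W_OE.size), scatter_rng)
        output.W_OE += d
        np.maximum(output.W_OE, 0.0, out=output.W_OE)

    if recurrent_plastic:
        synaptic_normalize(recurrent.W_EE)
    if config.sn_output:
        synaptic_normalize(output.W_OE)

    if recurrent_plastic:
        ip_update(recurrent.T_E, x_curr, config.eta_ip, config.mu_ip_recurrent)
    if config.ip_output:
        ip_update(output.T_O, o_curr, config.eta_ip, config.mu_ip_output)
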