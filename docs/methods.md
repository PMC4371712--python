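# Methods

## Model

The simulator implements a two-layer network of binary threshold
neurons.  The first layer is a recurrent reservoir of `N_E` excitatory
and `N_I = round(N_E / 5)` inhibitory units; the second is a readout
layer driven by the excitatory units only.  States update synchronously:

    x(t+1) = Θ(W_EE x(t) − W_EI y(t) + u(t) − T_E)
    y(t+1) = Θ(W_IE x(t) − T_I)
    o      = a(W_OE x − T_O)

with `Θ` the Heaviside step and `a` winner-takes-all (WTA) for
multi-unit readouts or `Θ` for a single readout unit.  Excitatory→
excitatory connectivity is sparse with a fixed support (the eligibility
mask; no self-connections, no structural growth); all other
connectivity is dense.  All weights are non-negative at all times.
External input is additive with weight 1: each symbol of a task
alphabet activates a fixed, seeded subset of excitatory units.

Three plasticity rules act each step, in the order STDP → clip at
zero → synaptic normalization → intrinsic plasticity:

* **STDP** (recurrent): `Δw_ij = m_r η_STDP (x_j(t−1) x_i(t) − x_j(t) x_i(t−1))`,
  restricted to the eligibility mask.
* **STDP** (readout): `Δw_ij = m_o η_STDP x_j(t−1) o_i(t)` where
  `x(t−1)` is the state that drove `o(t)` — purely Hebbian on the
  driver, no anti-causal term.
* **Synaptic normalization (SN)**: each unit's incoming weights are
  rescaled to sum to 1, preserving relative strengths.  Applied every
  step to `W_EE` and (by default) `W_OE`; never to the static `W_EI`,
  `W_IE`.
* **Intrinsic plasticity (IP)**: `ΔT_i = η_IP (activity_i − μ_IP,i)`,
  whose fixed point is a mean firing rate of `μ_IP` per unit.  IP — not
  noise — is the exploration mechanism: threshold drift continually
  perturbs which units fire, deterministically.

The modulation factor `m_o` is derived from the reward `r` by one of
two strategies: `M0: m = r` or `Mk: m = r − r̄(k)` with `r̄(k)` the
moving average of the previous `k` rewards (a reward-prediction-error
estimate; a constant reward stream drives `m → 0`).  The recurrent
factor `m_r` is either 1 (unmodulated, the default) or shares `m_o`.
Negative modulation inverts STDP (Anti-STDP); zero suppresses it.

## Rewards

Supervised tasks: reward 1 for a correct output symbol, `wrong_reward`
∈ {0, −1} otherwise.  Positions whose target is unpredictable by
construction (word-initial letters; the first steps of a delay window)
carry *no learning signal*: the modulation is forced to 0 and the step
does not enter the Mk history.  (A literal reward of 0 fed into Mk
would produce a spurious negative modulation `−r̄`.)

For the single-unit pattern detector an alternative `detector` reward
treats only emitted detections as events: a hit earns 1, a false alarm
earns `wrong_reward`, and both a correct rejection and a miss earn 0.
A miss already produces no readout STDP (the update is gated by the
output), and punishing it would invert the recurrent STDP that is
building the target representation; confining plasticity to the steps
around detections is what lets the recurrent layer represent parts of
the target word exclusively.  Rewarding correct rejections instead (the
literal symbol-match reward) floods the recurrent layer with
indiscriminate STDP and measurably lowers detection performance.

Generation task: the per-step reward is `L/n`, where `L` is the length
of the longest suffix of the last `n` output symbols that is a prefix
of a target word (`1 2 … n` or `n … 2 1`); the full reward of 1 arrives
at the step emitting a word's last symbol.  A doubled word-initial
symbol would collect `1/n` forever, so it is punished with `−1/n`
(configurable).  The reference formulation punishes only the doubled
"1"; we apply the same guard to every word-initial symbol because the
descending word's first symbol admits the same degenerate loop.  The
per-step reward is computed from the current suffix (consistent with
the one-step readout STDP rule); accumulating credit only at word
completion is a noted alternative.

## Training protocol

Two phases of 20,000 steps.  Phase 1 runs all plasticity (recurrent
modulation only if configured).  Every 100 steps the network is cloned
and scored on a fixed 500-step validation stream; the best of the 200
candidates seeds phase 2, in which the recurrent layer is entirely
frozen (no STDP, SN or IP) and only the readout continues to adapt,
with the same validation cadence.  The better of the phase-1 and
phase-2 winners is tested on 10,000 fresh steps (the phase-1 winner is
itself the phase-2 candidate at time zero, so this is the
best-on-validation rule applied across both phases).  Evaluation always
starts from a silent reservoir and is fully deterministic.

Comparison models:

* **SORN** — the unmodulated ancestor: same reservoir plasticity, but
  the readout is fit by non-negative least squares (NNLS) on harvested
  states against one-hot targets (non-negativity mirrors the positivity
  of the plastic weights).  Snapshots every 1,000 steps give 20
  candidates (200, via a 100-step interval, for the pattern task where
  the reward-modulated network is strongest); each candidate re-processes
  the stream frozen, its readout is fit and validated, the best is kept.
  For a single-unit readout the NNLS prediction is thresholded at 0.5.
* **Static** — the best SORN's recurrent weights with the values
  permuted across the eligibility mask (thresholds kept, no
  re-normalization), readout refit per shuffle, best of `n_shuffles`
  kept.
* **Random** — trained exactly like the reward-modulated network, but
  every step's *reward-modulated* STDP update values are re-assigned to
  uniformly random eligible positions before application ("lucky
  guessing").  An unmodulated recurrent rule (`m_r = 1`) carries no
  reward information and is applied as is, so the control isolates what
  reward-guided credit assignment adds over chance placement.
* **Noise exploration** — readout IP replaced by bit-flip noise: the
  WTA winner is flipped with probability `p` per training step, with
  readout thresholds frozen to the per-unit average over the last 1,000
  steps of a preliminary 20,000-step unmodulated run of the same
  network.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `η_STDP` | 0.004 | STDP learning rate (both layers) |
| `η_IP` | 0.01 | threshold learning rate |
| `μ_IP` (recurrent) | 0.1 | target excitatory firing rate, task-tuned in [0.05, 0.25] |
| `μ_IP` (readout) | symbol frequencies | per-unit expected occurrence probability |
| sparsity | 0.10 | fraction of eligible excitatory→excitatory pairs |
| `t_max` | 1.0 | upper bound of the uniform initial thresholds |
| units per symbol | ⌈0.05 N_E⌉ | input subset size, disjoint across symbols |

Initial weights are |N(0, 1)| deviates on their support, immediately
row-normalized (positivity plus the SN fixed point); the reference
formulation states only "drawn from a normal distribution".  `Θ(0) = 1`
everywhere (the boundary is unstated in the reference; one convention
is applied consistently).  WTA ties break to the lowest index, keeping
trajectories reproducible.  Initial thresholds are uniform on
[0, `t_max`]; IP immediately adapts `T_E` and `T_O`, so `t_max`
effectively sets the static inhibitory threshold scale.  `t_max = 1.0`
places the reservoir in the regime where the supervised baseline solves
the counting task essentially perfectly, which we use as the dynamical
calibration of the inhibitory balance.

Per-task reward settings (strategy, window, punishment, `μ_IP`) are
selected by a per-task grid search and frozen in
`rmsorn.defaults.TASK_DEFAULTS`; the experiment registry and CLI apply
them automatically unless overridden.  The reward-prediction-error
strategy is the default for most tasks; counting and pattern
recognition use direct reward modulation with punishment
(`wrong_reward = −1`), which proved markedly more stable than
reward-0-for-errors on long words.  The counting defaults also use
8 input units per symbol at 7% connectivity and `η_STDP = 0.012`,
which let the network count reliably through `n = 8` while keeping the
`n = 20` regime stable.

For the 30-unit pattern-recognition network the defaults deviate
further, each for a mechanistic reason:

* larger input subsets (5 of 30 units per symbol) — with 4 symbols most
  of the reservoir receives input, and selectivity arises from IP
  raising input-unit thresholds above the pure input drive;
* a recurrent target rate of 0.0625 — an input unit whose rate target
  is its symbol frequency (0.25) times the context frequency (0.25)
  must recruit recurrent context drive to fire at all, which is exactly
  the two-symbol selectivity the task needs;
* denser recurrent connectivity (0.25) — at `N_E = 30` a 10%-sparse
  graph gives each unit ~3 recurrent inputs and essentially no memory;
  0.25 restores a usable in-degree;
* `η_STDP = 0.008`, `η_IP = 0.002` — faster synaptic sculpting over a
  slower, steadier threshold drift.

With these settings the mean pattern-recognition test performance over
replicate runs sits around 92%, with individual runs reaching 97–100%;
runs that fall short typically fail on the word-initial letter, whose
correct labeling requires two-symbol context in one of the three
possible preceding contexts.

## Synthetic data

All inputs are synthetic by construction — the benchmark tasks *are*
seeded stream generators (word alternations, uniform streams, a 6-state
Markov chain), reproducible from `(task, n, seed, length)`.  There is
no external data; what the tests show is therefore exactly what the
model does on the reference task family, not on natural data.

## Problem sizes and numerical choices

The acceptance script keeps the full per-run protocol (20,000 steps per
phase, 200 validations per phase, 10,000-step test) and reduces only
replicate counts (4–10 runs per condition instead of the 10 × 10
evaluation design), a choice made for single-CPU turnaround; stochastic
spread across training runs is correspondingly larger than in the
reference averages.  The comparison networks for the pattern task
evaluate the full 200 candidates but fit each candidate's readout on a
10,000-step harvest.  Rows whose incoming weights all reach zero are
left unnormalized (the unit simply stays silent).  Weight clipping at
zero precedes normalization.  Degenerate streams (no scorable
positions) raise errors rather than returning NaN.

## Limitations

* Learning rates and per-task reward settings are reproduced from a
  fresh grid search, not from the original supplementary material
  (unavailable); absolute numbers can differ from the reference within
  the stochastic spread of the protocol.
* Run-to-run variance at `N_E = 30` is substantial; means over small
  replicate counts carry sampling error of a few percentage points.
* No spiking or continuous-time dynamics, no structural or inhibitory
  plasticity, no eligibility traces / delayed rewards — the model is a
  single-step-reward binary network by design.
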