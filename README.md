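# rmsorn

A simulator for **reward-modulated self-organizing recurrent networks**
(RM-SORN): two-layer networks of binary threshold neurons that learn
symbol-sequence tasks through the interaction of three local plasticity
rules — intrinsic plasticity (IP), synaptic normalization (SN) and
reward-modulated spike-timing-dependent plasticity (STDP) — instead of
a supervised readout.  The package is aimed at computational-
neuroscience work on the interplay of homeostatic and reward-driven
plasticity: it provides the network model, the eight benchmark tasks it
is evaluated on, the two-phase training protocol, and the supervised /
static / random comparison networks.

## Model

The recurrent layer holds `N_E` excitatory and `N_E/5` inhibitory
binary units with sparse excitatory connectivity on a fixed eligibility
mask; the readout layer is driven by the excitatory units:

    x(t+1) = Θ(W_EE x(t) − W_EI y(t) + u(t) − T_E)
    y(t+1) = Θ(W_IE x(t) − T_I)
    o      = a(W_OE x − T_O)        a = WTA (several units) or Θ (one unit)

Each step, STDP updates the weights (scaled by a modulation factor `m`
derived from the reward, so that `m > 0` reinforces, `m = 0` suppresses
and `m < 0` inverts the rule), SN rescales each unit's incoming weights
to sum 1, and IP drifts thresholds toward a target firing rate — the
deterministic exploration mechanism that replaces noise.  Modulation
follows either `M0: m = r` or the reward-prediction error
`Mk: m = r − r̄(k)`.  Training runs in two phases of 20,000 steps with a
validation every 100 steps; the recurrent layer is frozen in phase 2.
See `docs/methods.md` for the full model description and parameter
rationale.

## Worked example

Train the reward-modulated network on the counting task (predict the
next letter of random alternations of `abbbbc` / `eddddf`, which
requires counting the repeated letters to get each word's last letter
right):

```python
from rmsorn import train_rmsorn, TrainingProtocol
from rmsorn.defaults import default_params

res = train_rmsorn("counting", n=4, n_excitatory=100,
                   protocol=TrainingProtocol(), seed=1,
                   **default_params("counting"))
print(round(res["performance"], 3), round(res["counting_performance"], 3))
```

This prints

```
1.0 1.0
```

— the overall test performance (fraction of correctly predicted
non-excluded letters; word-initial letters are unpredictable and not
scored) and the counting performance (accuracy on word-final letters
only, the memory-demanding part of the task).  A perfect score on both
means the network learned to count the four b's/d's from its own
recurrent dynamics, with no supervised error signal — only a scalar
reward for correct predictions.

The same interface runs the comparison models
(`train_sorn_baseline`, `make_static_baseline`,
`train_random_baseline`), the sequence generator (`RMSornGenerator`),
the noise-exploration variant (`noise_exploration_mode`) and the
per-task `grid_search`.  Estimators follow scikit-learn conventions
(`fit` / `predict` / `score`, `get_params` / `clone`).

A command-line interface mirrors the library:

```
rmsorn run --task counting --n 8 --size 100 --seed 3 --out results.csv --summary results.json
rmsorn baseline --kind sorn --task counting --n 8 --size 100 --out sorn.csv
rmsorn sweep --grid conditions.yaml --out-prefix sweep
```

Per-run results go to CSV (one row per dataset x network replicate),
mean/sd summaries to JSON; both are byte-stable given the same
configuration and seed.

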