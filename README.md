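# synwm — working memory from synaptic facilitation, in spikes

`synwm` is a self-contained simulator of a spiking working-memory network
in which items are stored in the *state of synapses* rather than in
persistent firing alone.  It is aimed at computational neuroscientists who
want a fast, reproducible, dependency-light implementation of the
facilitation-based working-memory model class: leaky integrate-and-fire
neurons with exponential postsynaptic currents, Tsodyks–Markram short-term
plasticity on all excitatory-to-excitatory synapses, selective populations
embedded in a winner-take-all circuit, and the stimulation protocols that
expose the model's three operating regimes.

## The model in brief

Neurons follow `tau_m dV/dt = -V + R_m(I_exc + I_inh + I_ext)` with
exponential synaptic currents (`tau_s = 2 ms`) and piecewise-constant
Gaussian noise drive redrawn every 1 ms.  Each E→E synapse carries
utilization `u` and resources `x`:

    between spikes:  u -> U with tau_f = 1500 ms,   x -> 1 with tau_d = 200 ms
    at a spike:      u += U(1-u),                    x -= u x

and transmits with efficacy `J_abs · u(t+) · x(t-)`.  Because
`tau_f ≫ tau_d`, a recently active population keeps elevated `u` for
seconds: the memory trace.  Depending on the background drive the loaded
item is silent (reactivatable by a nonspecific pulse), refreshed by
periodic population spikes, or held as elevated asynchronous firing.  The
number of items that can alternate volleys is bounded by
`N_c ≈ T_max / t_s` with `T_max = tau_d ln[(tau_f/tau_d)/(1-U)] ≈ 445 ms`.

Numerically, the linear neuron dynamics advance with their exact
propagator on a 0.05 ms grid, while synapse states update in closed form
only at presynaptic spikes (event-driven).  The inner loop is numba-jitted;
runs are bit-for-bit reproducible given a seed.  See `docs/methods.md` for
the full model account, calibration story and analysis definitions.

## Worked example

```bash
python examples/01_synapse_dynamics.py
```

prints the efficacy of each spike in a 10 Hz train through one
facilitating synapse:

```
spike   t (ms)    u+      x-      J_eff (mV)
    1      100   0.3439   1.0000     0.1548
    2      200   0.4605   0.7914     0.1640
    ...
    9      900   0.7730   0.4631     0.1611
   10     1000   0.7857   0.4572     0.1617

periodic steady state: u+* = 0.8253, x-* = 0.4401, J* = 0.1634 mV
first-spike efficacy:  0.1548 mV
T_max = tau_d*ln[(tau_f/tau_d)/(1-U)] = 445.1 ms
```

The efficacy *rises* over the train (facilitation beats depression at low
rates) and `T_max` bounds how long a population may pause between
refreshing volleys — hence how many items can time-share the circuit.

Network-level: `examples/03_working_memory_regimes.py` loads one item into
a quarter-scale network and prints the spontaneous rate, the volley train
of the loaded population and its delay-period rate increase;
`run_preset("fig2b", seed=1, out_dir="out")` does the same full-scale and
writes the raster, the mean `u`/`x` traces and a summary JSON.

```python
from synwm.presets import run_preset
res, summary = run_preset("fig2b", seed=1, out_dir="out/fig2b")
print(summary["median_ps_spacing_ms"], summary["mean_rate_increase_hz"])
```

A thin CLI wraps the same machinery:

```bash
synwm preset fig4 --seed 1 --out out/fig4      # three items alternating
synwm calibrate --target-rate 0.7              # background bisection
```

## Layout

| path | contents |
|---|---|
| `src/synwm/stp.py` | plasticity closed forms, efficacy variants, PSP/alpha calibration |
| `src/synwm/neuron.py` | LIF + exponential-current exact propagator, noise |
| `src/synwm/network.py` | populations, fixed-in-degree wiring, weight classes |
| `src/synwm/protocols.py` | stimulation epochs compiled to per-neuron drives |
| `src/synwm/engine.py` | time-driven loop with event-driven plasticity (numba) |
| `src/synwm/analysis.py` | rates, population-spike detection, capacity counting |
| `src/synwm/config.py` | validated YAML bundles, provenance tags, fixture scaling |
| `src/synwm/calibrate.py` | background-drive bisection |
| `src/synwm/presets.py` | figure-style experiments (fig2a…fig5, capacity) |
| `src/synwm/cli.py` | `synwm simulate / preset / analyze / calibrate` |
| `examples/` | narrative scripts, one per capability |
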