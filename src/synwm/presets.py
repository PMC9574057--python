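"""Experiment presets: the model's canonical stimulation protocols.

Each preset bundles a network configuration, an operating regime
(background level) and a stimulation timeline:

* ``fig2a`` - spontaneous regime; one item loaded, memory stays silent
  until nonspecific readout pulses reactivate it.
* ``fig2b`` - synchronous regime; one item loaded, autonomous periodic
  population spikes until the background is stepped back down at 5.2 s.
* ``fig2c`` - asynchronous regime; one item loaded, elevated asynchronous
  activity until the background is stepped back down.
* ``fig3a`` - spontaneous regime; two items, periodic readout (300 ms
  period) and a distractor noise burst on 15% of the excitatory neurons.
* ``fig3b`` - synchronous regime; two items, distractor noise burst.
* ``fig4``  - synchronous regime; three items loaded at 3000, 6000 and
  9000 ms, alternating population spikes.
* ``fig5``  - as ``fig3b`` with overlapping selective populations.
* ``capacity4`` / ``capacity5`` - four (five) items with the facilitation
  time constant raised to 2000 (3000) ms.
* ``capacity4_break`` - four items at the default facilitation time
  constant, demonstrating the loss of synchrony beyond three items.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .analysis import (
    count_held_items,
    detect_population_spikes,
    firing_rate_difference,
    median_ps_spacing,
    population_rate,
    tmax_estimate,
    capacity_estimate,
)
from .config import ConfigBundle, default_config
from .engine import SimParams, prepare_network, run_simulation
from .network import build_network
from .protocols import Epoch, ProtocolSpec

logger = logging.getLogger("synwm")

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "build_protocol",
           "run_preset", "PresetSanityError"]

LOAD_DURATION = 350.0       # ms, item-loading epoch length
READOUT_DURATION = 100.0    # ms, nonspecific readout pulse length
READOUT_PERIOD = 300.0      # ms, period of the readout train
SETTLE = 3000.0             # ms of background before the first load


class PresetSanityError(RuntimeError):
    """Raised when a preset run fails its regime sanity check."""


@dataclass(frozen=True)
class ExperimentPreset:
    """A named, fully self-contained experiment."""

    name: str
    regime: str                      # background level: A, B or C
    loads: tuple                     # (population, t_start) pairs
    T: float
    bg_decrease_at: float | None = None
    readout_from: float | None = None
    readout_until: float | None = None
    noise_at: float | None = None    # distractor on 15% of E
    tau_f: float | None = None       # facilitation override (ms)
    overlap: bool = False
    description: str = ""

    def config(self, base: ConfigBundle | None = None) -> ConfigBundle:
        bundle = base if base is not None else default_config()
        if self.tau_f is not None:
            bundle = replace(bundle, stp=replace(bundle.stp, tau_f=self.tau_f))
        if self.overlap:
            bundle = replace(bundle,
                             network=replace(bundle.network, overlap=True))
        return bundle

    def protocol(self, bundle: ConfigBundle) -> ProtocolSpec:
        return build_protocol(
            bundle, self.regime, self.loads, self.T,
            bg_decrease_at=self.bg_decrease_at,
            readout_from=self.readout_from,
            readout_until=self.readout_until,
            noise_at=self.noise_at,
        )


def build_protocol(
    bundle: ConfigBundle,
    regime: str,
    loads,
    T: float,
    bg_decrease_at: float | None = None,
    readout_from: float | None = None,
    readout_until: float | None = None,
    noise_at: float | None = None,
) -> ProtocolSpec:
    """Assemble the epoch list for one experiment.

    Background drives E at the regime's level (stepping down to the
    spontaneous level at ``bg_decrease_at`` if given) and I at its fixed
    level throughout.  Item loads, readout pulses and the 15%-of-E
    distractor all add Gaussian noise currents on top.
    """
    bg = bundle.background
    sig = bg.sigma(regime)
    epochs = []
    if bg_decrease_at is not None:
        epochs.append(Epoch(0, bg_decrease_at, "excitatory",
                            bg.mu_E(regime), sig, f"background-E-{regime}"))
        epochs.append(Epoch(bg_decrease_at, T, "excitatory",
                            bg.mu_E_A, bg.sigma_AB, "background-E-A"))
    else:
        epochs.append(Epoch(0, T, "excitatory", bg.mu_E(regime), sig,
                            f"background-E-{regime}"))
    epochs.append(Epoch(0, T, "inhibitory", bg.mu_I, sig, "background-I"))
    for pop, t0 in loads:
        epochs.append(Epoch(t0, t0 + LOAD_DURATION, ("population", pop),
                            bg.load_mu, bg.load_sigma, f"load-pop{pop}"))
    if readout_from is not None:
        until = readout_until if readout_until is not None else T
        t = readout_from
        while t + READOUT_DURATION <= until:
            epochs.append(Epoch(t, t + READOUT_DURATION, "excitatory",
                                bg.readout_mu, bg.readout_sigma, "readout"))
            t += READOUT_PERIOD
    if noise_at is not None:
        epochs.append(Epoch(noise_at, noise_at + LOAD_DURATION,
                            ("fraction_exc", 0.15),
                            bg.load_mu, bg.load_sigma, "distractor"))
    return ProtocolSpec(epochs)


PRESETS = {p.name: p for p in [
    ExperimentPreset(
        name="fig2a", regime="A", loads=((0, SETTLE),), T=6000.0,
        readout_from=4600.0, readout_until=5600.0,
        description="silent synaptic memory, reactivated by readout pulses",
    ),
    ExperimentPreset(
        name="fig2b", regime="B", loads=((0, SETTLE),), T=6000.0,
        bg_decrease_at=5200.0,
        description="autonomous periodic population spikes",
    ),
    ExperimentPreset(
        name="fig2c", regime="C", loads=((0, SETTLE),), T=6000.0,
        bg_decrease_at=5200.0,
        description="asynchronous elevated delay activity",
    ),
    ExperimentPreset(
        name="fig3a", regime="A", loads=((0, SETTLE), (1, 3900.0)),
        T=8000.0, readout_from=4500.0, noise_at=6300.0,
        description="two items under periodic readout with a distractor",
    ),
    ExperimentPreset(
        name="fig3b", regime="B", loads=((0, SETTLE), (1, 3900.0)),
        T=8000.0, noise_at=6300.0,
        description="two items alternating autonomously with a distractor",
    ),
    ExperimentPreset(
        name="fig4", regime="B",
        loads=((0, 3000.0), (1, 6000.0), (2, 9000.0)), T=12000.0,
        description="three items alternating population spikes",
    ),
    ExperimentPreset(
        name="fig5", regime="B", loads=((0, SETTLE), (1, 3900.0)),
        T=8000.0, noise_at=6300.0, overlap=True,
        description="two items with overlapping selective populations",
    ),
    ExperimentPreset(
        name="capacity4_break", regime="B",
        loads=((0, 3000.0), (1, 6000.0), (2, 9000.0), (3, 12000.0)),
        T=15000.0,
        description="a fourth item at default facilitation breaks synchrony",
    ),
    ExperimentPreset(
        name="capacity4", regime="B", tau_f=2000.0,
        loads=((0, 3000.0), (1, 6000.0), (2, 9000.0), (3, 12000.0)),
        T=15000.0,
        description="four items held with facilitation slowed to 2 s",
    ),
    ExperimentPreset(
        name="capacity5", regime="B", tau_f=3000.0,
        loads=((0, 3000.0), (1, 6000.0), (2, 9000.0), (3, 12000.0),
               (4, 15000.0)),
        T=18000.0,
        description="five items held with facilitation slowed to 3 s",
    ),
]}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {sorted(PRESETS)}"
        ) from None


def analyze_run(res, popmap, bundle: ConfigBundle, preset: ExperimentPreset):
    """Standard summary of a preset run (JSON-serializable)."""
    det = bundle.analysis.detection_params()
    n_exc = popmap.N_E
    first_load = min(t for _, t in preset.loads)
    last_load_end = max(t for _, t in preset.loads) + LOAD_DURATION
    spont = (max(0.0, first_load - 2000.0), first_load)
    pre = (res.spike_times >= spont[0]) & (res.spike_times < spont[1])
    spont_rate = float(
        ((res.spike_ids < n_exc) & pre).sum() / n_exc
        / ((spont[1] - spont[0]) / 1000.0)
    )
    delay_end = preset.bg_decrease_at or preset.T
    trains, deltas = {}, {}
    for pop, t0 in preset.loads:
        mem = popmap.pop_members[pop]
        tr = detect_population_spikes(
            res.spike_times, res.spike_ids, mem, pop,
            t0 + LOAD_DURATION, preset.T, spont, det,
        )
        trains[pop] = tr
        dr = firing_rate_difference(
            res.spike_times, res.spike_ids, mem, spont,
            (t0 + LOAD_DURATION, delay_end),
        )
        deltas[pop] = dr.mean
    T_max = tmax_estimate(bundle.stp)
    window = (last_load_end + 150.0, preset.T)
    held = count_held_items(list(trains.values()), window, T_max,
                            bundle.analysis.capacity_gap_factor)
    t_s = median_ps_spacing(
        [tr for tr in trains.values()
         if count_held_items([tr], window, T_max,
                             bundle.analysis.capacity_gap_factor)],
        window,
    )
    summary = {
        "preset": preset.name,
        "spontaneous_rate_hz": spont_rate,
        "ps_times_ms": {int(p): tr.times.tolist() for p, tr in trains.items()},
        "ps_participation": {int(p): tr.participation.tolist()
                             for p, tr in trains.items()},
        "mean_rate_increase_hz": {int(p): float(d) for p, d in deltas.items()},
        "held_items": int(held),
        "t_max_ms": float(T_max),
        "median_ps_spacing_ms": float(t_s) if np.isfinite(t_s) else None,
        "capacity_estimate": (float(capacity_estimate(T_max, t_s))
                              if np.isfinite(t_s) and t_s > 0 else None),
        "metadata": res.metadata,
    }
    return summary


def run_preset(
    name: str,
    seed: int,
    out_dir=None,
    base_config: ConfigBundle | None = None,
    make_plots: bool = True,
    sanity_bounds: tuple = (0.02, 8.0),
):
    """Build, simulate and analyze one preset; optionally write artifacts.

    Returns ``(SimulationResult, summary dict)``.  When ``out_dir`` is
    given, writes ``raster.txt`` (time_ms, neuron_id), ``membership.json``,
    ``traces.csv``, ``summary.json`` and raster/trace plots.  Raises
    :class:`PresetSanityError` if the pre-load spontaneous rate of regime
    B/C runs falls outside ``sanity_bounds`` (Hz).
    """
    preset = get_preset(name)
    bundle = preset.config(base_config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    popmap, table = build_network(bundle.network, rng)
    prep = prepare_network(popmap, table, bundle.neuron_E, bundle.neuron_I,
                           bundle.dt)
    proto = preset.protocol(bundle)
    traced = tuple(sorted({p for p, _ in preset.loads}))
    sim = SimParams(T=preset.T, dt=bundle.dt, seed=seed, traced_pops=traced)
    logger.info("preset %s: %d neurons, %d connections, T=%.0f ms",
                name, popmap.N_E + popmap.N_I, prep.n_connections, preset.T)
    res = run_simulation(prep, None, proto, stp=bundle.stp, sim=sim,
                         variant=bundle.variant)
    summary = analyze_run(res, popmap, bundle, preset)
    if preset.regime in ("B", "C"):
        lo, hi = sanity_bounds
        r = summary["spontaneous_rate_hz"]
        if not lo <= r <= hi:
            raise PresetSanityError(
                f"preset {name}: spontaneous rate {r:.2f} Hz outside "
                f"[{lo}, {hi}] Hz - recalibrate the background levels"
            )
    if out_dir is not None:
        _write_outputs(Path(out_dir), res, popmap, summary, make_plots)
    return res, summary


def _write_outputs(out: Path, res, popmap, summary, make_plots: bool):
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "raster.txt",
               np.column_stack([res.spike_times, res.spike_ids]),
               fmt=["%.2f", "%d"], header="time_ms neuron_id")
    with open(out / "membership.json", "w") as fh:
        json.dump(
            {"N_E": int(popmap.N_E), "N_I": int(popmap.N_I),
             "populations": {str(i): m.tolist()
                             for i, m in enumerate(popmap.pop_members)}},
            fh,
        )
    if len(res.trace_times):
        header = "time_ms," + ",".join(
            f"u_pop{p},x_pop{p}" for p in res.traced_pops
        )
        cols = [res.trace_times]
        for i in range(len(res.traced_pops)):
            cols += [res.trace_u[:, i], res.trace_x[:, i]]
        np.savetxt(out / "traces.csv", np.column_stack(cols),
                   delimiter=",", header=header, comments="")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if make_plots:
        _plot(out, res, popmap)


def _plot(out: Path, res, popmap):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        2, 1, figsize=(10, 7), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    shown = []
    for p in res.traced_pops:
        shown.append((p, popmap.pop_members[p][:100]))
    colors = plt.cm.tab10.colors
    for i, (p, mem) in enumerate(shown):
        sel = np.isin(res.spike_ids, mem)
        remap = {int(n): j for j, n in enumerate(mem)}
        ys = [remap[int(n)] + i * 110 for n in res.spike_ids[sel]]
        axes[0].plot(res.spike_times[sel], ys, ".", ms=1.5,
                     color=colors[i % 10], label=f"population {p}")
    axes[0].set_ylabel("neuron (subset per population)")
    axes[0].legend(loc="upper right", fontsize=8)
    for i, p in enumerate(res.traced_pops):
        axes[1].plot(res.trace_times, res.trace_u[:, i], "-",
                     color=colors[i % 10], label=f"u pop {p}")
        axes[1].plot(res.trace_times, res.trace_x[:, i], "--",
                     color=colors[i % 10], alpha=0.6, label=f"x pop {p}")
    axes[1].set_ylim(0, 1.05)
    axes[1].set_xlabel("time (ms)")
    axes[1].set_ylabel("mean STP variables")
    axes[1].legend(loc="upper right", fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(out / "raster_traces.png", dpi=120)
    plt.close(fig)
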