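"""Quantitative readouts of simulation output.

Population rates, detection of population spikes (brief synchronized
volleys of a selective population), per-neuron firing-rate differences
between the delay period and the spontaneous state, capacity counting over
multi-item runs, and the analytic capacity estimate from the plasticity
time constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSpikeTrain",
    "RateDiffResult",
    "PSDetectionParams",
    "population_rate",
    "detect_population_spikes",
    "firing_rate_difference",
    "count_held_items",
    "median_ps_spacing",
    "tmax_estimate",
    "capacity_estimate",
]


@dataclass
class PopulationSpikeTrain:
    """Times of synchronized volleys of one population."""

    population: int
    times: np.ndarray          # ms, strictly increasing (peak of each volley)
    participation: np.ndarray  # fraction of members spiking in each volley


@dataclass
class RateDiffResult:
    """Per-neuron delay-minus-spontaneous rate differences (Hz)."""

    delta_r: np.ndarray
    neuron_ids: np.ndarray
    spontaneous_interval: tuple
    delay_interval: tuple

    @property
    def mean(self) -> float:
        return float(self.delta_r.mean())


@dataclass(frozen=True)
class PSDetectionParams:
    """Criterion for a population spike.

    A PS is a contiguous excursion of the binned population rate above
    ``threshold_factor`` times the baseline mean rate (absolute floor
    ``floor_hz`` when the baseline is silent); excursions closer than
    ``min_separation_ms`` are merged into one event at the higher peak.
    """

    bin_ms: float = 5.0
    threshold_factor: float = 10.0
    min_separation_ms: float = 50.0
    floor_hz: float = 10.0


def population_rate(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    members: np.ndarray,
    t_start: float,
    t_end: float,
    bin_ms: float,
):
    """Binned per-neuron firing rate of a population, in Hz.

    Returns ``(bin_centers_ms, rate_hz)`` where each bin's value is the
    population spike count divided by (bin width x population size).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty population")
    sel = np.isin(spike_ids, members)
    t = spike_times[sel]
    edges = np.arange(t_start, t_end + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (bin_ms * 1e-3) / members.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def detect_population_spikes(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    members: np.ndarray,
    population: int,
    t_start: float,
    t_end: float,
    baseline_window: tuple,
    params: PSDetectionParams = PSDetectionParams(),
) -> PopulationSpikeTrain:
    """Find population spikes of one population in ``[t_start, t_end)``.

    The threshold is ``threshold_factor`` times the population's mean rate
    over ``baseline_window`` (a quiet reference interval), or ``floor_hz``
    if the baseline is zero.  Each super-threshold excursion is reported at
    the time of its peak bin; its participation is the fraction of members
    firing at least once during the excursion.
    """
    members = np.asarray(members)
    b0, b1 = baseline_window
    _, base_rate = population_rate(
        spike_times, spike_ids, members, b0, b1, params.bin_ms
    )
    baseline = float(base_rate.mean())
    thresh = max(params.threshold_factor * baseline, params.floor_hz)
    centers, rate = population_rate(
        spike_times, spike_ids, members, t_start, t_end, params.bin_ms
    )
    above = rate > thresh
    if not above.any():
        return PopulationSpikeTrain(population, np.empty(0), np.empty(0))
    # contiguous excursions
    d = np.diff(above.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    events = []  # (peak_time, peak_rate, t_lo, t_hi)
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(rate[s:e]))
        events.append((centers[k], rate[k],
                       centers[s] - params.bin_ms / 2,
                       centers[e - 1] + params.bin_ms / 2))
    # merge events closer than min_separation_ms, keeping the higher peak
    merged = [events[0]]
    for ev in events[1:]:
        if ev[0] - merged[-1][0] < params.min_separation_ms:
            prev = merged[-1]
            best = ev if ev[1] > prev[1] else prev
            merged[-1] = (best[0], best[1], prev[2], ev[3])
        else:
            merged.append(ev)
    times = np.array([m[0] for m in merged])
    part = np.empty(len(merged))
    member_set = members
    for i, m in enumerate(merged):
        in_win = (spike_times >= m[2]) & (spike_times <= m[3])
        firing = np.intersect1d(np.unique(spike_ids[in_win]), member_set)
        part[i] = len(firing) / len(member_set)
    return PopulationSpikeTrain(population, times, part)


def firing_rate_difference(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    members: np.ndarray,
    spontaneous_interval: tuple,
    delay_interval: tuple,
) -> RateDiffResult:
    """Per-neuron spike-count rate difference between two windows (Hz).

    For each population member, ``delta_r = N_delay/dt_delay -
    N_spont/dt_spont`` with counts taken in the respective windows.
    """
    members = np.asarray(members)
    s0, s1 = spontaneous_interval
    d0, d1 = delay_interval
    if not (s1 > s0 and d1 > d0):
        raise ValueError("both intervals must have positive length")
    sel = np.isin(spike_ids, members)
    t, ids = spike_times[sel], spike_ids[sel]
    pos = {int(nid): i for i, nid in enumerate(members)}
    idx = np.array([pos[int(i)] for i in ids], dtype=np.int64) \
        if len(ids) else np.empty(0, dtype=np.int64)
    n_s = np.zeros(len(members))
    n_d = np.zeros(len(members))
    in_s = (t >= s0) & (t < s1)
    in_d = (t >= d0) & (t < d1)
    np.add.at(n_s, idx[in_s], 1)
    np.add.at(n_d, idx[in_d], 1)
    delta = n_d / ((d1 - d0) * 1e-3) - n_s / ((s1 - s0) * 1e-3)
    return RateDiffResult(
        delta_r=delta, neuron_ids=members,
        spontaneous_interval=(s0, s1), delay_interval=(d0, d1),
    )


def count_held_items(
    ps_trains: list,
    window: tuple,
    T_max: float,
    gap_factor: float = 2.0,
) -> int:
    """Number of loaded items still alternating population spikes.

    A population counts as held when, over ``window``, its PS train has no
    gap (including the window edges) longer than ``gap_factor * T_max``:
    beyond that its facilitation has decayed past the point where a volley
    can recur, which is the operational meaning of losing synchrony.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("empty capacity window")
    max_gap = gap_factor * T_max
    held = 0
    for train in ps_trains:
        t = train.times[(train.times >= w0) & (train.times <= w1)]
        if len(t) == 0:
            continue
        gaps = np.diff(np.concatenate([[w0], t, [w1]]))
        if gaps.max() <= max_gap:
            held += 1
    return held


def median_ps_spacing(ps_trains: list, window: tuple) -> float:
    """Median spacing between consecutive population spikes of any train.

    PS times of all (held) populations are pooled and sorted; with k items
    alternating every t_s, consecutive pooled events are ~t_s apart.
    Returns NaN with fewer than two events.
    """
    w0, w1 = window
    pooled = np.sort(np.concatenate(
        [tr.times[(tr.times >= w0) & (tr.times <= w1)] for tr in ps_trains]
    )) if ps_trains else np.empty(0)
    if len(pooled) < 2:
        return float("nan")
    return float(np.median(np.diff(pooled)))


def tmax_estimate(params) -> float:
    """Maximal limit-cycle period of the facilitation-driven reactivation.

    ``T_max = tau_d * ln[(tau_f/tau_d) / (1 - U)]`` (ms): the longest
    interval between successive population spikes for which the synaptic
    variables still return to values able to trigger the next volley.
    Requires a facilitation-dominated parameter set,
    ``tau_f / (tau_d (1-U)) > 1``.
    """
    arg = (params.tau_f / params.tau_d) / (1.0 - params.U)
    if arg <= 1.0:
        raise ValueError(
            f"no limit cycle: tau_f/(tau_d(1-U)) = {arg:.4f} <= 1"
        )
    return params.tau_d * math.log(arg)


def capacity_estimate(T_max: float, t_s: float) -> float:
    """Analytic working-memory capacity: N_c = T_max / t_s.

    ``t_s`` is the observed spacing between successive population spikes
    (any population); at capacity the alternation cycle of N_c items fills
    the maximal period.
    """
    if t_s <= 0:
        raise ValueError("t_s must be positive")
    return T_max / t_s
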