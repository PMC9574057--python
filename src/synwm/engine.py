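"""Time-driven network simulation with event-driven synaptic plasticity.

The engine advances the whole network on a fixed grid (default
dt = 0.05 ms) using the exact propagator of the linear LIF + exponential
current dynamics, while facilitation/depression variables of the plastic
synapses are updated in closed form only at presynaptic spikes.  Spikes are
delivered after their per-synapse delay as jumps of the postsynaptic
current, scaled so that efficacies (in mV) equal the peak PSP they evoke in
a quiescent neuron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .network import ConnectionTable, PopulationMap
from .neuron import NeuronParams, make_propagator
from .protocols import CompiledProtocol, ProtocolSpec, compile_protocol
from .stp import EfficacyVariant, STPParams, alpha_factor

__all__ = [
    "SimParams",
    "SimulationResult",
    "PreparedNetwork",
    "prepare_network",
    "run_simulation",
    "sample_stp_average",
]


@dataclass(frozen=True)
class SimParams:
    """Grid, duration, seed and recording options.

    ``dt`` must divide the 1 ms noise interval evenly.  ``traced_pops``
    selects the selective populations whose outbound plastic connections are
    averaged into (u, x) traces every ``stp_trace_period`` ms; at most
    ``trace_max_connections`` connections per population are averaged (a
    seeded subsample when there are more).
    """

    T: float
    dt: float = 0.05
    seed: int = 0
    record_raster: bool = True
    stp_trace_period: float = 10.0
    traced_pops: tuple = ()
    trace_max_connections: int = 20000
    max_mean_rate_hz: float = 80.0  # sizing of the spike record

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T < 0:
            raise ValueError("dt must be positive and T non-negative")
        n = 1.0 / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"dt = {self.dt} must divide the 1 ms noise interval evenly"
            )

    @property
    def steps_per_ms(self) -> int:
        return round(1.0 / self.dt)

    @property
    def n_steps(self) -> int:
        return round(self.T / self.dt)


@dataclass
class SimulationResult:
    """Raster, STP traces, protocol record and final synapse state."""

    spike_times: np.ndarray     # ms, multiples of dt
    spike_ids: np.ndarray
    trace_times: np.ndarray     # ms
    trace_u: np.ndarray         # (n_samples, n_traced)
    trace_x: np.ndarray
    traced_pops: tuple
    applied_protocol: list
    metadata: dict
    stp_u: np.ndarray           # final per-connection state (CSR order)
    stp_x: np.ndarray
    stp_t_last: np.ndarray
    conn_order: np.ndarray      # permutation: table row -> CSR row

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class PreparedNetwork:
    """Connectivity compiled to the engine's internal layout.

    Sorting 10^7-scale connection tables into CSR order and converting
    efficacies to current jumps costs more than a short simulation, so it is
    done once here and reused across runs (the per-synapse plasticity state
    is re-initialized on every run).  Tied to the (neuron params, dt) used
    to build it.
    """

    popmap: PopulationMap
    neuron_E: NeuronParams
    neuron_I: NeuronParams
    dt: float
    order: np.ndarray          # table row -> CSR row permutation
    indptr: np.ndarray
    conn_target: np.ndarray
    delay_steps: np.ndarray
    conn_jump: np.ndarray
    conn_plastic: np.ndarray
    src_sorted: np.ndarray
    n_connections: int


def prepare_network(
    popmap: PopulationMap,
    table: ConnectionTable,
    neuron_E: NeuronParams,
    neuron_I: NeuronParams,
    dt: float = 0.05,
) -> PreparedNetwork:
    """Sort the connection table by source and precompute current jumps.

    The jump of a static synapse is ``alpha * J / tau_syn`` (with ``alpha``
    the mV-to-current factor of the *target* class); plastic rows store the
    same quantity for ``J_abs``, modulated by ``u * x`` at each emission.
    Delays are rounded up to the grid, minimum one step.
    """
    N = popmap.N_E + popmap.N_I
    n_exc = popmap.N_E
    order = np.argsort(table.source, kind="stable").astype(np.int64)
    src_sorted = table.source[order]
    indptr = np.zeros(N + 1, dtype=np.int64)
    np.add.at(indptr, src_sorted.astype(np.int64) + 1, 1)
    indptr = np.cumsum(indptr)
    conn_target = table.target[order].astype(np.int32)
    delay_steps = np.ceil(table.delay[order] / dt - 1e-9).astype(np.int32)
    delay_steps = np.maximum(delay_steps, 1)
    conn_plastic = table.plastic[order]

    alpha_E = alpha_factor(neuron_E, neuron_E.tau_exc)
    alpha_I = alpha_factor(neuron_I, neuron_I.tau_exc)
    tgt_is_E = conn_target < n_exc
    w = table.weight[order]
    src_is_E = src_sorted < n_exc
    tau_for = np.where(
        src_is_E,
        np.where(tgt_is_E, neuron_E.tau_exc, neuron_I.tau_exc),
        np.where(tgt_is_E, neuron_E.tau_inh, neuron_I.tau_inh),
    )
    alpha = np.where(tgt_is_E, alpha_E, alpha_I)
    conn_jump = alpha * w / tau_for
    return PreparedNetwork(
        popmap=popmap, neuron_E=neuron_E, neuron_I=neuron_I, dt=dt,
        order=order, indptr=indptr, conn_target=conn_target,
        delay_steps=delay_steps, conn_jump=conn_jump,
        conn_plastic=conn_plastic, src_sorted=src_sorted,
        n_connections=len(w),
    )


def _derive_seeds(seed: int):
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2)
    kernel_seed = int(state[0] % (2 ** 31))
    init_rng = np.random.Generator(np.random.PCG64(state[1]))
    return kernel_seed, init_rng


def run_simulation(
    net,
    table,
    proto,
    neuron_E: NeuronParams = None,
    neuron_I: NeuronParams = None,
    stp: STPParams = STPParams(),
    sim: SimParams = None,
    variant: EfficacyVariant = EfficacyVariant.POST_U,
) -> SimulationResult:
    """Simulate the network under a stimulation protocol.

    Parameters
    ----------
    net : PreparedNetwork or PopulationMap
        Either a network already compiled with :func:`prepare_network`
        (``table``, ``neuron_E`` and ``neuron_I`` may then be None), or a
        population map accompanied by a ``ConnectionTable``.
    proto : ProtocolSpec or CompiledProtocol
        Stimulation timeline; a ``ProtocolSpec`` is compiled against the
        population map with a seed derived from ``sim.seed``.

    Runs are bit-for-bit reproducible for identical inputs and seed.
    Raises ``FloatingPointError`` if the state goes non-finite and
    ``RuntimeError`` if the spike record overflows its sizing.
    """
    if isinstance(net, PreparedNetwork):
        prep = net
        if prep.dt != sim.dt:
            raise ValueError(
                f"network prepared for dt={prep.dt}, simulation uses dt={sim.dt}"
            )
    else:
        prep = prepare_network(net, table, neuron_E, neuron_I, sim.dt)
    popmap = prep.popmap
    neuron_E, neuron_I = prep.neuron_E, prep.neuron_I
    N = popmap.N_E + popmap.N_I
    n_exc = popmap.N_E
    kernel_seed, init_rng = _derive_seeds(sim.seed)

    if isinstance(proto, ProtocolSpec):
        proto = compile_protocol(proto, popmap, init_rng, t_total=sim.T)
    elif not isinstance(proto, CompiledProtocol):
        raise TypeError("proto must be a ProtocolSpec or CompiledProtocol")

    # per-neuron propagator coefficients (two classes)
    prop_E = make_propagator(neuron_E, sim.dt)
    prop_I = make_propagator(neuron_I, sim.dt)
    if neuron_E.V_th != neuron_I.V_th or neuron_E.V_reset != neuron_I.V_reset \
            or neuron_E.t_ref != neuron_I.t_ref:
        raise ValueError(
            "engine assumes shared V_th, V_reset and t_ref across classes"
        )

    def percls(a, b):
        out = np.empty(N)
        out[:n_exc] = a
        out[n_exc:] = b
        return out

    pV = percls(prop_E.pV, prop_I.pV)
    pVe = percls(prop_E.pVe, prop_I.pVe)
    pVi = percls(prop_E.pVi, prop_I.pVi)
    pVx = percls(prop_E.pVx, prop_I.pVx)
    dec_e = percls(prop_E.decay_exc, prop_I.decay_exc)
    dec_i = percls(prop_E.decay_inh, prop_I.decay_inh)
    ref_steps = round(neuron_E.t_ref / sim.dt)

    indptr = prep.indptr
    conn_target = prep.conn_target
    delay_steps = prep.delay_steps
    conn_jump = prep.conn_jump
    conn_plastic = prep.conn_plastic
    src_sorted = prep.src_sorted

    # STP state (CSR order; static rows carried but untouched)
    n_conn = prep.n_connections
    u = np.full(n_conn, stp.U)
    x = np.ones(n_conn)
    t_last = np.zeros(n_conn)

    # initial membrane potentials uniform in [0, V_th)
    V0 = init_rng.uniform(0.0, neuron_E.V_th, size=N)

    # noise segments
    seg_bounds_ms = proto.bounds.astype(np.int64)
    seg_mu = np.ascontiguousarray(proto.mu)
    seg_sigma = np.ascontiguousarray(proto.sigma)

    # spike record sizing
    cap = max(1000, int(N * (sim.T / 1000.0) * sim.max_mean_rate_hz))
    spikes_step = np.empty(cap, dtype=np.int64)
    spikes_id = np.empty(cap, dtype=np.int32)

    # STP trace subsets
    trace_stride = (
        round(sim.stp_trace_period / sim.dt) if sim.traced_pops else 0
    )
    trace_lists = []
    for p in sim.traced_pops:
        members = np.zeros(N, dtype=bool)
        members[popmap.pop_members[p]] = True
        idx = np.nonzero(conn_plastic & members[src_sorted])[0]
        if len(idx) > sim.trace_max_connections:
            idx = np.sort(init_rng.choice(idx, size=sim.trace_max_connections,
                                          replace=False))
        trace_lists.append(idx.astype(np.int64))
    trace_indptr = np.zeros(len(trace_lists) + 1, dtype=np.int64)
    for i, idx in enumerate(trace_lists):
        trace_indptr[i + 1] = trace_indptr[i] + len(idx)
    trace_conn = (np.concatenate(trace_lists).astype(np.int64)
                  if trace_lists else np.empty(0, dtype=np.int64))
    n_samples = sim.n_steps // trace_stride if trace_stride else 0
    trace_u = np.full((n_samples, len(trace_lists)), np.nan)
    trace_x = np.full((n_samples, len(trace_lists)), np.nan)

    n_spikes, status, err_step, err_neuron = _kernel.run_kernel(
        sim.n_steps, sim.dt, sim.steps_per_ms, n_exc,
        pV, pVe, pVi, pVx, dec_e, dec_i,
        neuron_E.V_th, neuron_E.V_reset, ref_steps,
        V0,
        indptr, conn_target, delay_steps, conn_jump, conn_plastic,
        u, x, t_last, stp.U, stp.tau_f, stp.tau_d,
        variant is EfficacyVariant.POST_U,
        seg_bounds_ms, seg_mu, seg_sigma,
        kernel_seed,
        spikes_step, spikes_id,
        trace_stride, trace_indptr, trace_conn, trace_u, trace_x,
    )
    if status == _kernel.STATUS_NONFINITE:
        raise FloatingPointError(
            f"non-finite membrane potential: neuron {err_neuron} at "
            f"t = {err_step * sim.dt:.3f} ms"
        )
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError(
            f"spike record overflow at t = {err_step * sim.dt:.3f} ms; "
            f"increase SimParams.max_mean_rate_hz (current "
            f"{sim.max_mean_rate_hz} Hz)"
        )

    times = spikes_step[:n_spikes] * sim.dt
    ids = spikes_id[:n_spikes].copy()
    if not sim.record_raster:
        times = times[:0]
        ids = ids[:0]
    trace_times = (np.arange(1, n_samples + 1) * trace_stride * sim.dt
                   if trace_stride else np.empty(0))
    return SimulationResult(
        spike_times=times,
        spike_ids=ids,
        trace_times=trace_times,
        trace_u=trace_u,
        trace_x=trace_x,
        traced_pops=tuple(sim.traced_pops),
        applied_protocol=proto.applied,
        metadata={
            "seed": sim.seed, "dt": sim.dt, "T": sim.T,
            "n_neurons": N, "n_connections": n_conn,
            "variant": variant.value, "total_spikes": int(n_spikes),
        },
        stp_u=u, stp_x=x, stp_t_last=t_last,
        conn_order=prep.order,
    )


def sample_stp_average(
    result: SimulationResult,
    table: ConnectionTable,
    popmap: PopulationMap,
    pop_id: int,
    t: float,
    params: STPParams,
):
    """Mean left-limit (u, x) at time ``t`` over the plastic connections
    outbound from a selective population, decayed analytically from each
    connection's last presynaptic spike.  ``t`` must not precede any
    connection's last update."""
    members = np.zeros(popmap.N_E + popmap.N_I, dtype=bool)
    members[popmap.pop_members[pop_id]] = True
    src_sorted = table.source[result.conn_order]
    sel = table.plastic[result.conn_order] & members[src_sorted]
    if not sel.any():
        raise ValueError(f"population {pop_id} has no outbound plastic connections")
    dt_ = t - result.stp_t_last[sel]
    if (dt_ < -1e-9).any():
        raise ValueError("query time precedes last synapse update")
    u_m = params.U + (result.stp_u[sel] - params.U) * np.exp(-dt_ / params.tau_f)
    x_m = 1.0 + (result.stp_x[sel] - 1.0) * np.exp(-dt_ / params.tau_d)
    return float(u_m.mean()), float(x_m.mean())
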