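"""Leaky integrate-and-fire neurons with exponential postsynaptic currents.

The sub-threshold dynamics are linear:

    tau_m dV/dt   = -V + R_m (I_exc + I_inh + I_ext)
    tau_syn dI/dt = -I  (+ delta jumps at spike deliveries)

with the membrane potential measured relative to rest (rest = 0 mV).  The
external drive ``I_ext`` is a piecewise-constant Gaussian noise current,
redrawn every ``dt_ng`` = 1 ms.  Because the system is linear with
piecewise-constant input, it is advanced with its exact propagator (closed
form of the matrix exponential): no integration error accrues on the grid,
whatever the step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "NoiseSpec",
    "Propagator",
    "make_propagator",
    "step_neuron",
    "sample_noise",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and synaptic-current constants.

    Voltages are in mV relative to rest; currents are expressed so that
    ``R_m * I`` is in mV (the default ``R_m = 1`` makes current units "mV").
    """

    tau_m: float = 15.0      # membrane time constant, ms
    R_m: float = 1.0         # membrane resistance (current scale)
    V_th: float = 20.0       # firing threshold, mV above rest
    V_reset: float = 16.0    # post-spike reset, mV above rest
    t_ref: float = 2.0       # absolute refractory period, ms
    tau_exc: float = 2.0     # excitatory synaptic current time constant, ms
    tau_inh: float = 2.0     # inhibitory synaptic current time constant, ms

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_exc", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if not self.V_reset < self.V_th:
            raise ValueError(
                f"V_reset ({self.V_reset}) must be below V_th ({self.V_th})"
            )


@dataclass
class NeuronState:
    """Dynamic variables of one neuron."""

    V: float = 0.0
    I_exc: float = 0.0
    I_inh: float = 0.0
    refractory_until: float = -np.inf


@dataclass(frozen=True)
class NoiseSpec:
    """Piecewise-constant Gaussian current: mu + sigma*G_k on 1 ms intervals."""

    mu: float
    sigma: float
    dt_ng: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.dt_ng <= 0:
            raise ValueError(f"dt_ng must be positive, got {self.dt_ng}")


def _coupling(tau_m: float, tau_syn: float, R_m: float, dt: float) -> float:
    """V <- I coupling coefficient of the exact propagator over dt."""
    if math.isclose(tau_m, tau_syn, rel_tol=1e-12):
        # degenerate limit: t e^{-t/tau} response
        return R_m * (dt / tau_m) * math.exp(-dt / tau_m)
    return (
        R_m * tau_syn / (tau_syn - tau_m)
        * (math.exp(-dt / tau_syn) - math.exp(-dt / tau_m))
    )


@dataclass(frozen=True)
class Propagator:
    """Exact one-step update map for (V, I_exc, I_inh) with constant I_ext.

    V' = pV*V + pVe*I_exc + pVi*I_inh + pVx*I_ext
    I' = decay_exc*I_exc (resp. decay_inh*I_inh)
    """

    dt: float
    pV: float
    pVe: float
    pVi: float
    pVx: float
    decay_exc: float
    decay_inh: float


def make_propagator(params: NeuronParams, dt: float) -> Propagator:
    """Build the exact propagator of the LIF + exponential-current system.

    The synaptic currents decay independently with ``exp(-dt/tau_syn)``;
    the membrane integrates them in closed form, and relaxes toward
    ``R_m * I_ext`` with ``exp(-dt/tau_m)`` for the constant external drive.
    ``dt = 0`` yields the identity map.
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    pV = math.exp(-dt / params.tau_m)
    return Propagator(
        dt=dt,
        pV=pV,
        pVe=_coupling(params.tau_m, params.tau_exc, params.R_m, dt),
        pVi=_coupling(params.tau_m, params.tau_inh, params.R_m, dt),
        pVx=params.R_m * (1.0 - pV),
        decay_exc=math.exp(-dt / params.tau_exc),
        decay_inh=math.exp(-dt / params.tau_inh),
    )


def step_neuron(
    state: NeuronState,
    prop: Propagator,
    I_ext: float,
    params: NeuronParams,
    t: float,
):
    """Advance one neuron by one step; detect threshold crossing at the boundary.

    Returns ``(new_state, spiked)``.  While refractory the membrane is
    clamped at ``V_reset`` but the synaptic currents keep evolving.  On a
    spike the membrane is reset and the refractory clock set to
    ``t + dt + t_ref`` (the spike is attributed to the end of the step).
    """
    if not (
        math.isfinite(state.V)
        and math.isfinite(state.I_exc)
        and math.isfinite(state.I_inh)
    ):
        raise FloatingPointError(f"non-finite neuron state at t={t}: {state}")
    t_end = t + prop.dt
    refractory = t_end <= state.refractory_until
    if refractory:
        V = state.V
    else:
        V = (
            prop.pV * state.V
            + prop.pVe * state.I_exc
            + prop.pVi * state.I_inh
            + prop.pVx * I_ext
        )
    I_exc = prop.decay_exc * state.I_exc
    I_inh = prop.decay_inh * state.I_inh
    spiked = (not refractory) and V >= params.V_th
    if spiked:
        V = params.V_reset
        refractory_until = t_end + params.t_ref
    else:
        refractory_until = state.refractory_until
    return NeuronState(V=V, I_exc=I_exc, I_inh=I_inh,
                       refractory_until=refractory_until), spiked


def sample_noise(spec: NoiseSpec, n_intervals: int, rng: np.random.Generator):
    """Draw the per-interval values of the piecewise-constant noise current.

    Returns an array of length ``n_intervals`` with i.i.d. values
    ``mu + sigma*G_k``; the current is constant within each ``dt_ng``
    interval regardless of the simulation step.
    """
    if n_intervals < 0:
        raise ValueError("n_intervals must be non-negative")
    return spec.mu + spec.sigma * rng.standard_normal(n_intervals)
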