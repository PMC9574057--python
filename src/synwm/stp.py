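"""Tsodyks-Markram short-term plasticity with exact event-driven updates.

Each excitatory-to-excitatory synapse carries two dimensionless state
variables: the utilization ``u`` (fraction of available resources released
by a spike; a phenomenological stand-in for residual presynaptic calcium)
and the available resources ``x`` (normalized releasable neurotransmitter).
Between presynaptic spikes both relax exponentially toward their baselines
(``u -> U`` with time constant ``tau_f``, ``x -> 1`` with ``tau_d``); at a
spike ``u`` jumps by ``U*(1-u)`` and ``x`` is depleted by ``u*x``.  With
``tau_f > tau_d`` the synapse is facilitation-dominated, which is the regime
this package targets.

Because the inter-spike relaxation is a pair of decoupled linear ODEs, the
state never needs to be integrated on the simulation grid: it is advanced in
closed form from one presynaptic spike to the next.  The functions here are
pure and operate on scalars or numpy arrays alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "STPParams",
    "STPState",
    "EfficacyVariant",
    "stp_decay",
    "stp_spike_update",
    "modulated_efficacy",
    "stp_fixed_point",
    "alpha_factor",
    "psp_peak_time",
]


class EfficacyVariant(Enum):
    """Ordering of the utilization update relative to efficacy modulation.

    POST_U modulates with the utilization already incremented by the
    triggering spike, ``J_abs * u(t+) * x(t-)`` (the facilitation caused by a
    spike acts on that same spike's release).  PRE_U uses the pre-spike value,
    ``J_abs * u(t-) * x(t-)``.  POST_U yields efficacies at least as large as
    PRE_U on any spike train and is the default.
    """

    POST_U = "post_u"
    PRE_U = "pre_u"


@dataclass(frozen=True)
class STPParams:
    """Constants of the facilitation/depression dynamics.

    Parameters
    ----------
    U : float
        Baseline utilization, in (0, 1].
    tau_f : float
        Facilitation (calcium removal) time constant, ms.
    tau_d : float
        Depression (resource recovery) time constant, ms.
    """

    U: float = 0.19
    tau_f: float = 1500.0
    tau_d: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if self.tau_f <= 0.0 or self.tau_d <= 0.0:
            raise ValueError(
                f"time constants must be positive, got tau_f={self.tau_f}, "
                f"tau_d={self.tau_d}"
            )


@dataclass
class STPState:
    """Per-connection dynamic state.

    ``t_last`` is the time (ms) of the last presynaptic spike processed;
    ``u`` and ``x`` hold the post-spike (right-limit) values at ``t_last``.
    """

    u: float
    x: float = 1.0
    t_last: float = 0.0

    @classmethod
    def resting(cls, params: STPParams, t: float = 0.0) -> "STPState":
        """Baseline state (u=U, x=1): the no-spike fixed point."""
        return cls(u=params.U, x=1.0, t_last=t)


def stp_decay(state: STPState, t_now: float, params: STPParams):
    """Relax (u, x) from ``state.t_last`` to ``t_now`` without a spike.

    Returns the left-limit pair ``(u_minus, x_minus)`` at ``t_now``; the
    state itself is not mutated.
    """
    dt = t_now - state.t_last
    if dt < 0:
        raise ValueError(
            f"causality violated: t_now={t_now} < t_last={state.t_last}"
        )
    u_minus = params.U + (state.u - params.U) * math.exp(-dt / params.tau_f)
    x_minus = 1.0 + (state.x - 1.0) * math.exp(-dt / params.tau_d)
    return u_minus, x_minus


def stp_spike_update(u_minus: float, x_minus: float, params: STPParams):
    """Apply the discontinuous jump at a presynaptic spike.

    ``u`` facilitates by ``U*(1-u)`` and ``x`` is depleted by the released
    fraction ``u_plus * x_minus``.  Returns ``(u_plus, x_plus)``.
    """
    u_plus = u_minus + params.U * (1.0 - u_minus)
    x_plus = x_minus - u_plus * x_minus
    return u_plus, x_plus


def modulated_efficacy(
    J_abs: float,
    state: STPState,
    t_spike: float,
    params: STPParams,
    variant: EfficacyVariant = EfficacyVariant.POST_U,
):
    """Efficacy of a spike at ``t_spike`` and the resulting synapse state.

    Returns ``(J_eff, new_state)``.  POST_U: ``J_eff = J_abs * u(t+) * x(t-)``;
    PRE_U: ``J_eff = J_abs * u(t-) * x(t-)``.  In both variants the state
    advances identically (only the reported efficacy differs).
    """
    u_minus, x_minus = stp_decay(state, t_spike, params)
    u_plus, x_plus = stp_spike_update(u_minus, x_minus, params)
    if variant is EfficacyVariant.POST_U:
        J_eff = J_abs * u_plus * x_minus
    else:
        J_eff = J_abs * u_minus * x_minus
    return J_eff, STPState(u=u_plus, x=x_plus, t_last=t_spike)


def stp_fixed_point(params: STPParams, isi: float):
    """Steady state of (u, x) under a periodic presynaptic train.

    For a fixed inter-spike interval the decay+spike cycle is an affine
    contraction, so it has a unique, globally attracting fixed point with a
    closed form.  Returns ``(u_star_plus, x_star_minus)``: the post-spike
    utilization and the pre-spike resources on the limit cycle.
    """
    if isi <= 0:
        raise ValueError(f"isi must be positive, got {isi}")
    U = params.U
    Ef = math.exp(-isi / params.tau_f)
    Ed = math.exp(-isi / params.tau_d)
    # u+ -> decay -> u- = U + (u+ - U) Ef ; spike: u+ = U + (1-U) u-
    u_star = U * (1.0 + (1.0 - U) * (1.0 - Ef)) / (1.0 - (1.0 - U) * Ef)
    # x+ -> recover -> x- = 1 + (x- (1-u*) - 1) Ed at the fixed point
    x_star = (1.0 - Ed) / (1.0 - (1.0 - u_star) * Ed)
    return u_star, x_star


def psp_peak_time(tau_m: float, tau_syn: float) -> float:
    """Time to peak of the PSP evoked by an exponential current pulse (ms)."""
    if tau_m == tau_syn:
        return tau_m
    return (tau_m * tau_syn / (tau_m - tau_syn)) * math.log(tau_m / tau_syn)


def alpha_factor(neuron, tau_syn: float) -> float:
    """Current-per-mV conversion for synaptic efficacies.

    Synaptic efficacies J are expressed as peak PSP amplitudes in mV, while
    the exponential-current synapse injects charge: a spike through a synapse
    of efficacy J makes the postsynaptic current jump by ``alpha * J /
    tau_syn``.  ``alpha`` is fixed by the contract that a single such spike,
    delivered to a neuron at rest, deflect the membrane potential by exactly
    J mV at the peak of the PSP.

    Solving the membrane equation for an exponentially decaying input current
    of initial amplitude ``alpha*J/tau_syn`` gives the peak at
    ``t_peak = tau_m*tau_syn/(tau_m-tau_syn) * ln(tau_m/tau_syn)`` and hence

        alpha = (tau_m - tau_syn) / (R_m * (b^(tau_syn/(tau_m-tau_syn))
                                            - b^(tau_m/(tau_m-tau_syn))))

    with ``b = tau_syn/tau_m``.  The degenerate ``tau_syn == tau_m`` case
    uses the ``t e^{-t/tau}`` limit form (peak ``R_m*alpha/(tau*e)`` at
    ``t = tau``).

    Parameters
    ----------
    neuron : NeuronParams
        Provides ``tau_m`` and ``R_m`` of the postsynaptic cell.
    tau_syn : float
        Synaptic current time constant, ms.
    """
    tau_m = neuron.tau_m
    R_m = neuron.R_m
    if tau_syn <= 0:
        raise ValueError(f"tau_syn must be positive, got {tau_syn}")
    if math.isclose(tau_m, tau_syn, rel_tol=1e-12):
        # I(t) = (alpha J / tau) e^{-t/tau}; V(t) = R alpha J t e^{-t/tau}/tau^2
        # peaks at t=tau with value R alpha J / (tau e)
        return tau_m * math.e / R_m
    b = tau_syn / tau_m
    r = tau_syn / (tau_m - tau_syn)
    peak_per_unit = (b ** r - b ** (r + 1.0)) / (tau_m - tau_syn)
    # V_peak = R_m * (alpha J / tau_syn) * tau_syn/(tau_m-tau_syn) * (b^r - b^(r+1))
    return 1.0 / (R_m * peak_per_unit)
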