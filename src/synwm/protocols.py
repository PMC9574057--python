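"""Stimulation protocols: timelines of piecewise-constant noise-current epochs.

A protocol is an ordered list of epochs; each epoch injects an independent
Gaussian noise current (mean ``mu``, SD ``sigma``, redrawn every 1 ms) into
a target set of neurons for a time window.  Overlapping epochs sum: the
total drive of a neuron on a given 1 ms interval is Gaussian with mean
``sum(mu)`` and variance ``sum(sigma^2)`` over the epochs covering it.

Target selectors: ``"all"``, ``"excitatory"``, ``"inhibitory"``,
``("population", p)`` for selective population ``p``, or
``("fraction_exc", f)`` for a random fraction of the excitatory neurons
(drawn once per epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PopulationMap

__all__ = ["Epoch", "ProtocolSpec", "CompiledProtocol", "compile_protocol"]

DT_NG = 1.0  # noise-generator interval, ms


@dataclass(frozen=True)
class Epoch:
    """One noise-current injection window."""

    t_start: float    # ms
    t_end: float      # ms
    target: object    # selector, see module docstring
    mu: float         # mean current (R_m*I in mV)
    sigma: float      # SD of the per-interval values
    label: str = ""

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"epoch must have t_start < t_end, got [{self.t_start}, {self.t_end})"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered collection of epochs (they may overlap; currents add)."""

    epochs: tuple

    def __init__(self, epochs):
        object.__setattr__(self, "epochs", tuple(epochs))

    @property
    def t_end(self) -> float:
        return max((e.t_end for e in self.epochs), default=0.0)


@dataclass
class CompiledProtocol:
    """Per-neuron (mu, sigma) on homogeneous time segments.

    ``bounds`` is the sorted array of segment boundaries in ms (aligned to
    the 1 ms noise grid); segment ``s`` covers ``[bounds[s], bounds[s+1])``
    and every neuron draws ``mu[s, j] + sigma[s, j] * G`` once per 1 ms
    interval inside it.
    """

    bounds: np.ndarray         # (n_seg+1,) ms
    mu: np.ndarray             # (n_seg, N) float64
    sigma: np.ndarray          # (n_seg, N) float64
    applied: list = field(default_factory=list)  # record of resolved epochs


def _resolve_target(sel, popmap: PopulationMap, rng: np.random.Generator):
    """Neuron-id array for a target selector."""
    N = popmap.N_E + popmap.N_I
    if isinstance(sel, str):
        if sel == "all":
            return np.arange(N)
        if sel == "excitatory":
            return popmap.excitatory
        if sel == "inhibitory":
            return popmap.inhibitory
        raise ValueError(f"unknown target selector {sel!r}")
    kind = sel[0]
    if kind == "population":
        p = int(sel[1])
        if not 0 <= p < popmap.n_pops:
            raise ValueError(
                f"protocol references population {p}, but the network has "
                f"{popmap.n_pops} selective populations"
            )
        return popmap.pop_members[p]
    if kind == "fraction_exc":
        f = float(sel[1])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {f}")
        k = int(round(f * popmap.N_E))
        return np.sort(rng.choice(popmap.N_E, size=k, replace=False))
    raise ValueError(f"unknown target selector {sel!r}")


def compile_protocol(
    spec: ProtocolSpec, popmap: PopulationMap, rng: np.random.Generator,
    t_total: float | None = None,
) -> CompiledProtocol:
    """Flatten overlapping epochs into homogeneous segments.

    Epoch boundaries are snapped to the 1 ms noise grid.  Within a segment
    the total per-neuron drive is Gaussian with summed means and summed
    variances, which is drawn as a single value per interval (equivalent in
    distribution to summing independent per-epoch draws).  Random-fraction
    targets are resolved once per epoch using ``rng``.
    """
    N = popmap.N_E + popmap.N_I
    snapped = []
    for e in spec.epochs:
        t0 = round(e.t_start / DT_NG) * DT_NG
        t1 = round(e.t_end / DT_NG) * DT_NG
        snapped.append((t0, t1, e))
    if t_total is None:
        t_total = max((t1 for _, t1, _ in snapped), default=0.0)
    t_total = float(t_total)
    edges = {0.0, t_total}
    for t0, t1, _ in snapped:
        edges.add(min(t0, t_total))
        edges.add(min(t1, t_total))
    bounds = np.array(sorted(edges))
    n_seg = len(bounds) - 1
    mu = np.zeros((n_seg, N))
    var = np.zeros((n_seg, N))
    applied = []
    for t0, t1, e in snapped:
        ids = _resolve_target(e.target, popmap, rng)
        applied.append({
            "t_start": t0, "t_end": t1, "mu": e.mu, "sigma": e.sigma,
            "label": e.label, "n_targets": int(len(ids)),
            "target": repr(e.target),
        })
        segs = np.nonzero((bounds[:-1] >= t0) & (bounds[:-1] < t1))[0]
        for s in segs:
            mu[s, ids] += e.mu
            var[s, ids] += e.sigma ** 2
    return CompiledProtocol(bounds=bounds, mu=mu, sigma=np.sqrt(var),
                            applied=applied)
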