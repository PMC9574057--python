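"""Structured network construction: populations, connectivity, weights.

The excitatory population is split into ``n_pops`` selective populations
(one per memory item, their mutual connections potentiated by assumed prior
Hebbian learning) plus a non-selective remainder; a separate inhibitory
population provides non-specific global inhibition, which is what turns the
selective populations into competitors (winner-take-all).

Connectivity is fixed-in-degree: every neuron receives exactly
``round(c * N_E)`` excitatory and ``round(c * N_I)`` inhibitory connections,
drawn uniformly from the source class (with replacement when multapses are
allowed).  All excitatory-to-excitatory connections are plastic
(facilitating); connections involving inhibitory neurons are static.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "PopulationMap",
    "ConnectionTable",
    "assign_populations",
    "build_connections",
    "assign_weights",
    "build_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, connectivity and synaptic-efficacy classes of the network.

    Efficacies are peak-PSP amplitudes in mV; inhibitory ones are negative.
    ``frac_potentiated_background`` is the fraction of E->E connections not
    touching any selective population that are nevertheless potentiated,
    emulating memories the model does not track.
    """

    N_E: int = 8000
    N_I: int = 2000
    n_pops: int = 5
    pop_size: int = 800
    overlap: bool = False
    c: float = 0.2
    J_p: float = 0.9            # potentiated E->E, mV (calibrated)
    J_b: float = 0.10           # baseline E->E, mV
    J_IE: float = 0.22          # E->I, mV (calibrated)
    J_EI: float = -0.30         # I->E, mV, inhibitory (calibrated)
    J_II: float = -0.20         # I->I, mV (inhibitory)
    frac_potentiated_background: float = 0.10
    delay_range: tuple = (0.1, 1.0)   # ms, uniform
    allow_multapses: bool = True
    allow_autapses: bool = True
    J_p_overlap_boost: float = 1.05   # J_p multiplier in overlap mode

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("population sizes must be positive")
        if self.n_pops < 0 or self.pop_size < 0:
            raise ValueError("n_pops and pop_size must be non-negative")
        if not self.overlap and self.n_pops * self.pop_size > self.N_E:
            raise ValueError(
                f"n_pops*pop_size = {self.n_pops * self.pop_size} exceeds "
                f"N_E = {self.N_E} without overlap"
            )
        if self.overlap and self.pop_size > self.N_E:
            raise ValueError("pop_size exceeds N_E")
        if not 0.0 <= self.frac_potentiated_background <= 1.0:
            raise ValueError("frac_potentiated_background must be in [0, 1]")
        if not 0.0 < self.c <= 1.0:
            raise ValueError(f"connection probability c must be in (0, 1]")
        lo, hi = self.delay_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"invalid delay_range {self.delay_range}")
        if self.J_EI > 0 or self.J_II > 0:
            raise ValueError("inhibitory efficacies J_EI, J_II must be <= 0")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def indegree_E(self) -> int:
        """Excitatory connections received by every neuron."""
        return round(self.c * self.N_E)

    @property
    def indegree_I(self) -> int:
        """Inhibitory connections received by every neuron."""
        return round(self.c * self.N_I)


@dataclass
class PopulationMap:
    """Membership of neurons: selective populations, non-selective E, I.

    Neurons ``0..N_E-1`` are excitatory, ``N_E..N_E+N_I-1`` inhibitory.
    ``pop_members[p]`` lists the E neurons of selective population ``p``.
    In overlap mode a neuron may appear in several populations.
    """

    N_E: int
    N_I: int
    pop_members: list  # list of np.ndarray of neuron ids
    membership_mask: np.ndarray  # (n_pops, N_E) bool

    @property
    def n_pops(self) -> int:
        return len(self.pop_members)

    @property
    def excitatory(self) -> np.ndarray:
        return np.arange(self.N_E)

    @property
    def inhibitory(self) -> np.ndarray:
        return np.arange(self.N_E, self.N_E + self.N_I)

    @property
    def non_selective(self) -> np.ndarray:
        sel = self.membership_mask.any(axis=0) if self.n_pops else \
            np.zeros(self.N_E, dtype=bool)
        return np.nonzero(~sel)[0]

    def is_excitatory(self, ids: np.ndarray) -> np.ndarray:
        return np.asarray(ids) < self.N_E


@dataclass
class ConnectionTable:
    """Flat list of directed synapses.

    ``plastic`` is True exactly on E->E rows (the facilitating synapses);
    ``weight`` is the absolute efficacy J_abs in mV, negative for
    connections from inhibitory sources.
    """

    source: np.ndarray   # int32
    target: np.ndarray   # int32
    weight: np.ndarray   # float64, mV
    delay: np.ndarray    # float64, ms
    plastic: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.source)


def assign_populations(cfg: NetworkConfig, rng: np.random.Generator) -> PopulationMap:
    """Draw selective-population membership.

    Without overlap the first ``n_pops * pop_size`` excitatory neurons are
    partitioned into contiguous blocks (identity of selective neurons is
    immaterial under the symmetric connectivity).  With overlap each
    population draws ``pop_size`` excitatory neurons uniformly without
    replacement, independently across populations, so a neuron can belong to
    several items.
    """
    mask = np.zeros((cfg.n_pops, cfg.N_E), dtype=bool)
    members = []
    for p in range(cfg.n_pops):
        if cfg.overlap:
            ids = rng.choice(cfg.N_E, size=cfg.pop_size, replace=False)
            ids = np.sort(ids)
        else:
            ids = np.arange(p * cfg.pop_size, (p + 1) * cfg.pop_size)
        mask[p, ids] = True
        members.append(ids.astype(np.int64))
    return PopulationMap(N_E=cfg.N_E, N_I=cfg.N_I, pop_members=members,
                         membership_mask=mask)


def build_connections(
    cfg: NetworkConfig, popmap: PopulationMap, rng: np.random.Generator
) -> ConnectionTable:
    """Draw the fixed-in-degree connectivity and delays; weights via
    :func:`assign_weights`.

    Every neuron receives exactly ``round(c*N_E)`` excitatory and
    ``round(c*N_I)`` inhibitory inputs, sources uniform over the class.
    Multapses (repeated source-target pairs) are independent synapses with
    their own delay and plasticity state.
    """
    N, N_E, N_I = cfg.N, cfg.N_E, cfg.N_I
    kE, kI = cfg.indegree_E, cfg.indegree_I
    if not cfg.allow_multapses:
        avail_E = N_E - (0 if cfg.allow_autapses else 1)
        avail_I = N_I - (0 if cfg.allow_autapses else 1)
        if kE > avail_E or kI > avail_I:
            raise ValueError(
                "required in-degree exceeds available sources without multapses"
            )

    def draw_sources(n_src: int, offset: int, k: int) -> np.ndarray:
        # (N, k) source matrix; row = target neuron
        if cfg.allow_multapses:
            src = rng.integers(0, n_src, size=(N, k)) + offset
            if not cfg.allow_autapses:
                tgt = np.arange(N)[:, None]
                bad = src == tgt
                while bad.any():
                    src[bad] = rng.integers(0, n_src, size=int(bad.sum())) + offset
                    bad = src == np.broadcast_to(tgt, src.shape)
        else:
            src = np.empty((N, k), dtype=np.int64)
            for j in range(N):
                pool = rng.permutation(n_src) + offset
                if not cfg.allow_autapses:
                    pool = pool[pool != j]
                src[j] = pool[:k]
        return src

    src_E = draw_sources(N_E, 0, kE)
    src_I = draw_sources(N_I, N_E, kI)
    targets = np.repeat(np.arange(N, dtype=np.int32), kE + kI)
    sources = np.concatenate([src_E, src_I], axis=1).astype(np.int32).ravel()
    lo, hi = cfg.delay_range
    delays = rng.uniform(lo, hi, size=sources.shape[0])
    plastic = (sources < N_E) & (targets < N_E)
    table = ConnectionTable(
        source=sources,
        target=targets,
        weight=np.zeros(sources.shape[0]),
        delay=delays,
        plastic=plastic,
    )
    return assign_weights(table, popmap, cfg, rng)


def assign_weights(
    table: ConnectionTable,
    popmap: PopulationMap,
    cfg: NetworkConfig,
    rng: np.random.Generator,
) -> ConnectionTable:
    """Fill in absolute efficacies by connection class.

    E->E within a shared selective population: ``J_p`` (times the overlap
    boost when populations may overlap); other E->E pairs touching a
    selective population: ``J_b``; E->E among the remaining (non-selective)
    pairs: ``J_p`` with probability ``frac_potentiated_background`` else
    ``J_b``.  E->I: ``J_IE``; I->E: ``J_EI``; I->I: ``J_II`` (inhibitory
    values negative).
    """
    src, tgt = table.source, table.target
    N_E = cfg.N_E
    w = np.empty(len(table))

    src_E = src < N_E
    tgt_E = tgt < N_E
    ee = src_E & tgt_E
    w[src_E & ~tgt_E] = cfg.J_IE
    w[~src_E & tgt_E] = cfg.J_EI
    w[~src_E & ~tgt_E] = cfg.J_II

    J_p = cfg.J_p * (cfg.J_p_overlap_boost if cfg.overlap else 1.0)
    if popmap.n_pops:
        mask = popmap.membership_mask  # (P, N_E)
        src_sel = mask[:, src[ee]]     # (P, n_ee)
        tgt_sel = mask[:, tgt[ee]]
        shared = (src_sel & tgt_sel).any(axis=0)
        src_any = src_sel.any(axis=0)
        tgt_any = tgt_sel.any(axis=0)
    else:
        n_ee = int(ee.sum())
        shared = np.zeros(n_ee, dtype=bool)
        src_any = tgt_any = shared
    background = ~src_any & ~tgt_any          # neither end selective
    w_ee = np.full(int(ee.sum()), cfg.J_b)
    w_ee[shared] = J_p
    bg_pot = background & (rng.random(background.shape[0])
                           < cfg.frac_potentiated_background)
    w_ee[bg_pot] = J_p
    w[ee] = w_ee
    table.weight = w
    return table


def build_network(cfg: NetworkConfig, rng: np.random.Generator):
    """Convenience: populations + weighted connectivity from one generator."""
    popmap = assign_populations(cfg, rng)
    table = build_connections(cfg, popmap, rng)
    return popmap, table


def save_connections(table: ConnectionTable, path) -> None:
    """Write the realized table as a whitespace-separated columnar file."""
    arr = np.column_stack([
        table.source, table.target, table.weight, table.delay,
        table.plastic.astype(int),
    ])
    np.savetxt(path, arr, fmt=["%d", "%d", "%.6f", "%.6f", "%d"],
               header="source target weight_mV delay_ms plastic")


def load_connections(path) -> ConnectionTable:
    """Read a table written by :func:`save_connections`."""
    arr = np.loadtxt(path, ndmin=2)
    return ConnectionTable(
        source=arr[:, 0].astype(np.int32),
        target=arr[:, 1].astype(np.int32),
        weight=arr[:, 2],
        delay=arr[:, 3],
        plastic=arr[:, 4].astype(bool),
    )
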