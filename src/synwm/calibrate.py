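"""Calibration of the background drive against the printed regime anchors.

The reference model family publishes the coupling structure but not the
background-current levels, so they are found empirically: the excitatory
background mean is bisected until the spontaneous excitatory rate matches a
target (0.7 Hz by default), and the synchronous/asynchronous operating
points are chosen relative to that level.  The shipped defaults in
:class:`synwm.config.BackgroundLevels` are the outcome of this procedure on
the full-size network; the functions here let users redo it after changing
couplings or network size.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import ConfigBundle
from .engine import PreparedNetwork, SimParams, run_simulation
from .protocols import Epoch, ProtocolSpec

logger = logging.getLogger("synwm")

__all__ = ["spontaneous_rate", "calibrate_background_mu"]


def spontaneous_rate(
    prep: PreparedNetwork,
    bundle: ConfigBundle,
    mu_E: float,
    sigma: float,
    T: float = 3000.0,
    seed: int = 0,
    settle: float = 1000.0,
) -> float:
    """Mean excitatory firing rate (Hz) under background drive only.

    The first ``settle`` ms are discarded to let the network relax from its
    random initial state.
    """
    bg = bundle.background
    proto = ProtocolSpec([
        Epoch(0, T, "excitatory", mu_E, sigma, "background-E"),
        Epoch(0, T, "inhibitory", bg.mu_I, sigma, "background-I"),
    ])
    res = run_simulation(
        prep, None, proto, stp=bundle.stp,
        sim=SimParams(T=T, seed=seed), variant=bundle.variant,
    )
    n_exc = prep.popmap.N_E
    m = res.spike_times > settle
    return float(((res.spike_ids < n_exc) & m).sum() / n_exc
                 / ((T - settle) / 1000.0))


def calibrate_background_mu(
    prep: PreparedNetwork,
    bundle: ConfigBundle,
    target_rate: float = 0.7,
    bracket: tuple = (20.5, 22.5),
    sigma: float | None = None,
    iters: int = 6,
    T: float = 3000.0,
    seed: int = 0,
):
    """Bisect the excitatory background mean for a target spontaneous rate.

    Returns ``(mu_E, achieved_rate)``.  The rate is a stochastic, steeply
    increasing function of the mean, so a handful of iterations on a 3 s
    window locates the operating point to within the run-to-run spread.
    """
    if sigma is None:
        sigma = bundle.background.sigma_AB
    lo, hi = bracket
    rate = float("nan")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        rate = spontaneous_rate(prep, bundle, mid, sigma, T=T, seed=seed)
        logger.info("calibrate: mu_E=%.3f -> %.3f Hz", mid, rate)
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), rate
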