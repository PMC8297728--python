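"""Schedule optimization and enhancement maps.

Compares looped and conventional experiments the way the measurements are
compared: each scheme is individually optimized (mixing time for the
conventional experiment; loop count and per-loop mixing jointly for the
looped one) before the fold factor is taken.  All searches are
deterministic grid scans with bracketed scalar refinement; at this
dimensionality gradients buy nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .noesy import conventional_schedule, run_conventional_noesy
from .spin import SpinSystem
from .tocsy import build_liouvillian, run_conventional_tocsy

__all__ = [
    "NoTransferError",
    "optimize_conventional_mixing",
    "optimize_lprosy_schedule",
    "enhancement_map",
]

# search defaults: conventional NOESY mixing capped at 400 ms (the ~100 ms
# practical cap at fast exchange emerges from the optimization itself);
# per-loop mixing grid 5-100 ms in 5 ms steps, refined x10 near the optimum.
CONV_CAP = {"noesy": 0.4, "tocsy": 1.0}
LOOP_TAU_GRID = np.arange(0.005, 0.1001, 0.005)
MAX_LOOPS_DEFAULT = 30


class NoTransferError(RuntimeError):
    """The cross-peak objective is identically zero: nothing to optimize."""


def _conv_amplitude(system, pair, experiment_type, tau, clamp_water=False):
    source, dest = pair
    sched = conventional_schedule([source], tau, clamp_water=clamp_water)
    if experiment_type == "noesy":
        peaks = run_conventional_noesy(system, sched)
    else:
        peaks = run_conventional_tocsy(system, pair, sched)
    return peaks.cross[(source, dest)]


def optimize_conventional_mixing(
    system: SpinSystem,
    pair: tuple[str, str],
    experiment_type: str,
    t_max: float | None = None,
    n_grid: int = 81,
    clamp_water: bool = False,
) -> tuple[float, float]:
    """Mixing time maximizing |cross amplitude|; returns (tau*, amplitude).

    Coarse bracketing grid on [0, t_max] followed by bounded scalar
    refinement between the neighbours of the best grid point.
    """
    if experiment_type not in ("noesy", "tocsy"):
        raise ValueError(f"unknown experiment type {experiment_type!r}")
    if t_max is None:
        t_max = CONV_CAP[experiment_type]
    taus = np.linspace(0.0, t_max, n_grid)
    amps = np.array(
        [_conv_amplitude(system, pair, experiment_type, t, clamp_water) for t in taus]
    )
    mags = np.abs(amps)
    if mags.max() < 1e-15:
        raise NoTransferError(
            f"no {experiment_type} transfer for pair {pair}: flat objective"
        )
    i = int(mags.argmax())
    lo = taus[max(i - 1, 0)]
    hi = taus[min(i + 1, len(taus) - 1)]
    res = minimize_scalar(
        lambda t: -abs(_conv_amplitude(system, pair, experiment_type, t, clamp_water)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    t_star = float(res.x)
    a_star = _conv_amplitude(system, pair, experiment_type, t_star, clamp_water)
    if abs(a_star) < mags[i]:  # refinement must never lose to the grid
        t_star, a_star = float(taus[i]), float(amps[i])
    return t_star, float(a_star)


def _lprosy_setup(system, pair, experiment_type, clamp_water):
    """(generator matrix, per-tau loop-amplitude sweep) for either engine."""
    from .noesy import _labeled_generator, lprosy_labeled_series
    from .spin import build_generator
    from .tocsy import lprosy_state_series

    source = pair[0]
    if experiment_type == "noesy":
        gen = build_generator(system)
        A = _labeled_generator(gen, system, clamp_water)
        i_dest = system.index(pair[1])
        m_src = system.pool(source).m_eq

        def sweep(P, tau, max_loops):
            series = lprosy_labeled_series(P, system, source, tau, max_loops)
            return ((x[i_dest] / m_src) for x in series)

    else:
        A, _ = build_liouvillian(system, pair)

        def sweep(P, tau, max_loops):
            series = lprosy_state_series(P, system, source, tau, max_loops)
            return (x[1] for x in series)

    return A, sweep


def _best_loops(amplitudes) -> tuple[int, float]:
    best_amp, best_l = 0.0, 1
    for l, a in enumerate(amplitudes, start=1):
        if abs(a) > abs(best_amp):
            best_amp, best_l = float(a), l
    return best_l, best_amp


def optimize_lprosy_schedule(
    system: SpinSystem,
    pair: tuple[str, str],
    experiment_type: str,
    max_loops: int = MAX_LOOPS_DEFAULT,
    tau_grid: np.ndarray | None = None,
    clamp_water: bool = False,
) -> tuple[int, float, float]:
    """Joint (loop count, per-loop mixing) search; returns (l1*, tau*, amp).

    For each candidate mixing the per-loop propagator is exponentiated once
    and reused across loop counts, so the joint scan is cheap.  The mixing
    grid is refined tenfold around the coarse optimum.
    """
    if max_loops < 1:
        raise ValueError("max_loops must be >= 1")
    if tau_grid is None:
        tau_grid = LOOP_TAU_GRID
    A, sweep = _lprosy_setup(system, pair, experiment_type, clamp_water)

    def scan(taus):
        best = (1, float(taus[0]), 0.0)
        for tau in taus:
            P = expm(A * tau)
            l, amp = _best_loops(sweep(P, tau, max_loops))
            if abs(amp) > abs(best[2]):
                best = (l, float(tau), amp)
        return best

    l1, tau, amp = scan(tau_grid)
    step = np.median(np.diff(tau_grid)) if len(tau_grid) > 1 else tau_grid[0]
    fine = np.arange(max(tau - step, 1e-4), tau + step + 1e-12, step / 10.0)
    l1f, tauf, ampf = scan(fine)
    if abs(ampf) > abs(amp):
        l1, tau, amp = l1f, tauf, ampf
    if abs(amp) < 1e-15:
        raise NoTransferError(f"no looped {experiment_type} transfer for pair {pair}")
    return l1, tau, float(amp)


def enhancement_map(
    system_template: SpinSystem,
    kex_grid,
    coupling_grid,
    experiment_type: str,
    pair: tuple[str, str],
    max_loops: int = MAX_LOOPS_DEFAULT,
) -> pd.DataFrame:
    """Optimized-enhancement surface over exchange-rate x coupling grids.

    ``coupling_grid`` holds sigma values (s^-1, signed) for NOESY or J
    values (Hz) for TOCSY.  Each cell optimizes both schedules and records
    the fold factor; cells with no transfer propagate as NaN, never as 0.
    Rows are indexed by k_ex, columns by the coupling.
    """
    kex_grid = np.asarray(list(kex_grid), dtype=float)
    coupling_grid = np.asarray(list(coupling_grid), dtype=float)
    if kex_grid.size == 0 or coupling_grid.size == 0:
        raise ValueError("grids must be non-empty")
    out = np.full((kex_grid.size, coupling_grid.size), np.nan)
    for ik, kex in enumerate(kex_grid):
        for ic, c in enumerate(coupling_grid):
            if experiment_type == "noesy":
                sys_kc = system_template.with_rates(kex=kex, sigma=c, pair=pair)
            else:
                sys_kc = system_template.with_rates(kex=kex, j=c, pair=pair)
            try:
                _, a_conv = optimize_conventional_mixing(sys_kc, pair, experiment_type)
                _, _, a_lp = optimize_lprosy_schedule(
                    sys_kc, pair, experiment_type, max_loops=max_loops
                )
            except NoTransferError:
                continue
            if a_conv != 0.0:
                out[ik, ic] = abs(a_lp) / abs(a_conv)
    df = pd.DataFrame(out, index=kex_grid, columns=coupling_grid)
    df.index.name = "kex"
    df.columns.name = "coupling"
    return df
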