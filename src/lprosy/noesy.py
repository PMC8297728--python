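"""NOESY propagation: conventional vs looped-projective (L-PROSY) schedules.

Both experiments are modeled in the longitudinal (Solomon + chemical
exchange) space.  Selective pulses are ideal: they label the targeted
labile pool without perturbing water or the aliphatic pools.  The Ramsey
t1 encoding is amplitude labeling, cos(Omega t1); amplitudes are reported
at the t1 = 0 increment, which is equivalent to comparing integrated peak
amplitudes and keeps lineshapes out of the model.

The labeled magnetization packet L evolves homogeneously, L(t) = exp(A t) L0.
In the looped experiment each loop re-labels the labile source with its
*exchange-replenished* polarization: projection scrambles whatever label
(and lattice-recovered polarization) the projected spin still carries, so
the freshly labellable amplitude after a loop of duration tau is the
magnetization that entered the pool from water since the last labeling,

    fresh = [k_out M_eq / (R1 + k_out)] (1 - exp(-(R1 + k_out) tau)) ,

with k_out the exchange rate to water.  Without exchange (k_out = 0) the
loops beyond the first inject nothing, so looping cannot beat a single
optimized mixing -- the repolarization by solvent exchange is the entire
source of the L-PROSY gain.  Accumulated destination z-magnetization is
preserved between loops and keeps relaxing (no freezing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .spin import LongitudinalGenerator, SpinSystem, build_generator

__all__ = [
    "SequenceSchedule",
    "PeakAmplitudes",
    "UndefinedEnhancementError",
    "propagate_longitudinal",
    "run_conventional_noesy",
    "run_lprosy_noesy",
    "enhancement",
]


class ScheduleError(ValueError):
    """Invalid pulse-sequence schedule."""


class UndefinedEnhancementError(ZeroDivisionError):
    """Conventional amplitude is zero: the fold factor is undefined."""


@dataclass(frozen=True)
class SequenceSchedule:
    """Experiment descriptor.

    ``mixing_time`` is the single mixing of the conventional experiment;
    ``per_loop_mixing``/``loop_count`` describe the looped one.  ``t1_max``
    and ``t1_points`` document the indirect-dimension grid (amplitudes are
    evaluated at the first increment).  ``clamp_water`` holds the water pool
    exactly at equilibrium (infinite-reservoir limit); the default keeps
    finite-pool dynamics.
    """

    experiment: str  # "conventional" | "lprosy"
    selective_targets: tuple[str, ...]
    mixing_time: float = 0.0
    per_loop_mixing: float = 0.0
    loop_count: int = 1
    t1_max: float = 0.0
    t1_points: int = 1
    clamp_water: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in ("conventional", "lprosy"):
            raise ScheduleError(f"unknown experiment {self.experiment!r}")
        if self.loop_count < 1:
            raise ScheduleError("loop_count must be >= 1")
        for t in (self.mixing_time, self.per_loop_mixing, self.t1_max):
            if t < 0:
                raise ScheduleError("all schedule times must be >= 0")
        if not self.selective_targets:
            raise ScheduleError("at least one selective target is required")


@dataclass
class PeakAmplitudes:
    """Diagonal/cross amplitudes as fractions of the source equilibrium.

    ``cross[(s, d)]`` is the labeled magnetization found on pool ``d`` after
    the schedule, per unit equilibrium magnetization of source ``s``.
    """

    diagonal: dict = field(default_factory=dict)
    cross: dict = field(default_factory=dict)
    schedule: SequenceSchedule | None = None

    def cross_amplitude(self, source: str, dest: str) -> float:
        return self.cross[(source, dest)]


def propagate_longitudinal(
    m0: np.ndarray, gen: LongitudinalGenerator, t: float
) -> np.ndarray:
    """Exact affine solution M(t) = M_eq + exp(A t) (M0 - M_eq)."""
    if t < 0:
        raise ScheduleError("propagation time must be >= 0")
    m0 = np.asarray(m0, dtype=float)
    if t == 0:
        return m0.copy()
    return gen.m_eq + expm(gen.matrix * t) @ (m0 - gen.m_eq)


def _labeled_generator(gen: LongitudinalGenerator, system: SpinSystem,
                       clamp_water: bool) -> np.ndarray:
    """Generator for the labeled (homogeneous) packet.

    Clamping the water pool at equilibrium means it can carry no label:
    its row and incoming/outgoing label couplings are removed while loss
    terms already on other pools' diagonals are kept.
    """
    A = gen.matrix.copy()
    if clamp_water:
        for w in system.water_names():
            iw = system.index(w)
            A[iw, :] = 0.0
            A[:, iw] = 0.0
    return A


def _check_targets(system: SpinSystem, schedule: SequenceSchedule) -> None:
    labile = set(system.labile_names())
    for t in schedule.selective_targets:
        system.index(t)
        if t not in labile:
            raise ScheduleError(
                f"selective target {t!r} is not a labile pool; the selective "
                "labeling scheme addresses labile sources only"
            )


def _collect(system: SpinSystem, source: str, L: np.ndarray,
             diagonal: dict, cross: dict) -> None:
    m_src = system.pool(source).m_eq
    i_src = system.index(source)
    diagonal[source] = L[i_src] / m_src
    for name in system.names:
        if name == source:
            continue
        cross[(source, name)] = L[system.index(name)] / m_src


def run_conventional_noesy(
    system: SpinSystem, schedule: SequenceSchedule, sigma_sign: float = 1.0
) -> PeakAmplitudes:
    """Single selective labeling followed by one mixing period.

    Sources are run independently (the model is linear), so amplitudes for
    several selective targets do not interfere.
    """
    if schedule.experiment != "conventional":
        raise ScheduleError("schedule.experiment must be 'conventional'")
    _check_targets(system, schedule)
    gen = build_generator(system, sigma_sign=sigma_sign)
    A = _labeled_generator(gen, system, schedule.clamp_water)
    P = expm(A * schedule.mixing_time)
    diagonal: dict = {}
    cross: dict = {}
    for source in schedule.selective_targets:
        L0 = np.zeros(system.n)
        L0[system.index(source)] = system.pool(source).m_eq
        L = P @ L0
        _collect(system, source, L, diagonal, cross)
    return PeakAmplitudes(diagonal=diagonal, cross=cross, schedule=schedule)


def fresh_label_after(m_eq: float, r1: float, k_out: float, tau: float) -> float:
    """Exchange-replenished labellable magnetization a time tau after projection.

    Solves du/dt = k_out m_eq - (R1 + k_out) u from u(0) = 0: inflow from
    the (near-equilibrium) water reservoir at the detailed-balance rate,
    leakage by relaxation and back-exchange.  Zero when there is no
    exchange: lattice-recovered polarization of a projected spin is
    scrambled and cannot be re-labeled.
    """
    rate = r1 + k_out
    if k_out <= 0 or rate <= 0 or tau <= 0:
        return 0.0
    return (k_out * m_eq / rate) * (1.0 - np.exp(-rate * tau))


def lprosy_labeled_series(
    P: np.ndarray,
    system: SpinSystem,
    source: str,
    tau: float,
    loop_count: int,
):
    """Yield the labeled vector after each of ``loop_count`` loops.

    Loop 1 labels the full equilibrium source magnetization; subsequent
    loops re-label only the exchange-replenished amount
    (:func:`fresh_label_after`).
    """
    i_src = system.index(source)
    p = system.pool(source)
    k_out = sum(system.kex_rate(source, w) for w in system.water_names())
    fresh = fresh_label_after(p.m_eq, p.r1, k_out, tau)
    L = np.zeros(system.n)
    for j in range(loop_count):
        L[i_src] = p.m_eq if j == 0 else fresh
        L = P @ L
        yield L


def run_lprosy_noesy(
    system: SpinSystem, schedule: SequenceSchedule, sigma_sign: float = 1.0
) -> PeakAmplitudes:
    """Looped projective NOESY: l1 cycles of (re-label source, mix).

    Per loop the labile source is freshly labeled with its
    exchange-replenished magnetization; accumulated labeled z-magnetization
    on the other pools persists and keeps relaxing.
    """
    if schedule.experiment != "lprosy":
        raise ScheduleError("schedule.experiment must be 'lprosy'")
    _check_targets(system, schedule)
    gen = build_generator(system, sigma_sign=sigma_sign)
    A = _labeled_generator(gen, system, schedule.clamp_water)
    P = expm(A * schedule.per_loop_mixing)
    diagonal: dict = {}
    cross: dict = {}
    for source in schedule.selective_targets:
        for L in lprosy_labeled_series(
            P, system, source, schedule.per_loop_mixing, schedule.loop_count
        ):
            pass
        _collect(system, source, L, diagonal, cross)
    return PeakAmplitudes(diagonal=diagonal, cross=cross, schedule=schedule)


def enhancement(
    lp: PeakAmplitudes, conv: PeakAmplitudes, peak: tuple[str, str]
) -> float:
    """|looped| / |conventional| fold factor for one cross-peak."""
    try:
        a_lp = lp.cross[peak]
        a_conv = conv.cross[peak]
    except KeyError as exc:
        raise KeyError(f"peak {peak} missing from amplitudes") from exc
    if a_conv == 0.0:
        raise UndefinedEnhancementError(
            f"conventional amplitude for {peak} is zero; enhancement undefined"
        )
    return abs(a_lp) / abs(a_conv)


def conventional_schedule(
    targets, mixing_time: float, clamp_water: bool = False
) -> SequenceSchedule:
    """Convenience constructor for a conventional schedule."""
    return SequenceSchedule(
        experiment="conventional",
        selective_targets=tuple(str(t) for t in np.atleast_1d(targets)),
        mixing_time=float(mixing_time),
        clamp_water=clamp_water,
    )


def lprosy_schedule(
    targets, per_loop_mixing: float, loop_count: int, clamp_water: bool = False
) -> SequenceSchedule:
    """Convenience constructor for a looped schedule."""
    return SequenceSchedule(
        experiment="lprosy",
        selective_targets=tuple(str(t) for t in np.atleast_1d(targets)),
        per_loop_mixing=float(per_loop_mixing),
        loop_count=int(loop_count),
        clamp_water=clamp_water,
    )
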