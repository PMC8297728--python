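"""Liouville-space TOCSY engine for a labile/nonlabile spin pair under exchange.

DIPSI2 is idealized as continuous isotropic mixing, H = 2*pi*J (I1.I2).
Longitudinal transfer between the two z-polarizations then closes on a
four-dimensional operator subspace:

    basis = (I1z, I2z, ZQy, W)

where ZQy is the zero-quantum coherence mediating the transfer (scaled so
the no-exchange, no-relaxation transfer is exactly sin^2(pi J tau)) and W
is the scalar z-magnetization label carried by the water reservoir.  The
identity component is untouched by every term and is not tracked.

Chemical exchange of the labile spin (I1) with water is a stochastic jump:
it destroys I1 coherences and two-spin order at rate k_ex and swaps the
z-polarization with water at the detailed-balance rates.  The well-known
quenching of TOCSY cross-peaks once k_ex exceeds ~J ("exchange averaging of
the J coupling") emerges from this jump model rather than being imposed.

State amplitudes are normalized to the labile spin's equilibrium
magnetization; water's label is carried in the same absolute units so that
exchange conserves magnetization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .noesy import PeakAmplitudes, ScheduleError, SequenceSchedule, fresh_label_after
from .spin import SpinSystem, SpinSystemError

__all__ = [
    "LiouvilleState",
    "build_liouvillian",
    "run_conventional_tocsy",
    "run_lprosy_tocsy",
]

BASIS = ("I1z", "I2z", "ZQy", "W")


@dataclass
class LiouvilleState:
    """Coefficients over the reduced product-operator basis."""

    basis: tuple[str, ...]
    coefficients: np.ndarray

    def __getitem__(self, label: str) -> float:
        return float(self.coefficients[self.basis.index(label)])


def _exchange_rates(system: SpinSystem, labile: str) -> tuple[float, float, float]:
    """(k labile->water, k water->labile, R1_water); zero if no water pool."""
    waters = system.water_names()
    if not waters:
        return 0.0, 0.0, 0.0
    w = waters[0]
    return system.kex_rate(labile, w), system.kex_rate(w, labile), system.pool(w).r1


def build_liouvillian(
    system: SpinSystem,
    pair: tuple[str, str],
    mixing_mode: str = "isotropic",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Superoperator for the (labile, nonlabile) pair over ``BASIS``.

    ``mixing_mode='isotropic'`` applies the coherent J term (spin-lock /
    DIPSI2 limit); ``'free'`` removes it (weak-coupling free evolution does
    not mix z-polarizations).
    """
    if mixing_mode not in ("isotropic", "free"):
        raise ScheduleError(f"unknown mixing mode {mixing_mode!r}")
    labile, nonlabile = pair
    p1, p2 = system.pool(labile), system.pool(nonlabile)
    if p1.kind != "labile":
        raise SpinSystemError(f"pool {labile!r} is not labile")
    J = system.j_coupling(labile, nonlabile)  # raises if undefined
    k1w, kw1, r1w = _exchange_rates(system, labile)
    r2_1 = p1.r2 if p1.r2 is not None else p1.r1
    r2_2 = p2.r2 if p2.r2 is not None else p2.r1
    r_zq = 0.5 * (r2_1 + r2_2)  # zero-quantum coherence relaxation

    w = 2.0 * np.pi * J if mixing_mode == "isotropic" else 0.0
    #            I1z            I2z        ZQy            W
    L = np.array(
        [
            [-(p1.r1 + k1w),   0.0,      -0.5 * w,       kw1],
            [0.0,             -p2.r1,    +0.5 * w,       0.0],
            [w,               -w,        -(r_zq + k1w),  0.0],
            [k1w,              0.0,       0.0,           -(r1w + kw1)],
        ]
    )
    return L, BASIS


def run_conventional_tocsy(
    system: SpinSystem,
    pair: tuple[str, str],
    schedule: SequenceSchedule,
    mixing_mode: str = "isotropic",
) -> PeakAmplitudes:
    """Single isotropic mixing of ``mixing_time`` from a labeled labile spin."""
    if schedule.experiment != "conventional":
        raise ScheduleError("schedule.experiment must be 'conventional'")
    L, basis = build_liouvillian(system, pair, mixing_mode)
    x = np.zeros(4)
    x[0] = 1.0  # unit label on the labile source
    x = expm(L * schedule.mixing_time) @ x
    labile, nonlabile = pair
    return PeakAmplitudes(
        diagonal={labile: x[0]},
        cross={(labile, nonlabile): x[1]},
        schedule=schedule,
    )


def lprosy_state_series(
    P: np.ndarray,
    system: SpinSystem,
    labile: str,
    tau: float,
    loop_count: int,
):
    """Yield the Liouville state after each loop.

    Loop 1 labels the full labile polarization (normalized to 1); later
    loops re-label only the exchange-replenished amount, and every
    projection zeroes the labile zero-quantum coherence.
    """
    k1w, _, _ = _exchange_rates(system, labile)
    fresh = fresh_label_after(1.0, system.pool(labile).r1, k1w, tau)
    x = np.zeros(4)
    for j in range(loop_count):
        x[0] = 1.0 if j == 0 else fresh
        x[2] = 0.0  # projection destroys labile coherence
        x = P @ x
        yield x


def run_lprosy_tocsy(
    system: SpinSystem,
    pair: tuple[str, str],
    schedule: SequenceSchedule,
    mixing_mode: str = "isotropic",
) -> PeakAmplitudes:
    """Looped projective TOCSY.

    Per loop: the labile spin is freshly labeled with the z-polarization
    replenished by exchange with water since the previous projection, its
    coherences are projected away, a short isotropic mixing runs, and the
    destination z accumulates.
    """
    if schedule.experiment != "lprosy":
        raise ScheduleError("schedule.experiment must be 'lprosy'")
    L, basis = build_liouvillian(system, pair, mixing_mode)
    P = expm(L * schedule.per_loop_mixing)
    for x in lprosy_state_series(
        P, system, pair[0], schedule.per_loop_mixing, schedule.loop_count
    ):
        pass
    labile, nonlabile = pair
    return PeakAmplitudes(
        diagonal={labile: x[0]},
        cross={(labile, nonlabile): x[1]},
        schedule=schedule,
    )
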