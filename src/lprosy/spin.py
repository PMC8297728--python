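"""Exchange-coupled longitudinal spin systems.

The physical model is a set of magnetization pools (hydroxyl/amide "labile"
protons, the bulk water resonance, and non-exchanging aliphatic protons)
coupled by

* longitudinal auto-relaxation (rate ``R1``, s^-1),
* dipolar cross-relaxation between proton pools (signed rate ``sigma``, s^-1),
* chemical exchange between labile protons and water (first-order rates
  ``k_ex``, s^-1, obeying detailed balance with the pool populations), and
* scalar couplings ``J`` (Hz), used by the TOCSY engine only.

Longitudinal evolution is the affine Bloch-McConnell/Solomon system

    dM/dt = A (M - M_eq)

where ``A`` carries -R1 and exchange losses on the diagonal, +sigma and
exchange gains off the diagonal.  With this sign convention a two-pool
system with auto-rate rho and cross-rate sigma transfers

    M_cross(t) = (exp(-(rho - sigma) t) - exp(-(rho + sigma) t)) / 2

of a unit source deviation, so a *negative* sigma (small, fast-tumbling
molecules) yields cross-peaks of opposite sign to the diagonal -- the
"negative cross-peak" display convention for small saccharides.  The input
``R1`` is the full Solomon auto-relaxation rate of the pool.

All rates are s^-1, couplings Hz, times s.  No unit inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpinPool",
    "SpinSystem",
    "LongitudinalGenerator",
    "build_spin_system",
    "build_generator",
    "thermal_equilibrium",
]

POOL_KINDS = ("labile", "water", "nonlabile")


class SpinSystemError(ValueError):
    """Invalid spin-system configuration."""


@dataclass(frozen=True)
class SpinPool:
    """One magnetization pool.

    ``m_eq`` is the equilibrium longitudinal magnetization in arbitrary
    units proportional to the pool population (water is typically 1e3-1e5
    times a single hydroxyl proton).  ``R2`` is carried for the Liouville
    TOCSY engine; the longitudinal NOESY engine never reads it.
    """

    name: str
    kind: str
    m_eq: float = 1.0
    r1: float = 1.0
    r2: float | None = None
    offset: float = 0.0  # chemical-shift offset, Hz

    def __post_init__(self) -> None:
        if self.kind not in POOL_KINDS:
            raise SpinSystemError(
                f"unknown pool kind {self.kind!r} for pool {self.name!r}; "
                f"expected one of {POOL_KINDS}"
            )
        if not np.isfinite(self.r1) or self.r1 <= 0:
            raise SpinSystemError(f"pool {self.name!r}: R1 must be finite and > 0")
        if not self.m_eq > 0:
            raise SpinSystemError(f"pool {self.name!r}: m_eq must be > 0")
        # R2 >= R1 is physical but deliberately not enforced; flag only.
        object.__setattr__(self, "_r2_below_r1", self.r2 is not None and self.r2 < self.r1)

    @property
    def r2_below_r1(self) -> bool:
        return self._r2_below_r1


@dataclass
class SpinSystem:
    """Ordered pools plus pairwise exchange / cross-relaxation / J tables.

    ``kex`` holds *directed* rates ``{(a, b): k_a_to_b}``; reverse rates are
    completed from detailed balance ``k_ab * m_eq_a == k_ba * m_eq_b``.
    ``sigma`` and ``j`` are symmetric and stored on unordered pairs.
    """

    pools: list[SpinPool]
    kex: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma: dict[frozenset, float] = field(default_factory=dict)
    j: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise SpinSystemError("duplicate pool names")
        self._index = {n: i for i, n in enumerate(names)}

    # -- lookups -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pools]

    @property
    def n(self) -> int:
        return len(self.pools)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SpinSystemError(f"unknown pool {name!r}") from None

    def pool(self, name: str) -> SpinPool:
        return self.pools[self.index(name)]

    def kex_rate(self, a: str, b: str) -> float:
        return self.kex.get((a, b), 0.0)

    def sigma_rate(self, a: str, b: str) -> float:
        return self.sigma.get(frozenset((a, b)), 0.0)

    def j_coupling(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self.j:
            raise SpinSystemError(f"J coupling undefined for pair ({a}, {b})")
        return self.j[key]

    def has_j(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.j

    # -- matrices ----------------------------------------------------------
    def kex_matrix(self) -> np.ndarray:
        """Exchange sub-generator K with K[j, i] = k_{i->j}, K[i, i] = -sum out.

        Columns sum to zero: exchange conserves total magnetization.
        """
        n = self.n
        K = np.zeros((n, n))
        for (a, b), k in self.kex.items():
            ia, ib = self.index(a), self.index(b)
            K[ib, ia] += k
            K[ia, ia] -= k
        return K

    def sigma_matrix(self) -> np.ndarray:
        n = self.n
        S = np.zeros((n, n))
        for key, s in self.sigma.items():
            a, b = tuple(key)
            ia, ib = self.index(a), self.index(b)
            S[ia, ib] = S[ib, ia] = s
        return S

    def m_eq_vector(self) -> np.ndarray:
        return np.array([p.m_eq for p in self.pools], dtype=float)

    def labile_names(self) -> list[str]:
        return [p.name for p in self.pools if p.kind == "labile"]

    def water_names(self) -> list[str]:
        return [p.name for p in self.pools if p.kind == "water"]

    def with_rates(
        self,
        kex: float | None = None,
        sigma: float | None = None,
        j: float | None = None,
        pair: tuple[str, str] | None = None,
        exchange_pair: tuple[str, str] | None = None,
    ) -> "SpinSystem":
        """Copy of this system with selected rates replaced.

        ``kex`` replaces the forward rate of ``exchange_pair`` (default: the
        first labile->water pair present) and re-completes detailed balance;
        ``sigma``/``j`` replace the entry for ``pair``.
        """
        new_kex = dict(self.kex)
        new_sig = dict(self.sigma)
        new_j = dict(self.j)
        if kex is not None:
            if exchange_pair is None:
                labile = self.labile_names()
                water = self.water_names()
                if not labile or not water:
                    raise SpinSystemError("no labile/water pair to set kex on")
                exchange_pair = (labile[0], water[0])
            a, b = exchange_pair
            new_kex[(a, b)] = float(kex)
            new_kex[(b, a)] = float(kex) * self.pool(a).m_eq / self.pool(b).m_eq
        if sigma is not None:
            if pair is None:
                raise SpinSystemError("pair required to set sigma")
            new_sig[frozenset(pair)] = float(sigma)
        if j is not None:
            if pair is None:
                raise SpinSystemError("pair required to set J")
            new_j[frozenset(pair)] = float(j)
        return SpinSystem(pools=list(self.pools), kex=new_kex, sigma=new_sig, j=new_j)


@dataclass(frozen=True)
class LongitudinalGenerator:
    """Affine longitudinal evolution dM/dt = matrix @ M + recovery.

    ``recovery = -matrix @ m_eq`` so thermal equilibrium is the exact fixed
    point.  ``names`` preserves the pool ordering of the parent system.
    """

    matrix: np.ndarray
    recovery: np.ndarray
    names: tuple[str, ...]
    m_eq: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _parse_pair_key(key: str | tuple) -> tuple[str, str]:
    if isinstance(key, tuple):
        a, b = key
        return str(a), str(b)
    parts = [p.strip() for p in str(key).replace("->", "-").split("-")]
    if len(parts) != 2 or not all(parts):
        raise SpinSystemError(f"cannot parse pool pair from key {key!r}")
    return parts[0], parts[1]


def build_spin_system(config: dict) -> SpinSystem:
    """Validate a configuration mapping and assemble a :class:`SpinSystem`.

    Schema (YAML-compatible)::

        pools:
          OH: {kind: labile, m_eq: 1.0, r1: 1.0, r2: 20.0, offset: 1500.0}
          W:  {kind: water,  m_eq: 1000.0, r1: 0.3}
          CH: {kind: nonlabile, m_eq: 1.0, r1: 1.2, r2: 8.0}
        exchange: {OH-W: 100.0}     # forward rate a->b, s^-1
        sigma:    {OH-CH: -0.05}    # signed cross-relaxation, s^-1
        j:        {OH-CH: 5.0}      # scalar coupling, Hz

    Reverse exchange rates are auto-completed from detailed balance.
    Exchange may only be declared for a pair involving a labile or water
    pool; two nonlabile pools cannot exchange.
    """
    if "pools" not in config or len(config["pools"]) < 2:
        raise SpinSystemError("config must declare at least 2 pools")
    pools = []
    for name, spec in config["pools"].items():
        spec = dict(spec)
        pools.append(
            SpinPool(
                name=str(name),
                kind=spec.pop("kind"),
                m_eq=float(spec.pop("m_eq", 1.0)),
                r1=float(spec.pop("r1", 1.0)),
                r2=(float(spec["r2"]) if spec.get("r2") is not None else None),
                offset=float(spec.pop("offset", 0.0)),
            )
        )
    system = SpinSystem(pools=pools)

    for key, rate in dict(config.get("exchange", {})).items():
        a, b = _parse_pair_key(key)
        pa, pb = system.pool(a), system.pool(b)
        if pa.kind == "nonlabile" and pb.kind == "nonlabile":
            raise SpinSystemError(
                f"exchange declared between two nonlabile pools ({a}, {b})"
            )
        rate = float(rate)
        if not np.isfinite(rate) or rate < 0:
            raise SpinSystemError(f"exchange rate {a}->{b} must be finite and >= 0")
        system.kex[(a, b)] = rate
        # detailed balance: k_ab * m_eq_a = k_ba * m_eq_b
        system.kex[(b, a)] = rate * pa.m_eq / pb.m_eq

    for key, s in dict(config.get("sigma", {})).items():
        a, b = _parse_pair_key(key)
        system.index(a), system.index(b)
        s = float(s)
        if not np.isfinite(s):
            raise SpinSystemError(f"sigma({a},{b}) must be finite")
        system.sigma[frozenset((a, b))] = s

    for key, jval in dict(config.get("j", {})).items():
        a, b = _parse_pair_key(key)
        if a == b:
            raise SpinSystemError("J coupling must be between distinct pools")
        system.index(a), system.index(b)
        system.j[frozenset((a, b))] = float(jval)

    return system


def system_to_config(system: SpinSystem) -> dict:
    """Inverse of :func:`build_spin_system` (round-trips through YAML)."""
    cfg: dict = {"pools": {}, "exchange": {}, "sigma": {}, "j": {}}
    for p in system.pools:
        entry = {"kind": p.kind, "m_eq": p.m_eq, "r1": p.r1, "offset": p.offset}
        if p.r2 is not None:
            entry["r2"] = p.r2
        cfg["pools"][p.name] = entry
    seen = set()
    for (a, b), k in system.kex.items():
        if frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        cfg["exchange"][f"{a}-{b}"] = k
    for key, s in system.sigma.items():
        a, b = tuple(key)
        cfg["sigma"][f"{a}-{b}"] = s
    for key, jval in system.j.items():
        a, b = tuple(key)
        cfg["j"][f"{a}-{b}"] = jval
    return cfg


def build_generator(system: SpinSystem, sigma_sign: float = 1.0) -> LongitudinalGenerator:
    """Assemble the longitudinal Bloch-McConnell/Solomon generator.

    ``A[i, i] = -(R1_i + sum_j k_{i->j})`` and
    ``A[i, j] = sigma_sign * sigma_ij + k_{j->i}`` for ``i != j``.
    ``sigma_sign`` is the single global display-convention switch; the
    default reproduces opposite-sign (``negative'') cross-peaks for
    fast-tumbling molecules entered with ``sigma < 0``.
    """
    n = system.n
    r1 = np.array([p.r1 for p in system.pools])
    A = system.kex_matrix() + sigma_sign * system.sigma_matrix()
    A[np.diag_indices(n)] -= r1
    m_eq = system.m_eq_vector()
    recovery = -A @ m_eq
    return LongitudinalGenerator(
        matrix=A, recovery=recovery, names=tuple(system.names), m_eq=m_eq
    )


def thermal_equilibrium(system: SpinSystem) -> np.ndarray:
    """Equilibrium magnetization vector in pool order."""
    return system.m_eq_vector()
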