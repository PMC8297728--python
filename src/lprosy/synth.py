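"""Synthetic inputs: spin-system presets and conformer-ensemble generators.

These generators define the study conditions every simulation and geometry
routine is exercised under, without requiring downloads or real spectra.
All randomness flows through a single seeded :class:`numpy.random.Generator`
per call; the same seed always reproduces the same object.
"""

from __future__ import annotations

import numpy as np

from .ensemble import ConformerEnsemble
from .spin import SpinSystem, build_spin_system

__all__ = ["generate_synthetic_spin_system", "generate_synthetic_ensemble"]

# Hydroxyl protons in saccharides exchange with water at roughly 10-1000 1/s
# near room temperature; amide protons are one to two orders slower.
SUGAR_OH_KEX_RANGE = (10.0, 1000.0)
AMIDE_KEX_RANGE = (1.0, 100.0)
# water/labile population ratio; finite but large (infinite-reservoir limit
# is recovered by raising it)
WATER_POOL_RATIO = 1000.0


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def generate_synthetic_spin_system(
    preset: str = "sugar-OH",
    seed: int | None = None,
    overrides: dict | None = None,
) -> SpinSystem:
    """Three-pool labile/water/nonlabile system with preset-typical rates.

    ``sugar-OH`` draws the hydroxyl-water exchange rate log-uniformly from
    10-1000 1/s with small-molecule relaxation defaults; ``amide`` uses a
    slower exchange window and a three-bond amide J; ``custom`` starts from
    the sugar template and relies entirely on ``overrides`` (a nested
    mapping merged onto the config before validation).
    """
    rng = np.random.default_rng(seed)
    if preset == "sugar-OH":
        kex = float(np.exp(rng.uniform(*np.log(SUGAR_OH_KEX_RANGE))))
        config = {
            "pools": {
                "OH": {"kind": "labile", "m_eq": 1.0, "r1": 1.0, "r2": 20.0,
                       "offset": 1500.0},
                "W": {"kind": "water", "m_eq": WATER_POOL_RATIO, "r1": 0.3,
                      "r2": 1.0, "offset": 0.0},
                "CH": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.2, "r2": 8.0,
                       "offset": -800.0},
            },
            "exchange": {"OH-W": kex},
            "sigma": {"OH-CH": -0.05},
            "j": {"OH-CH": 5.0},
        }
    elif preset == "amide":
        kex = float(np.exp(rng.uniform(*np.log(AMIDE_KEX_RANGE))))
        config = {
            "pools": {
                "NH": {"kind": "labile", "m_eq": 1.0, "r1": 1.2, "r2": 15.0,
                       "offset": 2500.0},
                "W": {"kind": "water", "m_eq": WATER_POOL_RATIO, "r1": 0.3,
                      "r2": 1.0, "offset": 0.0},
                "HA": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.5, "r2": 10.0,
                       "offset": -500.0},
            },
            "exchange": {"NH-W": kex},
            "sigma": {"NH-HA": -0.1},
            "j": {"NH-HA": 7.0},
        }
    elif preset == "custom":
        # fixed-rate template; callers shape it entirely through overrides
        config = {
            "pools": {
                "OH": {"kind": "labile", "m_eq": 1.0, "r1": 1.0, "r2": 20.0,
                       "offset": 1500.0},
                "W": {"kind": "water", "m_eq": WATER_POOL_RATIO, "r1": 0.3,
                      "r2": 1.0, "offset": 0.0},
                "CH": {"kind": "nonlabile", "m_eq": 1.0, "r1": 1.2, "r2": 8.0,
                       "offset": -800.0},
            },
            "exchange": {"OH-W": 100.0},
            "sigma": {"OH-CH": -0.05},
            "j": {"OH-CH": 5.0},
        }
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if overrides:
        _deep_update(config, overrides)
    return build_spin_system(config)


def _random_rigid(rng) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR-based) and a small random translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=3.0, size=3)


def generate_synthetic_ensemble(
    n_frames: int,
    n_atoms: int,
    mode: str = "single-well",
    noise: float = 0.1,
    seed: int | None = None,
    mixture: float = 0.7,
    separation: float = 5.0,
) -> ConformerEnsemble:
    """Deterministic synthetic conformer ensemble.

    ``single-well``: one rigid template plus Gaussian coordinate noise.
    ``two-state``: frames drawn from two rigid templates (probability
    ``mixture`` for state A) separated by displacing half the atoms by
    ``separation`` Angstrom, plus noise; each frame additionally receives a
    random rigid motion so that superposition is non-trivial.
    ``uniform-torsion``: a four-atom dihedral chain (atoms 0-3) whose
    torsion is drawn uniformly on [-180, 180) per frame; remaining atoms
    ride rigidly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_atoms < 4:
        raise ValueError("n_atoms must be >= 4")
    rng = np.random.default_rng(seed)
    template = rng.normal(scale=3.0, size=(n_atoms, 3))
    coords = np.empty((n_frames, n_atoms, 3))

    if mode == "single-well":
        for f in range(n_frames):
            coords[f] = template + rng.normal(scale=noise, size=(n_atoms, 3))
        states = np.zeros(n_frames, dtype=int)
    elif mode == "two-state":
        from .ensemble import kabsch_superpose

        # displace half the atoms, then rescale so the *superposed* RMSD
        # between the two rigid templates equals the requested separation
        delta = rng.normal(size=(n_atoms, 3))
        delta[: n_atoms // 2] = 0.0
        for _ in range(4):
            r, _, _ = kabsch_superpose(template, template + delta)
            delta *= separation / r
        template_b = template + delta
        states = (rng.random(n_frames) >= mixture).astype(int)  # 0 = A
        for f in range(n_frames):
            base = template if states[f] == 0 else template_b
            rot, trans = _random_rigid(rng)
            coords[f] = (base + rng.normal(scale=noise, size=(n_atoms, 3))) @ rot.T + trans
    elif mode == "uniform-torsion":
        # chain geometry: unit bonds, tetrahedral-ish angles; atom 3 rotated
        base = template.copy()
        base[0] = (0.0, 1.0, 1.0)
        base[1] = (0.0, 0.0, 1.0)
        base[2] = (0.0, 0.0, 0.0)
        torsions = rng.uniform(-180.0, 180.0, size=n_frames)
        for f, omega in enumerate(torsions):
            frame = base.copy()
            w = np.deg2rad(omega)
            # place atom 3 at unit distance from atom 2, dihedral = omega
            frame[3] = (-np.sin(w), np.cos(w), -0.5)
            coords[f] = frame + rng.normal(scale=noise, size=(n_atoms, 3))
        states = np.zeros(n_frames, dtype=int)
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")

    ens = ConformerEnsemble(
        coords=coords,
        atom_names=[f"A{i + 1}" for i in range(n_atoms)],
        resids=np.ones(n_atoms, dtype=int),
        resnames=["SYN"] * n_atoms,
    )
    ens.states = states  # ground truth for mixture-recovery checks
    return ens
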