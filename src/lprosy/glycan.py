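"""Structural-NMR computations for glycan analysis.

Karplus vicinal couplings and their inverse (torsion windows from an
observed 3J), NOE-effective <r^-6>^-1/6 ensemble distances, geometric
hydrogen-bond detection with trajectory occupancies, Arrhenius scaling of
exchange rates, chemical-shift temperature coefficients, Stejskal-Tanner
diffusion fits, and restraint-table assembly for external structure
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KarplusParams",
    "HBondCriteria",
    "RestraintTable",
    "karplus_j",
    "karplus_extrema",
    "torsion_candidates",
    "effective_noe_distance",
    "detect_hbonds",
    "arrhenius_scale",
    "temp_coefficient",
    "stejskal_tanner_fit",
    "hydrodynamic_radius_ratio",
    "build_restraints",
]

R_GAS = 8.314462618e-3  # kJ/(mol K)
GAMMA_1H = 2.6752218744e4  # rad/(s G)


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients of J(omega) = C + A cos^2(omega) + B cos(omega), Hz.

    The defaults are the HCCH parameterization used for glycerol-chain
    torsions of sialic acids: J = 0.48 + 10.18 cos^2(w) - 0.03 cos(w).
    """

    A: float = 10.18
    B: float = -0.03
    C: float = 0.48


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    A bond is recorded when the donor-acceptor distance d_DA <= ``d_da_max``
    (default 3.0 Angstrom) AND the D-H...A angle at the hydrogen is
    >= ``theta_dha_min`` (default 135 degrees, 180 = linear).  Both
    comparisons are inclusive at the boundary.
    """

    d_da_max: float = 3.0
    theta_dha_min: float = 135.0


@dataclass
class RestraintTable:
    """NOE distance bounds and torsion windows for structure calculation."""

    distances: pd.DataFrame = field(default_factory=pd.DataFrame)
    torsions: pd.DataFrame = field(default_factory=pd.DataFrame)


def karplus_j(omega, params: KarplusParams = KarplusParams()):
    """Vicinal 3J(omega) in Hz; omega in degrees.  Vectorized; even in omega."""
    c = np.cos(np.deg2rad(omega))
    return params.C + params.A * c * c + params.B * c


def karplus_extrema(params: KarplusParams = KarplusParams()) -> tuple[float, float]:
    """Analytic (min, max) of the Karplus curve over all torsions.

    J is quadratic in x = cos(omega) on [-1, 1]: the extrema lie at the
    interval ends or at the vertex x = -B/(2A).
    """
    xs = [-1.0, 1.0]
    if params.A != 0:
        xv = -params.B / (2.0 * params.A)
        if -1.0 <= xv <= 1.0:
            xs.append(xv)
    vals = [params.C + params.A * x * x + params.B * x for x in xs]
    return min(vals), max(vals)


def torsion_candidates(
    j_obs: float,
    tolerance: float,
    params: KarplusParams = KarplusParams(),
    step: float = 0.01,
) -> list[tuple[float, float]]:
    """All torsions omega in [-180, 180) with |J(omega) - j_obs| <= tolerance.

    Returned as merged closed intervals (degrees); intervals crossing the
    -180/180 seam are merged across it.  Empty if j_obs lies outside the
    curve's range.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    jmin, jmax = karplus_extrema(params)
    if j_obs - tolerance > jmax or j_obs + tolerance < jmin:
        return []
    omegas = np.arange(-180.0, 180.0, step)
    mask = np.abs(karplus_j(omegas, params) - j_obs) <= tolerance
    if not mask.any():
        return []
    # contiguous runs of the mask
    diff = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    intervals = [(float(omegas[s]), float(omegas[e])) for s, e in zip(starts, ends)]
    # merge across the periodic seam
    if len(intervals) > 1 and mask[0] and mask[-1]:
        first, last = intervals[0], intervals[-1]
        intervals = intervals[1:-1] + [(last[0], first[1] + 360.0)]
    return intervals


def _resolve_atoms(ensemble, selection) -> np.ndarray:
    """Indices of atoms matching a name, a list of names, or explicit indices."""
    if isinstance(selection, (int, np.integer)):
        return np.array([int(selection)])
    if isinstance(selection, str):
        selection = [selection]
    names = list(ensemble.atom_names)
    idx = []
    for item in selection:
        if isinstance(item, (int, np.integer)):
            idx.append(int(item))
        else:
            found = [i for i, n in enumerate(names) if n == item]
            if not found:
                raise KeyError(f"atom {item!r} not found in ensemble")
            idx.extend(found)
    return np.array(sorted(set(idx)))


def effective_noe_distance(ensemble, pair) -> float:
    """NOE-effective distance (<r^-6> over frames)^(-1/6), Angstrom.

    ``pair`` is (selection_a, selection_b); a selection naming several
    protons (diastereotopic H3A/E or H9R/S groups) contributes its per-frame
    *shortest* distance, matching how grouped NOEs are tabulated.
    """
    ia = _resolve_atoms(ensemble, pair[0])
    ib = _resolve_atoms(ensemble, pair[1])
    coords = ensemble.coords  # (frames, atoms, 3)
    if coords.shape[0] < 1:
        raise ValueError("ensemble has no frames")
    d = np.linalg.norm(
        coords[:, ia, None, :] - coords[:, None, ib, :], axis=-1
    )  # (frames, |a|, |b|)
    r = d.reshape(d.shape[0], -1).min(axis=1)  # per-frame shortest distance
    if np.any(r <= 0):
        raise ValueError("zero interatomic distance encountered")
    return float(np.mean(r ** -6.0) ** (-1.0 / 6.0))


def detect_hbonds(
    ensemble,
    donors,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
) -> pd.DataFrame:
    """Geometric H-bond occupancies over an ensemble.

    ``donors`` is a list of (donor_atom, hydrogen_atom) selections and
    ``acceptors`` a list of acceptor atoms.  For every donor/acceptor
    combination (acceptor distinct from the donor atom) the fraction of
    frames with d_DA <= cutoff and theta(D-H-A) >= cutoff is reported.
    """
    coords = ensemble.coords
    records = []
    for donor, hydrogen in donors:
        try:
            i_d = int(_resolve_atoms(ensemble, donor)[0])
            i_h = int(_resolve_atoms(ensemble, hydrogen)[0])
        except KeyError as exc:
            raise KeyError(f"donor {donor!r} lacks a resolvable hydrogen: {exc}") from exc
        for acceptor in acceptors:
            i_a = int(_resolve_atoms(ensemble, acceptor)[0])
            if i_a == i_d:
                continue
            d_da = np.linalg.norm(coords[:, i_a] - coords[:, i_d], axis=-1)
            v1 = coords[:, i_d] - coords[:, i_h]
            v2 = coords[:, i_a] - coords[:, i_h]
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
            )
            theta = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
            hit = (d_da <= criteria.d_da_max) & (theta >= criteria.theta_dha_min)
            records.append(
                {
                    "donor": str(donor),
                    "hydrogen": str(hydrogen),
                    "acceptor": str(acceptor),
                    "occupancy": float(hit.mean()),
                    "mean_d_da": float(d_da.mean()),
                    "mean_theta": float(theta.mean()),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["donor", "hydrogen", "acceptor", "occupancy", "mean_d_da", "mean_theta"],
    )


def arrhenius_scale(k_ref: float, t_ref: float, t: float, ea: float) -> float:
    """Exchange rate rescaled between temperatures by thermal activation.

    k(T) = k_ref * exp(-Ea/R * (1/T - 1/T_ref)), Ea in kJ/mol, T in K.
    The activation energy is an input: labile-proton exchange barriers vary
    with pH and catalysis and must be supplied.
    """
    if t_ref <= 0 or t <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if ea < 0:
        raise ValueError("activation energy must be >= 0")
    return float(k_ref * np.exp(-ea / R_GAS * (1.0 / t - 1.0 / t_ref)))


def temp_coefficient(shifts, temps) -> tuple[float, float]:
    """Least-squares temperature coefficient of a chemical shift, ppb/K.

    Returns (slope, standard_error).  Negative slope = upfield with
    warming; magnitudes of only a few ppb/K flag protons sequestered in
    hydrogen bonds.
    """
    shifts = np.asarray(shifts, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if shifts.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(temps) == 0:
        raise ValueError("degenerate temperatures")
    res = stats.linregress(temps, shifts)
    stderr = 0.0 if np.isnan(res.stderr) else res.stderr
    return float(res.slope * 1e3), float(stderr * 1e3)


def stejskal_tanner_fit(
    areas,
    gradients,
    delta: float,
    big_delta: float,
    gamma: float = GAMMA_1H,
) -> tuple[float, float, float]:
    """Translational diffusion coefficient from a PFG decay.

    Fits A(g) = A0 * exp(-D * gamma^2 g^2 delta^2 (Delta - delta/3)) with
    gradients in G/cm, delta/Delta in s and gamma in rad/(s G), giving D in
    cm^2/s.  Returns (D, D_stderr, A0).
    """
    areas = np.asarray(areas, dtype=float)
    g = np.asarray(gradients, dtype=float)
    if areas.size < 3:
        raise ValueError("need at least 3 gradient points")
    b = (gamma * g * delta) ** 2 * (big_delta - delta / 3.0)
    # log-linear initialization (robust, exact for noiseless data)
    pos = areas > 0
    if pos.sum() >= 2 and np.ptp(b[pos]) > 0:
        slope = np.polyfit(b[pos], np.log(areas[pos]), 1)[0]
    else:
        slope = 0.0
    if slope >= 0:
        raise ValueError("signal does not decay with gradient strength")
    p0 = (areas.max(), -slope)

    def model(bv, a0, d):
        return a0 * np.exp(-d * bv)

    popt, pcov = optimize.curve_fit(model, b, areas, p0=p0, maxfev=10000)
    a0, d = popt
    d_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return float(d), d_err, float(a0)


def hydrodynamic_radius_ratio(d_reference: float, d_analyte: float) -> float:
    """Rh_analyte / Rh_reference from the Stokes-Einstein reciprocity.

    Diffusion coefficients scale inversely with hydrodynamic radius at
    fixed temperature and viscosity, so D_ref / D_analyte equals the radius
    ratio of analyte to reference.
    """
    if d_analyte == 0:
        raise ZeroDivisionError("analyte diffusion coefficient is zero")
    return d_reference / d_analyte


def _wrap_deg(x: float) -> float:
    return float((x + 180.0) % 360.0 - 180.0)


def build_restraints(
    noe_rows,
    torsion_rows,
    distance_margin: float = 1.0,
    torsion_window: float = 30.0,
) -> RestraintTable:
    """Assemble restraints: distance +/- 1 A, torsion target +/- 30 deg.

    ``noe_rows``: iterables of mappings with ``atoms`` (pair label) and
    ``distance`` (> 0, Angstrom); optional ``source``.
    ``torsion_rows``: mappings with ``atoms``, ``target`` (deg) and optional
    ``degenerate``; degenerate +/- targets (the Karplus curve cannot tell
    omega from -omega, e.g. the +/-90 deg H6-C6-C7-H7 windows) emit both
    branches.  Torsion bounds are wrapped to [-180, 180).
    """
    d_rows = []
    for row in noe_rows:
        d = float(row["distance"])
        if d <= 0:
            raise ValueError(f"non-positive distance for {row.get('atoms')}")
        d_rows.append(
            {
                "atoms": row["atoms"],
                "distance": d,
                "lower": max(d - distance_margin, 0.0),
                "upper": d + distance_margin,
                "source": row.get("source", ""),
            }
        )
    t_rows = []
    for row in torsion_rows:
        target = float(row["target"])
        branches = [target]
        if row.get("degenerate"):
            branches = sorted({_wrap_deg(target), _wrap_deg(-target)})
        for tgt in branches:
            t_rows.append(
                {
                    "atoms": row["atoms"],
                    "target": _wrap_deg(tgt),
                    "lower": _wrap_deg(tgt - torsion_window),
                    "upper": _wrap_deg(tgt + torsion_window),
                    "source": row.get("source", ""),
                }
            )
    return RestraintTable(
        distances=pd.DataFrame(
            d_rows, columns=["atoms", "distance", "lower", "upper", "source"]
        ),
        torsions=pd.DataFrame(
            t_rows, columns=["atoms", "target", "lower", "upper", "source"]
        ),
    )
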