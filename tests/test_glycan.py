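"""Karplus curve, NOE distances, H-bonds, Arrhenius, diffusion, restraints."""

import numpy as np
import pytest

from lprosy.ensemble import ConformerEnsemble
from lprosy.glycan import (
    GAMMA_1H,
    HBondCriteria,
    KarplusParams,
    arrhenius_scale,
    build_restraints,
    detect_hbonds,
    effective_noe_distance,
    hydrodynamic_radius_ratio,
    karplus_extrema,
    karplus_j,
    stejskal_tanner_fit,
    temp_coefficient,
    torsion_candidates,
)


# -- Karplus ---------------------------------------------------------------

def test_karplus_printed_coefficients():
    assert karplus_j(0.0) == pytest.approx(0.48 + 10.18 - 0.03)
    assert karplus_j(90.0) == pytest.approx(0.48, abs=1e-12)
    assert karplus_j(-90.0) == pytest.approx(0.48, abs=1e-12)
    # gauche-ish torsions near +/-90 deg stay under the 2 Hz reading
    assert karplus_j(90.0) < 2.0


def test_karplus_even_function():
    omegas = np.linspace(-180.0, 180.0, 73)
    assert np.allclose(karplus_j(omegas), karplus_j(-omegas))


def test_karplus_bounded_by_analytic_extrema():
    jmin, jmax = karplus_extrema()
    vals = karplus_j(np.linspace(-180.0, 180.0, 100001))
    assert vals.min() >= jmin - 1e-12
    assert vals.max() <= jmax + 1e-12


def test_torsion_candidates_round_trip():
    intervals = torsion_candidates(0.48, 0.01)
    assert intervals, "expected solutions around +/-90 deg"
    hits = [lo <= 90.0 <= hi or lo <= -90.0 <= hi for lo, hi in intervals]
    assert any(hits)
    for lo, hi in intervals:
        for w in np.linspace(lo, hi, 7):
            assert abs(float(karplus_j(((w + 180) % 360) - 180)) - 0.48) <= 0.01 + 1e-9


def test_torsion_candidates_out_of_range_empty():
    assert torsion_candidates(20.0, 0.5) == []


def test_torsion_candidates_anti_window_wraps_seam():
    j_anti = float(karplus_j(180.0))
    intervals = torsion_candidates(j_anti, 0.05)
    # the anti solution straddles -180/180; it must come back as one interval
    assert any(hi > 180.0 or lo <= -179.9 for lo, hi in intervals)


# -- NOE effective distances ----------------------------------------------

def _ensemble_from_distances(distances):
    """Two-atom ensemble with prescribed per-frame separations."""
    frames = [[[0.0, 0.0, 0.0], [d, 0.0, 0.0]] for d in distances]
    return ConformerEnsemble(coords=np.array(frames), atom_names=["HA", "HB"])


def test_effective_distance_constant():
    ens = _ensemble_from_distances([3.0, 3.0, 3.0])
    assert effective_noe_distance(ens, ("HA", "HB")) == pytest.approx(3.0)


def test_effective_distance_hand_value():
    # ((2^-6 + 4^-6)/2)^(-1/6) = 2.2392...
    ens = _ensemble_from_distances([2.0, 4.0])
    expected = ((2.0 ** -6 + 4.0 ** -6) / 2.0) ** (-1.0 / 6.0)
    d = effective_noe_distance(ens, ("HA", "HB"))
    assert d == pytest.approx(expected, rel=1e-12)
    assert d == pytest.approx(2.24, abs=0.005)


def test_effective_distance_power_mean_bounds():
    rng = np.random.default_rng(11)
    dists = rng.uniform(2.0, 6.0, size=50)
    ens = _ensemble_from_distances(dists)
    d = effective_noe_distance(ens, ("HA", "HB"))
    assert dists.min() <= d <= dists.max()
    # frame-permutation invariance
    ens_p = _ensemble_from_distances(dists[::-1])
    assert effective_noe_distance(ens_p, ("HA", "HB")) == pytest.approx(d, rel=1e-12)


def test_effective_distance_group_uses_shortest():
    # diastereotopic pair: per-frame min distance enters the average
    frames = np.array(
        [
            [[0, 0, 0], [2.0, 0, 0], [5.0, 0, 0]],
            [[0, 0, 0], [6.0, 0, 0], [3.0, 0, 0]],
        ],
        dtype=float,
    )
    ens = ConformerEnsemble(coords=frames, atom_names=["OH", "H9R", "H9S"])
    d = effective_noe_distance(ens, ("OH", ["H9R", "H9S"]))
    expected = ((2.0 ** -6 + 3.0 ** -6) / 2.0) ** (-1.0 / 6.0)
    assert d == pytest.approx(expected, rel=1e-12)


def test_effective_distance_missing_atom():
    ens = _ensemble_from_distances([3.0])
    with pytest.raises(KeyError):
        effective_noe_distance(ens, ("HA", "HX"))


# -- H-bonds ---------------------------------------------------------------

def _hbond_frame(d_da, theta_deg):
    """Donor at origin, H on +x; acceptor placed for a given d_DA and angle."""
    theta = np.deg2rad(theta_deg)
    h = np.array([1.0, 0.0, 0.0])
    # direction of H->A makes angle theta with H->D at the hydrogen
    direction = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    # choose the H-A length so that |D-A| = d_da
    # solve |h + t*dir| = d_da for t > 0
    b = 2.0 * h @ direction
    c = 1.0 - d_da ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    a = h + t * direction
    return np.array([[0.0, 0.0, 0.0], h, a])


@pytest.mark.parametrize(
    "d,theta,expected",
    [
        (2.8, 170.0, 1.0),   # clearly bonded
        (3.2, 180.0, 0.0),   # too long even if linear
        (2.8, 120.0, 0.0),   # too bent
    ],
)
def test_hbond_geometry_cutoffs(d, theta, expected):
    frame = _hbond_frame(d, theta)
    ens = ConformerEnsemble(coords=frame[None], atom_names=["OD", "HD", "OA"])
    df = detect_hbonds(ens, [("OD", "HD")], ["OA"])
    assert df.loc[0, "occupancy"] == expected
    assert df.loc[0, "mean_d_da"] == pytest.approx(d, abs=1e-9)
    assert df.loc[0, "mean_theta"] == pytest.approx(theta, abs=1e-6)


def test_hbond_boundary_is_inclusive():
    """A geometry sitting exactly on both cutoffs counts as bonded."""
    frame = _hbond_frame(3.0, 135.0)
    ens = ConformerEnsemble(coords=frame[None], atom_names=["OD", "HD", "OA"])
    measured = detect_hbonds(ens, [("OD", "HD")], ["OA"], HBondCriteria(1e9, 0.0))
    d_meas = measured.loc[0, "mean_d_da"]
    t_meas = measured.loc[0, "mean_theta"]
    exact = detect_hbonds(
        ens, [("OD", "HD")], ["OA"], HBondCriteria(d_meas, t_meas)
    )
    assert exact.loc[0, "occupancy"] == 1.0


def test_hbond_occupancy_monotone_in_criteria():
    rng = np.random.default_rng(5)
    frames = np.stack(
        [_hbond_frame(rng.uniform(2.5, 3.5), rng.uniform(110, 180)) for _ in range(200)]
    )
    ens = ConformerEnsemble(coords=frames, atom_names=["OD", "HD", "OA"])
    loose = detect_hbonds(ens, [("OD", "HD")], ["OA"], HBondCriteria(3.5, 120.0))
    default = detect_hbonds(ens, [("OD", "HD")], ["OA"])
    tight = detect_hbonds(ens, [("OD", "HD")], ["OA"], HBondCriteria(2.7, 160.0))
    occ = [df.loc[0, "occupancy"] for df in (loose, default, tight)]
    assert 1.0 >= occ[0] >= occ[1] >= occ[2] >= 0.0


def test_hbond_missing_hydrogen():
    ens = _ensemble_from_distances([3.0])
    with pytest.raises(KeyError, match="hydrogen"):
        detect_hbonds(ens, [("HA", "HX")], ["HB"])


# -- Arrhenius and temperature coefficients --------------------------------

def test_arrhenius_identity_and_limits():
    assert arrhenius_scale(100.0, 263.15, 263.15, 40.0) == pytest.approx(100.0)
    assert arrhenius_scale(100.0, 263.15, 310.0, 0.0) == pytest.approx(100.0)
    ks = [arrhenius_scale(100.0, 263.15, t, 40.0) for t in (263.15, 278.15, 298.15)]
    assert ks[0] < ks[1] < ks[2]
    with pytest.raises(ValueError):
        arrhenius_scale(100.0, -5.0, 278.15, 40.0)


def test_temp_coefficient_two_points():
    slope, _ = temp_coefficient([6.00, 5.95], [278.0, 288.0])
    assert slope == pytest.approx(-5.0)


def test_temp_coefficient_constant_and_degenerate():
    slope, err = temp_coefficient([5.5, 5.5, 5.5], [270.0, 280.0, 290.0])
    assert slope == 0.0
    with pytest.raises(ValueError):
        temp_coefficient([5.5, 5.4], [280.0, 280.0])


def test_temp_coefficient_recovers_noisy_slope():
    rng = np.random.default_rng(2)
    temps = np.linspace(268.0, 298.0, 6)
    true = -8.0  # ppb/K
    shifts = 6.0 + true * 1e-3 * (temps - temps.mean()) + rng.normal(0, 2e-3, 6)
    slope, err = temp_coefficient(shifts, temps)
    assert abs(slope - true) <= 2.0 * err


# -- diffusion -------------------------------------------------------------

def test_stejskal_tanner_recovery_noiseless():
    d_true = 3.0e-6  # cm^2/s
    delta, big_delta = 2e-3, 0.1
    g = np.linspace(0.0, 50.0, 8)
    b = (GAMMA_1H * g * delta) ** 2 * (big_delta - delta / 3.0)
    areas = 7.5 * np.exp(-d_true * b)
    d, err, a0 = stejskal_tanner_fit(areas, g, delta, big_delta)
    assert d == pytest.approx(d_true, rel=1e-4)
    assert a0 == pytest.approx(7.5, rel=1e-6)  # g=0 intercept recovered


def test_stejskal_tanner_rejects_non_decaying():
    g = np.linspace(0.0, 50.0, 6)
    with pytest.raises(ValueError, match="decay"):
        stejskal_tanner_fit(np.ones_like(g), g, 2e-3, 0.1)


def test_radius_ratio_reciprocity():
    # D_ref / D_analyte = Rh_analyte / Rh_ref
    assert hydrodynamic_radius_ratio(6.0e-6, 2.0e-6) == pytest.approx(3.0)
    with pytest.raises(ZeroDivisionError):
        hydrodynamic_radius_ratio(1.0, 0.0)


# -- restraints ------------------------------------------------------------

def test_restraint_distance_bounds():
    table = build_restraints(
        [{"atoms": "IIOH7-IIIH3", "distance": 3.2}], []
    )
    row = table.distances.iloc[0]
    assert (row["lower"], row["upper"]) == (2.2, 4.2)


def test_restraint_torsion_wrap():
    table = build_restraints([], [{"atoms": "w8", "target": 180.0}])
    row = table.torsions.iloc[0]
    assert row["target"] == -180.0  # wrapped representative of 180
    assert row["lower"] == 150.0
    assert row["upper"] == -150.0


def test_degenerate_torsion_emits_both_branches():
    table = build_restraints([], [{"atoms": "w7", "target": 90.0, "degenerate": True}])
    assert len(table.torsions) == 2
    assert sorted(table.torsions["target"]) == [-90.0, 90.0]


def test_restraint_rejects_nonpositive_distance():
    with pytest.raises(ValueError):
        build_restraints([{"atoms": "x", "distance": 0.0}], [])
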