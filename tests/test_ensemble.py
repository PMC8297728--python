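"""Superposition, 2D-RMSD maps, clustering, representatives, torsion maps."""

import numpy as np
import pytest

from lprosy.ensemble import (
    ConformerEnsemble,
    cluster_by_cutoff,
    dihedral_angles,
    kabsch_superpose,
    representative_models,
    rmsd2d_map,
    torsion_population_map,
)
from lprosy.synth import generate_synthetic_ensemble


def quaternion_rmsd(a, b):
    """Independent quaternion-eigenvalue superposition RMSD (Kearsley)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a - b
    p = a + b
    xm, ym, zm = m.T
    xp, yp, zp = p.T
    k = np.empty((4, 4))
    k[0, 0] = (xm ** 2 + ym ** 2 + zm ** 2).sum()
    k[1, 1] = (xm ** 2 + yp ** 2 + zp ** 2).sum()
    k[2, 2] = (xp ** 2 + ym ** 2 + zp ** 2).sum()
    k[3, 3] = (xp ** 2 + yp ** 2 + zm ** 2).sum()
    k[0, 1] = k[1, 0] = (yp * zm - ym * zp).sum()
    k[0, 2] = k[2, 0] = (xm * zp - xp * zm).sum()
    k[0, 3] = k[3, 0] = (xp * ym - xm * yp).sum()
    k[1, 2] = k[2, 1] = (xm * ym - xp * yp).sum()
    k[1, 3] = k[3, 1] = (xm * zm - xp * zp).sum()
    k[2, 3] = k[3, 2] = (ym * zm - yp * zp).sum()
    lam = np.linalg.eigvalsh(k)[0]
    return np.sqrt(max(lam, 0.0) / a.shape[0])


def random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# -- Kabsch ----------------------------------------------------------------

def test_identical_coordinates_zero_rmsd():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(10, 3))
    r, rot, t = kabsch_superpose(a, a)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3))


def test_rigid_motion_invariance():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(12, 3))
    rot = random_rotation(rng)
    b = a @ rot.T + np.array([3.0, -2.0, 7.0])
    r, _, _ = kabsch_superpose(a, b)
    assert r == pytest.approx(0.0, abs=1e-10)


def test_kabsch_matches_quaternion_oracle():
    rng = np.random.default_rng(42)
    for _ in range(25):
        a = rng.normal(scale=2.0, size=(10, 3))
        b = rng.normal(scale=2.0, size=(10, 3))
        r, _, _ = kabsch_superpose(a, b)
        assert r == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)


def test_degenerate_geometry_rejected():
    line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
    with pytest.raises(ValueError, match="ollinear|degenerate"):
        kabsch_superpose(line, line)


# -- 2D-RMSD map -----------------------------------------------------------

def test_identical_frames_zero_map():
    ens = generate_synthetic_ensemble(6, 8, mode="single-well", noise=0.0, seed=0)
    m = rmsd2d_map(ens)
    assert np.abs(m).max() < 1e-8


def test_map_symmetry_zero_diagonal_and_kabsch_agreement():
    ens = generate_synthetic_ensemble(15, 9, mode="two-state", noise=0.3, seed=4)
    m = rmsd2d_map(ens)
    assert np.array_equal(m, m.T)
    assert np.all(np.diag(m) == 0.0)
    for i, j in [(0, 5), (3, 11), (7, 14)]:
        r, _, _ = kabsch_superpose(ens.coords[i], ens.coords[j])
        assert m[i, j] == pytest.approx(r, abs=1e-8)


def test_two_state_block_structure():
    ens = generate_synthetic_ensemble(40, 10, mode="two-state", noise=0.3, seed=8)
    m = rmsd2d_map(ens)
    s = ens.states
    inter = m[np.ix_(s == 0, s == 1)]
    intra = m[np.ix_(s == 0, s == 0)]
    assert inter.min() > intra.max()


def test_stride_subsamples_frames():
    ens = generate_synthetic_ensemble(20, 8, mode="single-well", noise=0.1, seed=2)
    m = rmsd2d_map(ens, stride=4)
    assert m.shape == (5, 5)


# -- clustering ------------------------------------------------------------

def test_identical_frames_single_cluster():
    ens = generate_synthetic_ensemble(10, 8, mode="single-well", noise=0.0, seed=0)
    rep = cluster_by_cutoff(rmsd2d_map(ens), 2.0)
    assert rep.n_clusters == 1
    assert rep.fractions == [1.0]


def test_two_state_two_clusters():
    ens = generate_synthetic_ensemble(60, 10, mode="two-state", noise=0.3, seed=9,
                                      separation=5.0)
    rep = cluster_by_cutoff(rmsd2d_map(ens), 2.0)
    assert rep.n_clusters == 2
    assert sum(rep.fractions) == pytest.approx(1.0)


def test_cutoff_above_max_single_cluster():
    ens = generate_synthetic_ensemble(20, 8, mode="two-state", noise=0.3, seed=3)
    m = rmsd2d_map(ens)
    rep = cluster_by_cutoff(m, m.max() + 1.0)
    assert rep.n_clusters == 1 and rep.fractions == [1.0]


def test_cluster_permutation_equivariance():
    ens = generate_synthetic_ensemble(30, 8, mode="two-state", noise=0.3, seed=6)
    m = rmsd2d_map(ens)
    rep = cluster_by_cutoff(m, 2.0)
    perm = np.random.default_rng(0).permutation(30)
    rep_p = cluster_by_cutoff(m[np.ix_(perm, perm)], 2.0)
    assert sorted(rep.fractions) == sorted(rep_p.fractions)
    # co-membership is preserved under relabeling
    co = rep.labels[:, None] == rep.labels[None, :]
    co_p = rep_p.labels[:, None] == rep_p.labels[None, :]
    assert np.array_equal(co[np.ix_(perm, perm)], co_p)


def test_invalid_cutoff_rejected():
    with pytest.raises(ValueError):
        cluster_by_cutoff(np.zeros((3, 3)), 0.0)


def test_two_state_fraction_recovery_n500():
    """Mixture fractions recovered within binomial error at 500 frames."""
    ens = generate_synthetic_ensemble(500, 12, mode="two-state", noise=0.2,
                                      seed=7, mixture=0.7)
    rep = cluster_by_cutoff(rmsd2d_map(ens), 2.0)
    assert rep.n_clusters == 2
    major = max(rep.fractions)
    # exact recovery of the realized state partition ...
    assert major == pytest.approx((ens.states == 0).mean(), abs=1e-12)
    # ... which itself sits within binomial error of the nominal mixture
    assert abs(major - 0.7) <= 3.0 * np.sqrt(0.7 * 0.3 / 500)


# -- representative models -------------------------------------------------

def test_constant_trajectory_representative():
    ens = generate_synthetic_ensemble(21, 8, mode="single-well", noise=0.0, seed=0)
    rep = representative_models(ens, [10], window=11)
    assert rep.fractions == [1.0]
    r, _, _ = kabsch_superpose(rep.representatives[0], ens.coords[0])
    assert r == pytest.approx(0.0, abs=1e-10)


def test_representative_window_must_fit():
    ens = generate_synthetic_ensemble(12, 8, mode="single-well", noise=0.1, seed=0)
    with pytest.raises(ValueError):
        representative_models(ens, [1], window=11)
    with pytest.raises(ValueError):
        representative_models(ens, [6], window=10)  # even window


def test_two_state_representatives_recover_mixture():
    raw = generate_synthetic_ensemble(200, 10, mode="two-state", noise=0.2,
                                      seed=13, mixture=0.7)
    # arrange frames into contiguous state blocks so an 11-frame window can
    # be anchored inside each conformational region
    order = np.argsort(raw.states, kind="stable")
    ens = ConformerEnsemble(coords=raw.coords[order], atom_names=raw.atom_names)
    s = raw.states[order]
    n0 = int((s == 0).sum())
    anchors = [n0 // 2, n0 + (200 - n0) // 2]
    rep = representative_models(ens, anchors, window=11, cutoff=2.0)
    assert rep.fractions[0] == pytest.approx((s == 0).mean(), abs=0.02)
    assert rep.fractions[1] == pytest.approx((s == 1).mean(), abs=0.02)


def test_anchor_coverage_monotone():
    ens = generate_synthetic_ensemble(100, 10, mode="two-state", noise=0.2, seed=17)
    one = representative_models(ens, [50], window=11, cutoff=2.0)
    s = ens.states
    other_state = 1 - s[50]
    idx = [i for i in np.flatnonzero(s == other_state) if 5 <= i < 95]
    two = representative_models(ens, [50, idx[0]], window=11, cutoff=2.0)
    assert sum(two.fractions) >= sum(one.fractions) - 1e-12


# -- torsion maps ----------------------------------------------------------

def test_dihedral_known_geometry():
    # butane-like: trans arrangement = 180, cis = 0
    trans = np.array([[[1.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                       [1.0, -1.0, 0.0], [0.0, -2.0, 0.0]]])
    ang = dihedral_angles(trans, np.array([0, 1, 2, 3]))
    assert abs(abs(ang[0]) - 180.0) < 1e-9 or abs(ang[0] + 180.0) < 1e-9
    cis = np.array([[[1.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                     [1.0, -1.0, 0.0], [2.0, -0.0, 0.0]]])
    ang = dihedral_angles(cis, np.array([0, 1, 2, 3]))
    assert ang[0] == pytest.approx(0.0, abs=1e-9)


def test_torsion_map_bins_and_normalization():
    ens = generate_synthetic_ensemble(400, 6, mode="uniform-torsion", noise=0.0, seed=5)
    res = torsion_population_map(ens, {"omega": ["A1", "A2", "A3", "A4"]}, bin_width=5.0)
    frac = res["marginals"]["omega"]
    assert frac.size == 72  # 5 degree bins over 360
    assert frac.sum() == pytest.approx(1.0, abs=1e-12)
    # uniform angles: no bin wildly over-populated
    assert frac.max() < 5.0 / 72.0


def test_torsion_map_joint_for_two_torsions():
    ens = generate_synthetic_ensemble(50, 8, mode="single-well", noise=0.3, seed=5)
    res = torsion_population_map(
        ens,
        {"phi": ["A1", "A2", "A3", "A4"], "psi": ["A2", "A3", "A4", "A5"]},
        bin_width=5.0,
    )
    assert res["joint"].shape == (72, 72)
    assert res["joint"].sum() == pytest.approx(1.0)


def test_torsion_map_invalid_bin():
    ens = generate_synthetic_ensemble(10, 6, mode="single-well", seed=0)
    with pytest.raises(ValueError):
        torsion_population_map(ens, {"w": ["A1", "A2", "A3", "A4"]}, bin_width=7.0)
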