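"""Conformer-ensemble geometry analytics.

Kabsch least-squares superposition, all-vs-all 2D-RMSD maps, cutoff
clustering of trajectory frames, window-averaged representative models and
torsion-angle population maps -- the operations used to reduce a long
unrestrained MD trajectory of a flexible oligosaccharide to a handful of
representative conformers with trajectory fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ConformerEnsemble",
    "ClusterReport",
    "kabsch_superpose",
    "rmsd2d_map",
    "cluster_by_cutoff",
    "representative_models",
    "torsion_population_map",
    "dihedral_angles",
]


@dataclass
class ConformerEnsemble:
    """frames x atoms x 3 coordinates (Angstrom) with atom/residue labels."""

    coords: np.ndarray
    atom_names: list[str]
    resids: np.ndarray | None = None
    resnames: list[str] | None = None
    frame_stride_ps: float | None = None  # ps between stored frames, if known
    occupancies: np.ndarray | None = None
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError("atom_names length must match the atom dimension")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.resids is None:
            self.resids = np.ones(self.coords.shape[1], dtype=int)
        else:
            self.resids = np.asarray(self.resids, dtype=int)
        if self.resnames is None:
            self.resnames = ["UNK"] * self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, names=None, resids=None) -> np.ndarray:
        """Atom indices matching name and/or residue-id filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            names = {names} if isinstance(names, str) else set(names)
            mask &= np.array([n in names for n in self.atom_names])
        if resids is not None:
            resids = {int(resids)} if np.isscalar(resids) else set(int(r) for r in resids)
            mask &= np.isin(self.resids, list(resids))
        return np.flatnonzero(mask)


@dataclass
class ClusterReport:
    """Per-frame cluster assignments (-1 = unassigned) with fractions.

    ``fractions[k]`` is the share of frames assigned to cluster ``k``;
    unassigned "exception" frames make the fractions sum to < 1.
    ``representatives`` holds one coordinate set per cluster when the
    clustering produced (or was seeded with) reference models.
    """

    labels: np.ndarray
    fractions: list[float] = field(default_factory=list)
    representatives: list[np.ndarray] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.fractions)


def _check_subset_coords(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry")


def kabsch_superpose(
    a: np.ndarray, b: np.ndarray, subset: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal least-squares superposition of ``b`` onto ``a``.

    Returns (rmsd, rotation, translation) with ``b @ R.T + t`` the
    superposed copy.  Uses the SVD form of the Kabsch solution with the
    determinant correction that excludes reflections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if subset is not None:
        a, b = a[subset], b[subset]
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shapes")
    _check_subset_coords(a)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    diff = b0 @ rot.T - a0
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return rmsd, rot, t


def rmsd2d_map(
    ensemble: ConformerEnsemble,
    subset=None,
    stride: int = 1,
) -> np.ndarray:
    """All-vs-all superposition RMSD matrix over (strided) frames.

    ``subset`` is an index array or a selection understood by
    :meth:`ConformerEnsemble.select` (atom-name list).  Symmetric with a
    zero diagonal by construction.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = _as_subset(ensemble, subset)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    frames = ensemble.coords[::stride, idx, :]
    n, n_at = frames.shape[0], frames.shape[1]
    if n < 2:
        raise ValueError("need at least 2 frames after striding")
    # batched closed form: rmsd^2 = (T_i + T_j - 2(s1 + s2 +/- s3)) / N with
    # s the singular values of the cross-covariance and the sign from its
    # determinant (reflection exclusion) -- identical to per-pair Kabsch.
    centered = frames - frames.mean(axis=1, keepdims=True)
    norms = (centered ** 2).sum(axis=(1, 2))
    h = np.einsum("jak,ial->ijkl", centered, centered)  # (n, n, 3, 3)
    h = h.reshape(-1, 3, 3)
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.sign(np.linalg.det(h))
    sign[sign == 0] = 1.0
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    sq = (norms[:, None] + norms[None, :] - 2.0 * trace.reshape(n, n)) / n_at
    out = np.sqrt(np.clip(sq, 0.0, None))
    out = 0.5 * (out + out.T)  # enforce exact symmetry
    np.fill_diagonal(out, 0.0)
    return out


def _as_subset(ensemble: ConformerEnsemble, subset) -> np.ndarray:
    if subset is None:
        return np.arange(ensemble.n_atoms)
    subset = np.asarray(subset)
    if subset.dtype.kind in "iu":
        return subset
    return ensemble.select(names=list(subset))


def cluster_by_cutoff(
    rmsd_map: np.ndarray, cutoff: float, min_cluster_size: int = 2
) -> ClusterReport:
    """Single-linkage grouping of frames whose pairwise RMSD <= cutoff.

    Frames are connected when within the cutoff; connected components of
    size >= ``min_cluster_size`` become clusters (largest first), smaller
    components remain unassigned exceptions.  Deterministic, and
    equivariant under frame relabeling.
    """
    rmsd_map = np.asarray(rmsd_map, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if rmsd_map.ndim != 2 or rmsd_map.shape[0] != rmsd_map.shape[1]:
        raise ValueError("RMSD map must be square")
    if not np.allclose(rmsd_map, rmsd_map.T, atol=1e-8):
        raise ValueError("RMSD map must be symmetric")
    n = rmsd_map.shape[0]
    adj = csr_matrix(rmsd_map <= cutoff)
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    order = [c for c in np.argsort(-sizes) if sizes[c] >= min_cluster_size]
    labels = np.full(n, -1, dtype=int)
    fractions = []
    for new, c in enumerate(order):
        labels[comp == c] = new
        fractions.append(float(sizes[c] / n))
    return ClusterReport(labels=labels, fractions=fractions)


def representative_models(
    ensemble: ConformerEnsemble,
    anchor_frames,
    window: int = 11,
    subset=None,
    cutoff: float = 2.0,
) -> ClusterReport:
    """Window-averaged reference models and nearest-reference assignment.

    For each anchor frame, the ``window`` frames centred on it (default 11,
    i.e. the anchor +/- 5) are superposed onto the anchor and averaged into
    a reference model; averaging after superposition avoids rotational
    smearing.  Every frame is then assigned to the reference it matches
    best, provided that RMSD is <= ``cutoff``; per-reference trajectory
    fractions are reported.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    idx = _as_subset(ensemble, subset)
    half = window // 2
    nf = ensemble.n_frames
    refs = []
    for anchor in anchor_frames:
        if anchor - half < 0 or anchor + half >= nf:
            raise ValueError(
                f"anchor {anchor} with window {window} falls outside the trajectory"
            )
        target = ensemble.coords[anchor, idx]
        stack = []
        for f in range(anchor - half, anchor + half + 1):
            _, rot, t = kabsch_superpose(target, ensemble.coords[f, idx])
            stack.append(ensemble.coords[f, idx] @ rot.T + t)
        refs.append(np.mean(stack, axis=0))
    labels = np.full(nf, -1, dtype=int)
    for f in range(nf):
        rmsds = [kabsch_superpose(ref, ensemble.coords[f, idx])[0] for ref in refs]
        best = int(np.argmin(rmsds))
        if rmsds[best] <= cutoff:
            labels[f] = best
    fractions = [float((labels == k).mean()) for k in range(len(refs))]
    return ClusterReport(labels=labels, fractions=fractions, representatives=refs)


def dihedral_angles(coords: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Signed IUPAC dihedral (degrees, [-180, 180)) for 4 atoms per frame."""
    p = coords[:, quad, :]  # (frames, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.rad2deg(np.arctan2(y, x))
    return (ang + 180.0) % 360.0 - 180.0


def torsion_population_map(
    ensemble: ConformerEnsemble,
    torsion_defs: dict,
    bin_width: float = 5.0,
) -> dict:
    """Joint and marginal torsion population histograms over [-180, 180).

    ``torsion_defs`` maps a torsion name to four atom names or indices.
    With the default 5 degree bins each marginal has 72 bins; fractions are
    normalized to sum to 1.  When two torsions are given their joint
    normalized 2D histogram is included, along with the free-energy-like
    surface -ln(p) (NaN where p = 0).
    """
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError("bin width must be positive and divide 360")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    angles = {}
    for name, atoms in torsion_defs.items():
        quad = np.concatenate([_resolve_single(ensemble, a) for a in atoms])
        if quad.size != 4:
            raise ValueError(f"torsion {name!r} must resolve to exactly 4 atoms")
        angles[name] = dihedral_angles(ensemble.coords, quad)
    marginals = {
        name: np.histogram(a, bins=edges)[0] / a.size for name, a in angles.items()
    }
    out = {"bin_edges": edges, "marginals": marginals, "angles": angles}
    names = list(angles)
    if len(names) >= 2:
        h = np.histogram2d(angles[names[0]], angles[names[1]], bins=(edges, edges))[0]
        joint = h / h.sum()
        with np.errstate(divide="ignore"):
            fes = np.where(joint > 0, -np.log(joint), np.nan)
        out["joint"] = joint
        out["free_energy"] = fes
        out["joint_names"] = (names[0], names[1])
    return out


def _resolve_single(ensemble: ConformerEnsemble, atom) -> np.ndarray:
    if isinstance(atom, (int, np.integer)):
        return np.array([int(atom)])
    hits = [i for i, n in enumerate(ensemble.atom_names) if n == atom]
    if len(hits) != 1:
        raise KeyError(f"atom {atom!r} resolves to {len(hits)} atoms (need exactly 1)")
    return np.array(hits)
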