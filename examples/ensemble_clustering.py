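"""Conformer-ensemble reduction: 2D-RMSD map, cutoff clusters, NOE distances.

Generates a synthetic two-conformation ensemble (70/30 mixture, rigid
motions plus coordinate noise), computes the all-vs-all superposition RMSD
map, extracts clusters at a 2 A cutoff, and reports an NOE-effective
<r^-6>^-1/6 distance, which is dominated by the frames where the two atoms
approach each other.
"""

import numpy as np

from lprosy import (
    cluster_by_cutoff,
    effective_noe_distance,
    generate_synthetic_ensemble,
    rmsd2d_map,
)

ens = generate_synthetic_ensemble(300, 12, mode="two-state", noise=0.2,
                                  seed=11, mixture=0.7)
rmsd = rmsd2d_map(ens)
print(f"frames: {ens.n_frames}, atoms: {ens.n_atoms}")
print(f"RMSD map: median {np.median(rmsd):.2f} A, max {rmsd.max():.2f} A")

report = cluster_by_cutoff(rmsd, cutoff=2.0)
for k, frac in enumerate(report.fractions):
    print(f"cluster {k}: {frac * 100:.1f}% of the trajectory")

d = effective_noe_distance(ens, ("A1", "A7"))
plain = np.linalg.norm(
    ens.coords[:, 0] - ens.coords[:, 6], axis=-1
)
print(f"\nA1-A7 linear-average distance  : {plain.mean():.2f} A")
print(f"A1-A7 NOE-effective distance   : {d:.2f} A  "
      "(<r^-6>^-1/6, weighted toward close-approach frames)")
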