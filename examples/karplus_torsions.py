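"""From vicinal couplings to torsion windows and restraint tables.

Evaluates the HCCH Karplus curve used for sialic-acid glycerol-chain
torsions, inverts an observed small coupling into candidate torsion
windows, and assembles a distance/torsion restraint table (distance
+/- 1 A, torsion +/- 30 deg, both branches for the degenerate +/-90 deg
case) ready for an external structure calculation.
"""

from lprosy import build_restraints, karplus_j, torsion_candidates

for omega in (0.0, 60.0, 90.0, 180.0):
    print(f"3J({omega:6.1f} deg) = {float(karplus_j(omega)):5.2f} Hz")

print("\nObserved 3J(H6,H7) < 2 Hz -> candidate torsion windows (deg):")
for lo, hi in torsion_candidates(0.9, tolerance=1.1):
    print(f"  [{lo:7.1f}, {hi:7.1f}]")

table = build_restraints(
    [{"atoms": "IIOH7-IIIH3", "distance": 3.2, "source": "looped NOESY"}],
    [{"atoms": "IH6-IC6-IC7-IH7", "target": 90.0, "degenerate": True}],
)
print("\ndistance restraints:")
print(table.distances.to_string(index=False))
print("\ntorsion restraints (degenerate branch doubled):")
print(table.torsions.to_string(index=False))
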