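# Methods

## Longitudinal model (NOESY engine)

Magnetization pools (labile OH/NH, water, non-exchanging CH) evolve under
the affine Bloch–McConnell/Solomon system dM/dt = A(M − M_eq) with

- A_ii = −(R1_i + Σ_j k_{i→j}),
- A_ij = σ_ij + k_{j→i} (i ≠ j),

all rates in s⁻¹.  The input R1 is the *total* longitudinal auto-relaxation
rate of a pool (the Solomon ρ); cross-relaxation enters only off-diagonal.
With this sign convention the two-pool transfer of a unit source deviation
is (e^{−(ρ−σ)t} − e^{−(ρ+σ)t})/2, so σ < 0 — the fast-tumbling,
positive-NOE regime of small saccharides — produces cross-peaks of
opposite sign to the diagonal.  A single global `sigma_sign` switch flips
the display convention.  Exchange rates obey detailed balance
k_{a→b} M_eq,a = k_{b→a} M_eq,b; reverse rates are completed automatically
from pool sizes, the exchange sub-generator conserves total magnetization
(zero column sums), and thermal equilibrium is the unique stable fixed
point of the affine system.  Propagation is by `scipy.linalg.expm`, exact
to machine precision for this linear model.

Water is a finite but large pool (default 10³ × the labile pool, a choice
exposed as a parameter because measurements of it do not exist); the
infinite-reservoir limit is recovered either by raising the ratio or by
the `clamp_water` flag, which pins water at equilibrium so it can carry no
label.

## Experiment model

Selective pulses are ideal: they address the labile pools only and leave
water and aliphatic pools untouched.  The Ramsey t₁ evolution is amplitude
labeling (cos Ω t₁); amplitudes are evaluated at the t₁ = 0 increment,
equivalent to comparing integrated peak amplitudes, which keeps lineshape
physics out of the model entirely.  The labeled packet L therefore evolves
homogeneously, L(t) = e^{At} L₀, and amplitudes are reported as fractions
of the source pool's equilibrium magnetization.  Multiple selective
targets are propagated independently (the model is linear).

**Looping and projection.**  Each loop re-labels the labile source and
zeroes its transverse memory.  The freshly labellable amplitude is the
magnetization that exchange brought in from water since the previous
projection,

    fresh(τ) = [k_out·M_eq/(R1 + k_out)] · (1 − e^{−(R1 + k_out)τ}),

obtained from du/dt = k_out·M_eq − (R1 + k_out)u, u(0) = 0.  Polarization
a projected spin recovers through the lattice, and magnetization still
carrying an earlier label, are treated as scrambled: re-modulated by the
next Ramsey block, they drop out of the first-order phase-cycled signal.
This bookkeeping makes solvent exchange the *only* source of looped gain:
with k_out = 0 loops beyond the first inject nothing, a single loop is
exactly one conventional mixing, and the optimizer correctly collapses to
l₁\* = 1.  An earlier variant that allowed lattice-recovered polarization
to be re-labeled produced steady-state-NOE-like gains (~1.6×) even without
exchange; that behavior belongs to repetition-rate bookkeeping across
scans, not to the single-scan comparison made here, and was removed.
Accumulated destination z-magnetization persists across loops and keeps
relaxing — the reported gains already include that loss channel.

## TOCSY engine

DIPSI2 is idealized as continuous isotropic mixing H = 2πJ (I₁·I₂).
Longitudinal transfer closes on the four-dimensional operator subspace
(I1z, I2z, ZQy, W): the zero-quantum coherence mediates the transfer
(sin²(πJτ) in the no-exchange, no-relaxation limit; complete at
τ = 1/(2J)), relaxes at (R2₁+R2₂)/2, and is destroyed by the stochastic
exchange jump at k_ex, which also swaps z-polarization with the water
scalar W at the detailed-balance rates.  The identity component is
invariant under every term and is not tracked.  TOCSY quenching at
k_ex ≳ J — the "averaging away" of the coupling — emerges from this jump
model.  Looping follows the same projection bookkeeping as NOESY, with
the zero-quantum coherence additionally zeroed at each projection.  A
two-spin subsystem plus scalar water reservoir is the model size; relayed
(three-spin) transfer is out of scope for the quantitative claims.

## Schedule optimization

Everything is deterministic grid search: conventional mixing on an 81-point
grid (cap 400 ms NOESY / 1 s TOCSY — the ~100 ms practical NOESY cap at
fast exchange emerges from the optimization rather than being imposed)
followed by bounded scalar refinement between the best point's neighbours,
guarded so refinement can never return less than the grid optimum; the
looped schedule by a joint scan over loop count (1–30, covering the 10–14
loops typical of practice) and per-loop mixing (5–100 ms in 5 ms steps,
refined ×10 around the optimum).  Per candidate mixing the propagator is
exponentiated once and reused across loop counts.  Cells of an enhancement
map where no transfer exists propagate as NaN, never as 0.

**Shape of the enhancement surface.**  Gains rise with k_ex from 1 at the
repolarization-limited slow end and saturate at fast exchange near the
loop-count/destination-relaxation ceiling.  The experimental decline at
very fast exchange comes from the labile resonance broadening into water
and defeating *selective* labeling; with the ideal selective pulses
assumed here that mechanism is absent, so the simulated surface plateaus
instead of turning over, and the tests assert growth and finiteness
rather than an interior maximum.  With a finite water pool, label that
leaked into water dribbles back over hundreds of loops and postpones the
plateau; the plateau property is therefore tested with water clamped.

## Glycan analysis

- **Karplus:** ³J(ω) = C + A cos²ω + B cos ω with the HCCH defaults
  (C, A, B) = (0.48, 10.18, −0.03) Hz.  The inverse reading returns every
  ω ∈ [−180°, 180°) within a tolerance of an observed J as merged
  intervals (0.01° scan, seam-merged); analytic extrema of the quadratic
  in cos ω bound the curve and short-circuit impossible observations.
- **NOE distances:** (mean over frames of r⁻⁶)^{−1/6}; for diastereotopic
  groups the per-frame shortest distance enters, matching how grouped
  NOEs are tabulated.  Bounded by the per-frame min/max (power-mean
  inequality), frame-permutation invariant.
- **H-bonds:** geometric criterion d_DA ≤ 3.0 Å AND θ(D–H···A) ≥ 135°
  (angle at the hydrogen, 180° linear), inclusive at the boundary;
  occupancies are fractions of frames.
- **Arrhenius scaling:** k(T) = k_ref·e^{−Ea/R (1/T − 1/T_ref)}.  The
  activation energy is a required input — hydroxyl exchange barriers
  depend on pH and catalysis and no single value is defensible as a
  default.
- **Temperature coefficients:** least-squares slope in ppb/K (negative =
  upfield with warming); |slope| of a few ppb/K flags hydrogen-bonded
  protons.
- **Diffusion:** nonlinear fit of A(g) = A₀ e^{−Dγ²g²δ²(Δ−δ/3)}
  (log-linear initialization, exact on noiseless data); the ratio
  D_ref/D_analyte equals Rh_analyte/Rh_ref at matched conditions.
- **Restraints:** distance ± 1 Å (floored at 0) and torsion target ± 30°
  wrapped to [−180°, 180°); torsions flagged degenerate emit both ± branches
  because the even Karplus curve cannot distinguish them.

## Ensemble geometry

Kabsch superposition uses the SVD solution with the determinant correction
(no reflections); degenerate (<3 atoms or collinear) selections are
rejected.  The 2D-RMSD map is computed in closed form from batched
singular values of the pairwise cross-covariances — algebraically
identical to per-pair Kabsch (cross-checked in the tests) and fast enough
for thousands of frames; symmetry and zero diagonal are enforced exactly.
Cutoff clustering is single linkage (connected components of the
"RMSD ≤ cutoff" graph): the visual-inspection grouping of a 2D-RMSD map
needs a deterministic stand-in, single linkage is the closest formal
analogue, and it is deliberately isolated behind `cluster_by_cutoff` so it
can be swapped.  Components below `min_cluster_size` (default 2) remain
unassigned "exceptions", so cluster fractions may sum below 1.
Representative models average an odd window (default 11 frames, the
anchor ± 5) after superposing each frame onto the anchor — averaging
before superposition would smear rotations — and every frame is assigned
to its best reference when within the cutoff.  Torsions are signed IUPAC
dihedrals in [−180°, 180°); population maps default to 5° bins (72 per
marginal), normalized to 1, with an optional −ln p surface.

## Synthetic data

The spin-system presets encode the study conditions: hydroxyl–water
exchange drawn log-uniformly from 10–1000 s⁻¹ (the ambient-temperature
saccharide range), small-molecule relaxation (R1 ≈ 1 s⁻¹, R2 ≈ 8–20 s⁻¹),
σ(OH,CH) = −0.05 s⁻¹, J = 5 Hz, water 10³ × the labile pool.  Ensemble
fixtures generate a rigid template with Gaussian coordinate noise;
two-state mode mixes two templates whose *superposed* RMSD is calibrated
to the requested separation (default 5 Å) and applies a random rigid
motion per frame so superposition is non-trivial; uniform-torsion mode
rotates a four-atom dihedral uniformly.  All randomness flows through a
single seeded generator per call.

What the synthetic conditions do not emulate: real pulse shapes and their
finite selectivity, lineshapes and overlap, spin diffusion among many
protons, NUS reconstruction, and real conformational dynamics.  Passing
tests therefore validate the transfer/exchange physics and the geometry
operators, not the appearance of real spectra.

## Numerical choices and problem sizes

Matrix exponentials via `scipy.linalg.expm` (3–6 dimensional generators);
the independent oracle in the tests is fixed-step RK4 at dt = 10 µs, whose
step error is orders of magnitude below the 10⁻⁶ comparison tolerance
(forward Euler cannot reach that tolerance at any affordable step for
these rates).  Optimizers are noise-free and deterministic; ties at equal
amplitude resolve to the earlier grid point.  Test and acceptance
simulations use grids of a few hundred cells and ensembles of 200–500
frames × 10–12 atoms, sizes at which the full suite runs in seconds on one
core while leaving the statistical checks (binomial recovery at n = 500)
meaningful.

## Known limitations

Ideal pulses mean no selectivity collapse at extreme exchange rates (see
above) and no water-suppression artifacts; the NOESY engine is
longitudinal-only (R2 is used by the TOCSY zero-quantum term only);
diagonal-peak enhancements are reported but are less constrained by the
model than cross-peak ones; no lineshape or FID synthesis; restraint
tables are produced for external structure-calculation engines, not
consumed.
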