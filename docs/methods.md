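# Methods

This note records the models, numerical choices and limitations behind
`ringfit`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Scattering model

Bead models are point-scatterer sets with per-bead amplitudes `w`
(default 1.0 per residue-level bead; a heavier weight, e.g. 1.4, may be
assigned to glycan beads).  Intensities follow the Debye formula with the
self terms equal to `wᵢwⱼ`, so `I(0) = (Σw)²`.  Two evaluation paths exist:

- an exact double sum (used below ~600 beads and for invariance tests);
- a pair-distance histogram with 0.5 Å bins and a precomputed
  `sinc(q·r_bin)` matrix (used in refinement loops).  The binning
  approximation stays within ~10⁻³ relative error for the q range used
  here; its one observable side effect is that a rigid rotation can move
  distances across bin edges, so "exact" isometry invariance only holds in
  the exact mode.

No solvent-excluded-volume or hydration-shell term is included.  Every
comparison with data therefore fits a free scale factor and, optionally,
an additive constant, by weighted linear least squares; the reduced χ²
uses an `n − k` divisor (`k` = number of fitted nuisance parameters).
Absolute intensity calibration is carried as a metadata flag only, because
the free scale makes it irrelevant downstream.

## Guinier analysis

The fit is a weighted straight line of `ln I` against `q²` on the largest
low-q window satisfying `q·Rg ≤ limit`, iterated to self-consistency
(tolerance 10⁻³ Å, at most 50 iterations).  The default window limit is
0.8: the straight-line fit has a systematic truncation bias growing
roughly quadratically with the limit — about +1.7% in Rg at `q·Rg = 1.3`
for compact sphere-like particles, versus below 1% at 0.8 (this is
measured by the sphere-oracle tests).  The limit is configurable; very
noisy data may warrant widening it at the cost of that bias.  Aggregation
is flagged when the five lowest-q standardized residuals average above +1,
the classic upturn signature.

## Indirect Fourier transform

`p(r)` is expanded on 101 equally spaced nodes with both endpoints pinned
to zero; the σ-weighted linear system is regularized by a second-difference
(Tikhonov) penalty.  The regularization weight is chosen by generalized
cross-validation over a 33-point logarithmic grid spanning eight decades
around the natural scale `tr(AᵀA)/tr(D₂ᵀD₂)`.  Small negative ripple
(~1% of max p) is tolerated rather than imposing a non-negativity
constraint, which would turn the linear solve into a QP for no benefit at
this accuracy level.  The default fit range is `q ≤ 0.27 Å⁻¹`, the region
where data of the targeted quality are information-rich; it is
configurable everywhere.

### D_max selection

`scan_dmax` runs the IFT over a candidate grid and selects the smallest
value whose fit χ² lies within `max(5% of the minimum, sqrt(2/n))` of the
plateau minimum — the second term is one standard deviation of a reduced
χ², without which noise-driven drift of the plateau pushes the selection
to ever larger `D_max` — and whose `p(r)` shows no forced truncation dip
(tail excursion deeper than half of max p; genuine truncation dips are of
order the peak height, while edge ringing of noisy solutions stays well
below half).  On noise-free spheres the rule selects `2R` exactly; on
noisy synthetic oligomers it lands within ~5–7% of the model `D_max`,
typically a little low because the outermost distances carry little mass.
This softness is inherent to regularized IFT and is why vertex separations
are read from `p(r)` peaks, not from `D_max`.

## Rigid-body refinement

An assembly is one protomer (rigid bodies + placements) with symmetry
order n about the z axis; callers pre-orient input models.  The objective
is `χ² + w_r·E_restraint + w_c·E_clash` with `w_r = w_c = 1` (all terms on
the reduced-χ² scale).  Restraints are flat-bottom quadratics between
named anchor beads; a helper builds linker restraints with target
3.8 Å × (gap residues + 1) and 20% tolerance, the Cα virtual-bond rule.
Clashes are quadratic in the overlap below 3.8 Å between beads of
different bodies.

The optimizer is Metropolis simulated annealing with several pragmatic
stages, each of which earned its place against observed failure modes:

1. **Pre-relaxation**: greedy minimization of restraint + clash energy
   only (cheap, no scattering), so annealing starts from a connected,
   clash-free configuration instead of a state dominated by huge linker
   violations.  Only small moves are used here — the penalty terms are
   blind to body roll, and large rotations guided by them alone would
   scramble orientations.
2. **Annealing**: per-body Gaussian rotations/translations (σ = 10°/5 Å,
   shrinking with temperature), occasional large-angle rotations while
   hot and occasional concerted whole-protomer rotations; geometric
   cooling.  The auto start temperature targets ~50% initial acceptance
   but is capped at 50 score units: on the steep χ² landscapes of
   low-noise profiles an uncapped temperature turns the walk into basin
   roulette and forgets good starts.
3. **Quench and polish**: a greedy random quench with decaying step size,
   then a deterministic per-body compass (coordinate pattern) search.
   Random-walk moves alone stall at χ² ≈ 2–20 in narrow curved valleys.

The landscape genuinely contains discrete near-degenerate basins
(an arm bowed to the wrong side of its chord, an eye rolled about the axis
through its two linker attachment points).  Individual runs can and do
get trapped; this is handled at the protocol level: `run_batch` refines
many randomized starts (uniform rotations ≤ 60°, translations ≤ 30 Å,
clash-free), clusters all runs by the RMSD of their anchor–anchor distance
vectors (single linkage, 10 Å cutoff), excludes runs with χ² above twice
the best from statistics, and reports the medoid of the largest cluster
among the remaining runs.  The objective is invariant under global
rotation about z (and translation along z for n > 1); this degeneracy is
documented rather than removed, and the clustering metric (internal
distances only) is insensitive to it.

## The α statistic

The gyration tensor is unweighted (no mass weighting; recorded in output
metadata).  Axis signs are canonicalized (largest-magnitude component
positive, right-handed set), the smallest-eigenvalue axis is the "thin"
direction, and α is the protomer-averaged angle between the eye vector
(anchor `S345` → `A402`, matching the convention that the vector lies in
the vertex plane) and that axis, with the flip rule mapping means below
90° to 180° − mean.  A warning is raised when the two smallest eigenvalues
agree within 1%, where the thin axis — and hence α — is ill-defined.

## BME reweighting

Weights minimize `χ²_red/2 − θ·S_rel` with `S_rel = −Σ wᵢ ln(wᵢ/wᵢ⁰)`,
solved in the dual (`wᵢ ∝ wᵢ⁰ exp(−λ·Iᵢ)`) by L-BFGS from λ = 0, with a
free scale (and optional constant) refit between dual solves.  θ weights
the *reduced* χ² (n-point divisor), so its useful range is roughly
10⁻³–10⁴ independent of the number of data points.  Convergence is
declared at dual-gradient norm below 10⁻⁶; non-convergence returns the
best iterate with a flag.  `scan_theta` reports the (φ_eff, χ²) L-curve
and flags its maximum-curvature elbow, computed on range-normalized
coordinates with near-duplicate plateau points skipped.

## Synthetic oligomers

The generator emulates flat cyclic n-mers (n = 1–8) built from a compact
eye at each vertex plus a three-cluster connecting arm:

- Vertices sit on a ring with neighbor separation `eye_sep`
  (165/180/195 Å for the fp2/fp3/fp4 presets, mirroring the dimer, trimer
  and tetramer study conditions).  Eyes are flattened ellipsoids
  (semi-axes 1.0/0.75/0.3 × 20 Å) whose plane contains the eye vector,
  tilted by `alpha_true` to +z (presets 150°/128°/109°).
- Arms are straight peripheral edges for n ≥ 3 (trimers and tetramers are
  polygons with near-straight connections), antiparallel ±40 Å bowed arcs
  for the dimer (reproducing the ~80 Å arm-separation feature in its
  p(r)), and a pretzel loop for the monomer.  An out-of-plane parameter
  bows arm midpoints in z.
- The eye carries ~71% of the protomer mass (160 beads vs 3 × 22),
  matching a 5-of-7-domain vertex; with substantially heavier arms the
  neighbor vertex–vertex p(r) peak of the trimer is swallowed by arm
  chords and no longer reads out `eye_sep`.
- Bead fill uses an unscrambled Halton sequence, so noise-free pipelines
  are bit-reproducible; only profile noise consumes the random stream.
- The noise model is
  `σ(q) = eff·I(0)·(0.001 + 0.02 (q/q_max)²) + eff·0.01·I(q)` with
  `eff = noise_level` (floor 0.01 when noise-free), mimicking beamline
  data that are precise at low q and noisy at high q.  Its calibration is
  verified by the reduced-χ² test (mean 1.0 ± 0.25 over 50 replicates).
- `reference_restraints` builds the connectivity restraints a refinement
  against a synthetic target needs: eye→arm and arm→arm linkers per
  protomer, the head-to-tail closure to the next protomer's eye, and a
  disulfide-like eye–arm tie (tolerance 1.5 Å) placed off the linker axis
  so that eye roll is constrained.  Targets are the truth's own anchor
  distances (tolerance 20%, k = 10), so the truth scores zero.

What the generator does **not** emulate: atomic detail and glycans,
solvent contrast and hydration shells, inter-frame correlation of
SEC-SAXS, polydispersity/oligomer mixtures, and flexible linkers.
Passing recovery tests therefore demonstrate that the inference machinery
is correct and well calibrated under the stated geometry and noise model —
not that real heterogeneous data will be fitted to the same χ².

## Problem sizes and defaults

Recovery experiments run at reduced bead counts (40 per eye, 8 per arm
cluster, ~230 beads for a trimer) with a shortened annealing schedule
(8000 moves, cooling 0.95 per 40 moves, 2000-move quench, 6000-eval
polish); ten-run batches then finish in a couple of minutes per oligomer
on one CPU while recovering vertex separations within 5% and α within
10°.  The full-fidelity defaults (160-bead eyes, 20000 moves, cooling
0.97 per 100 moves) remain available through `RefineConfig` and the
generator parameters.

## Known limitations

- χ² against real measured curves will differ from bead-model expectations
  because of the missing hydration/contrast terms.
- `D_max` from noisy data is soft by ±5–10% (see above).
- α is only meaningful for flat assemblies; the degeneracy warning should
  be heeded.
- The annealer's score trace is non-increasing only at best-so-far
  checkpoints; individual runs may remain in side basins by design, with
  reliability coming from the batch protocol.
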