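# ringfit

Analysis of small-angle X-ray scattering (SAXS) data from flat, cyclic
protein oligomers — ring-shaped assemblies such as the properdin dimer,
trimer and tetramer, built from compact "eye" vertices joined by thin
multi-domain arms.

For such particles the interesting questions are geometric: how far apart
are the vertices, how planar is the ring, and which way do the
ligand-binding faces at the vertices point?  `ringfit` answers them with a
self-contained pipeline:

- **Model-free analysis** — profile validation, logarithmic rebinning,
  iterative Guinier fits (`ln I = ln I₀ − q²Rg²/3` on a window
  `q·Rg ≤ limit`), and a regularized indirect Fourier transform (IFT) of
  `I(q) = 4π ∫ p(r) sinc(qr) dr` to the pair distance distribution `p(r)`,
  with automatic `D_max` selection and peak/shoulder detection.  Vertex
  separations appear directly as high-`r` peaks in `p(r)`; a planar C₄ ring
  betrays itself by a diagonal feature at √2 times the edge peak.
- **Rigid-body refinement** — coarse bead models organized into rigid
  bodies, scattered through the Debye formula
  `I(q) = Σᵢⱼ wᵢwⱼ sin(qr₍ᵢⱼ₎)/(qr₍ᵢⱼ₎)`, assembled with C_n symmetry about
  z, and refined against data by simulated annealing under flat-bottom
  distance restraints and a soft-sphere clash penalty.  Batches of
  independent runs are clustered and a representative model selected, with
  high-χ² runs excluded from statistics.
- **Binding-site orientation (α angle)** — the angle between a per-protomer
  "eye vector" (two named anchor beads) and the smallest principal axis of
  the assembly, averaged over protomers and flipped into [90°, 180°]:
  α = 180° means all binding faces point the same way out of the ring
  plane, α = 90° means they lie in the plane.
- **Ensemble reweighting (BME)** — Bayesian maximum entropy reweighting of
  per-member calculated curves against a measured profile, trading reduced
  χ² against relative entropy via a regularization parameter θ, solved in
  the convex dual.
- **Synthetic truth models** — a deterministic generator of "eye + arm"
  cyclic oligomers with designed vertex separation and tilt plus a
  calibrated noise model, so the entire pipeline is testable end to end
  without any external data.

## Worked example

Generate a synthetic trimer (designed vertex separation 180 Å, tilt 128°),
simulate a 1%-noise profile and analyze it:

```sh
ringfit simulate --preset fp3 --noise 0.01 --seed 11 sim/
ringfit pr --dmax auto sim/profile.dat sim/profile.pr
```

which prints

```
dmax = 227.3 A  Rg = 94.54 A  chi2 = 0.777
  peak at 13.9 A (height 384)
  peak at 45.0 A (height 167)
  peak at 89.1 A (height 165)
  peak at 178.4 A (height 523)
```

Reading the output: the reduced χ² ≈ 0.8 says the regularized `p(r)`
reproduces the data within its uncertainties.  The peaks at small `r` are
intra-vertex (~14 Å bead packing, ~45 Å across the vertex) and arm-chord
distances; the dominant high-`r` peak at 178.4 Å is the neighbor
vertex–vertex separation, within 1% of the designed 180 Å.  The same library calls are available in Python
(`ringfit.ift_pr`, `ringfit.find_peaks`, …), and `ringfit run config.yml`
executes the whole pipeline (profile → Guinier → p(r) → refinement batch →
metrics) from one declarative config with a single master seed.

The refinement stage is exercised the same way: `ringfit.run_batch`
refines ten randomized starts of the known rigid bodies against the
simulated profile and returns a representative model whose vertex
separation and α angle can be compared with the designed truth (see
`tests/test_acceptance.py::test_recovery_experiment`).

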