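# Methods

## Physical model and scope

`volmap` treats the torso as a homogeneous, isotropic, quasi-static volume
conductor. Two inverse formulations are implemented over the same
body-surface data g (electrodes × samples, mV):

* **Volumetric (source) formulation.** The potential solves the Neumann
  Poisson problem −∇²φ = f in Ω with insulated boundary, where
  f = ∇·(σᵢ∇Vₘ) is a scalar surrogate of the net transmembrane current
  density, nonzero only in the myocardium Ω_H. The solvability of the
  Neumann problem requires ∫_Ω f dV = 0 at every instant; this *existence
  condition* is treated as an exact equality constraint of the inverse
  problem, not a soft penalty. Transfer entries are Green's-function values
  G(yᵢ, xⱼ): the response at heart node xⱼ to a unit point load at
  electrode yᵢ with uniform return flux −1/Area over the torso surface
  (compatible by construction). With unit conductivity inside the operator,
  absolute source units are arbitrary; only relative amplitudes and timing
  are interpreted.

* **Epicardial (potential) formulation.** The classical Cauchy problem for
  Laplace's equation in the annulus between heart and torso surfaces,
  discretized by collocation BEM, yields A with g = A h for epicardial
  potentials h.

Both inverse problems use zero-order Tikhonov regularization with a single
λ for the whole recording, selected on the L-curve.

## Discretization

* **FEM**: first-order (P1) tetrahedral elements. The Dirac electrode load
  is lumped to the nearest boundary vertex (sub-edge-length position
  error). The pure-Neumann stiffness has a one-dimensional constant null
  space; it is handled exactly by factorizing the saddle-point system
  [[K, 1],[1ᵀ, 0]] once (sparse LU) and reusing the factorization across
  electrodes and time samples. Assembling B therefore costs M solves
  (M = electrode count), not P (heart nodes) — the adjoint formulation.
* **Existence-condition quadrature**: the discrete form of ∫_Ω f dV is the
  single row wᵀ of lumped nodal volumes (each fully myocardial tet
  contributes volume/4 to its nodes). The same w appears in the forward
  load (b = w ⊙ f) and in predictions (g = B diag(w) f), which makes the
  discrete reciprocity between `forward_solve` and `B` *exact* — verified
  to 1e-14 in tests — and makes the row gauge of B provably irrelevant for
  any feasible source.
* **Source surrogate**: the weak form of ∇·(σᵢ∇Vₘ) over the myocardial
  tets with a no-flux closure at the heart boundary, converted to a density
  by dividing by w. Stiffness columns sum to zero, so w·f vanishes
  identically at every sample — generated data always satisfy the
  constraint the solver enforces.
* **BEM**: vertex collocation with lumped linear basis; double layers use
  exact triangle solid angles (van Oosterom–Strackee), single layers use
  centroid quadrature with one-level subdivision near the surface and an
  analytic vertex integral on adjacent triangles. All diagonal
  (solid-angle + singular) terms are fixed by the row-sum closure identity,
  which transfers constant potentials exactly (machine precision) instead
  of to first order. The epicardial normal derivative is eliminated through
  the heart single-layer block.
* **Geodesics**: shortest paths over the mesh edge graph (Dijkstra), with
  Euclidean edge weights; on surfaces for surface quantities and on the
  myocardial tet edge graph for localization errors of *both* methods
  (off-mesh points are snapped to the nearest eligible node and the
  snapping offsets added). Edge-graph paths overestimate true geodesics by
  a bounded lattice-inflation factor (≤ ~10% on the meshes used); the same
  convention is applied to both methods, so comparisons are unaffected.

## Inverse solver

The constrained problem min_{wᵀf=0} ‖B diag(w) f − g‖² + λ‖f‖² is solved by
rotating the unknowns with the orthonormal Householder basis of null(wᵀ):
the reduced problem is an ordinary Tikhonov fit (one SVD, reused over the λ
grid and all time samples), and the back-rotation restores f with the
constraint satisfied to machine precision. Because measured potentials only
carry inter-electrode differences, both the operator and the data are
re-referenced to zero mean over the electrode axis before fitting; together
with the null-space reduction this makes the solution invariant to the
Neumann gauge (per-row constants of B).

λ grid: 60 log-spaced points over [1e-8, 1e2] × σ₁², where σ₁ is the
largest singular value of the (reduced, referenced) operator. The L-curve
corner is the maximum finite-difference curvature of the
(log residual-norm, log solution-norm) curve over the grid; flat/degenerate
curves fall back to the smallest λ with a warning. Residual norms are
non-decreasing and solution norms non-increasing in λ — asserted on every
run. Scaling g by c scales f̂ by c; with an explicit λ this is exact, and
with L-curve selection the chosen λ is unchanged because the grid depends
only on the operator and curvature is shift-invariant in log space.

## Activation mapping

Per node: low-pass smoothing (order-4 Butterworth, default 40 Hz,
zero-phase), polarity orientation, then a transform that convolves the
slope-derived sample weights with a bank of symmetric raised-cosine
wavelets (half-widths ½×, 1×, 2× of twice the estimated median deflection
width); the LAT is the argmax of the transformed amplitude. On a clean
single-deflection signal this coincides with the steepest-slope instant
within one sample.

Polarity and slope weighting: extracellular potentials mark activation by
their steepest *negative* deflection, so potentials are processed as-is
with negative-slope weighting; Vₘ-like signals are negated first. A
volumetric source field, however, contains sources *and* sinks — the sign
of the activation deflection at a node depends on local wavefront geometry
— so a one-sided slope convention is ill-defined there. For `source`
polarity the transform therefore weights the rectified slope |dV/dt|
(identical to the one-sided rule on any single-deflection signal, but
polarity-invariant). Both weightings are available explicitly.

The earliest-activation site is the arithmetic centroid of the nodes with
LAT strictly below the 10th percentile (linear-interpolation percentile);
if the strict subset is empty (all-tied minimum) the tied minimum nodes are
used. The same rule defines the *true* origin site from ground-truth LATs,
mirroring how simulated beat origins are annotated.

## The synthetic phantom

The generator replaces anatomical imaging and bidomain simulation with a
deterministic desk-scale stand-in:

| parameter | default | rationale |
|---|---|---|
| torso radius | 150 mm | adult thorax scale |
| heart shell outer / inner radius | 60 / 25 mm | the shell models the **whole biventricular mass**; its 35 mm thickness spans free-wall (shallow) to septal (deep) source depths |
| heart center offset | (55, 0, 0) mm | anterior heart: epicardium ~35 mm behind the chest wall |
| basal truncation | z > 30 mm above heart center has no myocardium | valve-plane analog; the epicardial BEM mesh remains the full closed sphere, like clinical meshes that cover electrically silent bases |
| electrodes | 128, Fibonacci lattice snapped to distinct torso vertices | high-density vest analog |
| torso surface / heart volume edge | ~13 mm / 7 mm | vest-resolution torso; desk-scale myocardium (large studies use ~3.5 mm; coarsening changes resolution, not physics) |
| conduction velocity | 0.8 mm/ms | ventricular myocardium |
| upstroke duration | 5 ms | QRS-relevant upstroke width |
| sample rate / duration | 1 kHz / 260 ms | covers full activation of the shell |
| SNR | 20 dB additive white Gaussian, **global** (all electrodes and samples), realized exactly by rescaling | single-number noise specification; per-lead SNR is not modelled |

Activation is eikonal on the myocardial edge graph (LAT = graph distance /
velocity); Vₘ is a clamped quintic-smoothstep upstroke centred at the LAT —
chosen over a logistic because it is *exactly* constant at rest and
plateau, monotone, and has its maximum derivative exactly at the LAT;
repolarization is omitted (LAT estimation depends only on the upstroke).
Optional heterogeneous forward conductivities (blood 0.7, lungs 0.0389,
liver 0.1667, torso 0.8 S/m) exist to create forward/inverse model mismatch
in robustness studies; the default forward model is homogeneous.

What the phantom does **not** emulate: real ventricular anatomy (outflow
tracts, two cavities, septal insertion), fiber-orientation anisotropy,
ionic-model dynamics, ECG morphology (P/T waves), electrode-contact
artifacts, and geometry-estimation error. Passing benchmarks here therefore
demonstrate correctness and the *mechanisms* of the volumetric advantage
(depth sensitivity, basal-cap distortion of the surface method), not
clinical performance.

## Benchmark protocol

16 ectopic beats — 6 "base-analog" (outer wall near the truncation rim),
6 "septal-analog" (inner, endocardial-facing wall), 4 "free-wall-analog"
(outer equatorial wall) — are placed by deterministic farthest-point
sampling within each candidate band. Per case, the same conditioned 20 dB
signals feed both methods; localization error is measured from the true
percentile-centroid origin to each method's estimated site, in straight-line
mm and in myocardial edge-graph mm. The desk-scale runs reported by
`scripts/acceptance.py` use 5 noise seeds (the acceptance test uses 10);
the whole benchmark runs in minutes on one CPU.

## Numerical choices and degenerate inputs

* Meshing is Delaunay-based over surface vertices plus a body-centred-cubic
  filler lattice, valid for the star-shaped phantom domains generated here;
  near-zero-volume slivers are dropped, elements outside the torso
  discarded, and all tets oriented positive. A constrained quality mesher
  is out of scope; interior surfaces are honoured through their vertices.
* Flat (zero-variance) node signals are masked invalid in LAT maps rather
  than raising; all-equal LAT fields fall back to the full valid set for
  the earliest site.
* Channel QC flags flatlines and robust RMS outliers (median/MAD z-score
  with a relative floor so identical channels neither divide by zero nor
  hide a gross outlier); it refuses to flag more than half the channels
  unless explicitly overridden, and raises if all channels fail.
* Incompatible source fields (|w·f| above 1e-8 of the recording-wide source
  scale) are rejected by the forward solver rather than silently projected.
* The comb filter is realized as cascaded IIR notches (Q = 35) at
  50/100/150/200 Hz; the baseline high-pass is order-3 Butterworth at
  0.67 Hz; all stages are applied forward-backward (zero phase) because LAT
  estimation is phase-sensitive — quoted attenuations therefore double in
  dB relative to single-pass designs.

## Known limitations

* The analytic sphere oracle bounds operator error only for concentric
  spherical geometry; eccentric/truncated configurations are validated by
  reciprocity and convergence checks instead.
* Minimum-norm (zero-order Tikhonov) volumetric reconstructions are
  spatially smeared and mildly depth-biased; localization relies on the
  percentile-centroid rule being robust to this. Anatomical priors,
  temporal regularization, or sparsity are deliberately out of scope.
* Edge-graph geodesics inflate true distances by up to ~10% at the default
  mesh resolutions; both methods are scored with the same convention.
* The infarct metrics (17-segment assignment, TAT-outlier fibrosis rule
  with median + 2·MAD threshold, Jaccard segment overlap with a recall
  variant) follow field conventions where the exact definitions are not
  standardized; all thresholds are configurable.
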