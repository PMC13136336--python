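# volmap — volumetric electrocardiographic imaging

`volmap` reconstructs three-dimensional cardiac electrical activity from
body-surface potential recordings. It implements **volumetric ECGI** — an
inverse *source* problem that estimates a scalar current-source field
throughout the myocardial volume via Green's functions of a Neumann Poisson
problem — side by side with the classical **epicardial ECGI** baseline that
solves a Cauchy problem for Laplace's equation and recovers potentials on
the heart surface only. On top of either reconstruction it computes local
activation time (LAT) maps, earliest-activation sites for ectopic-beat
localization, and evaluation metrics (Euclidean/geodesic localization
errors, AHA 17-segment infarct characterization).

It is aimed at researchers in computational cardiac electrophysiology and
bioelectric inverse problems who want a self-contained, fully synthetic
test bed: the package ships a phantom generator (spherical torso, eccentric
truncated myocardial shell, 128-electrode lattice, eikonal activation,
bidomain-surrogate sources, FEM forward projection, calibrated noise), so
every experiment runs from scratch with no external data.

## The model

The torso Ω is a homogeneous quasi-static volume conductor. Cardiac
activity enters as a net current-source density

    f(x) = ∇·(σᵢ ∇Vₘ(x)),   x ∈ Ω_H   (zero outside the myocardium)

and the electric potential φ obeys the Neumann Poisson problem

    −∇²φ = f  in Ω,   ∂ₙφ = 0 on ∂Ω,   ∫_Ω f dV = 0,

the last identity being the existence (compatibility) condition. Each
transfer-matrix entry B(i,j) is the Green's function G(yᵢ, xⱼ) solving
−∇²G = δ_{yᵢ} with uniform insulated-boundary return flux −1/Area, computed
with one P1 FEM solve per electrode. Sources are estimated by
equality-constrained zero-order Tikhonov regularization,

    f̂ = argmin_{w·f = 0} ‖Bf − g‖₂² + λ‖f‖₂²,

with w the lumped nodal-volume quadrature of the existence condition and λ
chosen by the L-curve criterion. The epicardial baseline assembles the
classical BEM transfer matrix A (collocation, linear basis, insulated
torso) and solves the unconstrained Tikhonov problem for epicardial
potentials h. LATs come from a wavelet-weighted slope transform of each
reconstructed signal; the ectopic origin is the centroid of nodes below the
10th LAT percentile.

## Worked example

Reconstruct one deep (septal-analog) ectopic beat on the default phantom
with both methods and score the localization:

```python
import numpy as np
from volmap import RunConfig, BenchmarkScenario, PhantomStudy
from volmap.phantom import add_noise

cfg = RunConfig()                      # default phantom, 128 electrodes, 20 dB
study = PhantomStudy(cfg)              # meshes + transfer operators (~30 s)
region, node = [p for p in study.region_placements(BenchmarkScenario())
                if p[0] == "septum"][0]
gt, f, g = study.simulate_case(node)   # eikonal activation -> sources -> BSPM
g_noisy = add_noise(g, cfg.phantom.snr_db, seed=1)
recon = study.reconstruct(g_noisy)     # conditions signals, inverts both ways
true_site = study.true_origin_site(gt)
print("true origin site (mm):", np.round(true_site, 1))
for method, (sol, lm, site) in recon.items():
    eu, ge = study.score(true_site, site.centroid)
    print(f"{method:11s} lambda={sol.trace.selected:.3g}  "
          f"est site={np.round(site.centroid, 1)}  "
          f"euclidean={eu:.1f} mm  geodesic={ge:.1f} mm")
```

Output:

```
true origin site (mm): [ 87.8 -14.9  -6.7]
volumetric  lambda=0.0274  est site=[ 90.2 -14.9 -13.1]  euclidean=6.8 mm  geodesic=13.0 mm
epicardial  lambda=1.61e-05  est site=[87.3 -7.2  9.5]  euclidean=17.9 mm  geodesic=23.6 mm
```

The volumetric reconstruction places the origin 6.8 mm from the true site
(13.0 mm along the myocardial mesh); the surface-bound epicardial estimate
is roughly twice as far away — the expected behaviour for a source deep in
the wall.

A command-line surface wraps the same pipeline:

```bash
volmap phantom   --out run/            # full single-case run with artifacts
volmap benchmark --out bench/          # paired 16-case localization benchmark
volmap filter    --signals g.csv --mode clinical --fs 1000 --out f.csv
```

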