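# cilialign

Tools for quantifying — and mechanistically modelling — how motile cilia
align their beating direction with an external shear flow.

Multiciliated cells (ependymal cells lining the brain ventricles, airway
epithelium, oviduct) beat their cilia in a common direction and thereby
drive surface flows.  That direction is itself sensitive to flow: cultures
exposed to shear stresses of order 0.1 dyne/cm² re-orient their beating
toward the flow.  `cilialign` implements both sides of such an experiment:

* **Measurement.** A movie pipeline that turns a fast bright-field stack
  plus a fluorescent-tracer stack of the same field of view into per-cell
  records: ciliary beat frequency (CBF) from the dominant per-pixel FFT
  peak, cell outlines from frequency-coherent connected pixels, and beating
  direction from particle image velocimetry (PIV) of the cilia-driven flow
  on a 32-px (7.6 µm) grid.  Culture-level statistics follow: the alignment
  parameter Φ = (1/N) Σ p̂ᵢ·ê, ciliated-cell density, the shear-stress
  profile τ = 6ηQ/(h²w) of a tapered channel, and the dose-response fit
  Φ = 1 − exp(−τ/τ_c) whose critical stress τ_c characterises a culture's
  responsiveness.
* **Mechanism.** A slender-body-theory Stokes solver for arrays of tilted
  rigid rods (coarse-grained beating cilia) above a no-slip wall, which
  shows that cilia in dense carpets are *hydrodynamically screened*: the
  aligning torque T(θ, ρ) on an individual cilium drops roughly two-fold at
  a ciliated area fraction of ρ ≈ 0.1 and keeps falling with density.
  Balancing that torque against a linear torsional spring at the base
  (stiffness k, the stand-in for the anchoring actin mesh) gives the
  equilibrium angle θ* and the alignment surface Φ(ρ, k) = cos θ*: denser
  carpets and stiffer anchoring both reduce alignment.
* **Ground truth.** A synthetic-data module that renders beating-cell
  movies, tracer movies, dose-response datasets and parametric beat
  waveforms with planted parameters, so every stage of the analysis is
  covered by closed-loop recovery tests (planted directions are von Mises,
  making the expected alignment the Bessel ratio I₁(κ)/I₀(κ)).

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
from cilialign import sbt, pipeline, stats, synthetic

# 1) hydrodynamics: torque on an isolated tilted cilium in shear flow
disc = sbt.StokesDiscretization(segments_per_rod=24)
t0 = sbt.isolated_rod_torque(tilt_alpha=53.0, theta=np.pi / 2, discretization=disc)
print(f"isolated-rod torque T0(pi/2) = {t0:.3f} (eta*gammadot*L^3)")

# 2) movie pipeline on a synthetic field with known ground truth
spec = synthetic.SyntheticFieldSpec(shape=(256, 256), n_cells=12, kappa=4.0, seed=3)
layout = synthetic.make_field(spec)
bf = synthetic.render_bf_movie(layout)
fl = synthetic.render_tracer_movie(layout, synthetic.SyntheticTracerSpec(seed=4))
records, cbf, cells, flow = pipeline.analyze_fov(bf, fl)
res = stats.alignment_parameter(records, flow_direction=(1.0, 0.0))
print(f"{cells.n_cells} cells, {res.n_boxes} records, "
      f"Phi = {res.phi:.3f} (planted E[Phi] = {synthetic.expected_alignment(4.0):.3f})")

# 3) dose response: critical shear stress from noisy alignment data
df = synthetic.make_dose_dataset(np.geomspace(0.02, 0.8, 30), tau_c=0.1,
                                 noise_sd=0.05, seed=5)
fit = stats.fit_dose_response(df.tau, df.phi, n_boot=500, seed=6)
print(f"tau_c = {fit.tau_c:.3f} dyne/cm^2 "
      f"(68% CI {fit.ci_low:.3f}-{fit.ci_high:.3f}); Phi(tau_c) = {fit.predict(fit.tau_c):.3f}")
```

Output:

```
isolated-rod torque T0(pi/2) = 0.599 (eta*gammadot*L^3)
12 cells, 16 records, Phi = 0.855 (planted E[Phi] = 0.864)
tau_c = 0.103 dyne/cm^2 (68% CI 0.099-0.107); Phi(tau_c) = 0.632
```

Reading it: a single rigid rod of unit length, tilted 53° toward its
beating direction with its base just above a no-slip wall, feels a
dimensionless aligning torque of ≈ 0.6 when a unit shear flow crosses it at
right angles — this is the T₀ that the screening tables are normalized by.
The pipeline then recovers all 12 planted cells from a rendered movie pair
and measures an alignment within sampling error of the planted von Mises
expectation.  Finally, the dose-response fit recovers the planted critical
stress (0.1 dyne/cm²) within a few percent, and the fitted curve passes
through 1 − 1/e ≈ 0.632 at τ_c, as it must.

## Command line

The same operations are exposed as a thin CLI:

```sh
cilialign synth bf --seed 1 --out fov1/          # synthetic movie + truth
cilialign analyze --bf bf.tif --fl fl.tif --meta meta.json --out fov1/
cilialign stats --manifest conditions.yaml --out summary/
cilialign fit --summary summary/summary.csv
cilialign sbt sweep --config sweep.yaml --out table.csv
cilialign balance --table table.json --kmin 0 --kmax 1 --nk 21 --out phi.csv
```

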