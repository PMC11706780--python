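# nanopearl

Unmyelinated axons of the mammalian CNS are not smooth tubes: under
near-native preservation they are pearls-on-a-string, with nanoscopic
nonsynaptic varicosities (NSVs, ~180–400 nm wide) repeating along a
thin connector cable (~50–220 nm wide).  This geometry is set by
membrane mechanics and matters for function — conduction velocity
depends sensitively on the pearl dimensions.

`nanopearl` is a toolkit for the computational side of that problem,
aimed at membrane biophysicists and computational neuroscientists who
want to generate, measure and simulate pearled axon geometries:

* **synthetic data** — pearled radius profiles with analytic ground
  truth, STED-like intensity profiles, serial-section stacks and whole
  annotated cohorts, statistically matched to measured EM cohort
  summaries;
* **morphometry** — the EM measurement procedure on 1D radius profiles:
  inflection-point segmentation into NSVs and connectors, dimension and
  FWHM measurement, 190-nm periodicity checks, Pythagorean 3D
  correction, exclusion rules and cohort summaries (mean ± s.e.m.);
* **membrane mechanics** — axisymmetric relaxation of the Helfrich
  energy E = ∫(κ/2)(2H − C₀)² dA + σA + E_osm(V): a tense tube
  (σr₀²/κ ≫ 1) spontaneously pearls into unduloid-like trains, and the
  pearl dimensions respond to osmolarity, tension and rigidity;
* **conduction** — the generalized cable equation with Hodgkin–Huxley
  currents, c_m∂V/∂t = [1/(2πa√(1+a′²))]∂x(πa²/R_i ∂xV) − i_HH + i_stim,
  on pearled geometries, with voltage-gated sodium channels placed
  uniformly or clustered every 190 nm, and a time-to-peak conduction
  velocity readout;
* **pipeline** — seeded, manifest-tracked runs chaining
  generate → measure → relax → simulate, plus a `nanopearl` CLI.

See `docs/methods.md` for the models, assumptions and numerical
choices in detail.

## Worked example

```python
import numpy as np
from nanopearl import (PearlChainSpec, gen_pearl_profile, segment_profile,
                       predict_from_measurements)

# a pearled axon at the control dimensions, with jitter and tracing noise
profile, truth = gen_pearl_profile(
    PearlChainSpec(nsv_length=638, nsv_width=309,
                   connector_length=486, connector_width=136,
                   n_periods=8, jitter_cv=0.05, noise_sd=2.0, seed=1)
)

# measure it the way the EM images are measured
segments = segment_profile(profile)
nsv = [s for s in segments if s.kind == "nsv"]
conn = [s for s in segments if s.kind == "connector"]
print(f"measured NSV:       {np.mean([s.length for s in nsv]):.0f} x "
      f"{np.mean([s.width for s in nsv]):.0f} nm (n={len(nsv)})")
print(f"measured connector: {np.mean([s.length for s in conn]):.0f} x "
      f"{np.mean([s.width for s in conn]):.0f} nm (n={len(conn)})")

# predict the conduction velocity of that geometry
v = predict_from_measurements((638, 309, 486, 136))
print(f"predicted conduction velocity: {v:.3f} m/s")
```

prints

```
measured NSV:       625 x 310 nm (n=8)
measured connector: 502 x 135 nm (n=7)
predicted conduction velocity: 0.160 m/s
```

The measured dimensions recover the generating means to within the
per-period jitter (the ground truth for this seed averages 644 × 310
and 491 × 132 nm), and the velocity is the model's prediction for an
untreated cultured axon: a ~0.16 m/s unmyelinated fiber whose speed
would drop if the connectors narrowed or lengthened.

The same things are available from the shell:

```bash
nanopearl measure --seed 3 --out run1      # synthetic cohort + morphometry
nanopearl predict-table                    # velocities for the reference geometries
nanopearl sweep --which connector_width --lo 80 --hi 230 --steps 6
```

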