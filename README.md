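# arterymech

Microstructure-based passive/active mechanics of coronary arteries.

Vascular tissue mechanics usually treats the artery wall as a
phenomenological continuum, which fits pressure–diameter data well but
says nothing about the loads carried by individual elastin fibers,
collagen fibers and smooth muscle cells (SMCs).  `arterymech` implements
a fully microstructural alternative for the coronary artery: every
constituent enters with its own stress–strain law and its *measured*
orientation and waviness statistics, so the model predicts macroscopic
vessel behavior (pressure–radius and pressure–force curves, transmural
stress profiles) and microscopic fiber/cell stresses from one parameter
set.  It is written for researchers in vascular biomechanics who want to
simulate biaxial distension–extension experiments, estimate constituent
material parameters from them, or study how orientation dispersion and
collagen recruitment shape the wall response.

## The model in brief

The wall is a two-layer (media/adventitia) incompressible fiber
composite mapped from its zero-stress state (an open sector with opening
angle Θ) to a loaded cylinder at axial stretch λ_z.  The strain energy
is a volume-fraction-weighted sum over constituents, each an orientation
expectation of a single-fiber law with affine fiber strain
e = **E** : **N**⊗**N**:

* elastin: w = ½k_E e² (tension-only), with an isotropic inter-lamellar
  network in the media;
* collagen: w = k_C (e − e₀)^{1+M_C}/(1+M_C) beyond a random
  straightening strain e₀ (beta-distributed in the adventitia, uniform
  in the media) — wavy fibers are recruited only once straightened;
* adventitial orientations follow two-component truncated-normal
  mixtures; medial fibers and SMCs form symmetric families about the
  circumferential direction.

Activated SMCs generate a triaxial stress: an asymmetric length–tension
law σ(λ) = A[½ρ₁(λ_max^ρ₂ − λ^ρ₂ − 2)(λ − λ_max)² + σ_max] along the
cell, the same law scaled by τ transversely, and a linear law radially.
Radial equilibrium of the residually stressed thick-walled tube then
yields the luminal pressure p_i = ∫(σ_θθ − σ_rr)/r dr, the reduced axial
force F = π∫(2σ_zz − σ_θθ − σ_rr) r dr, and transmural Cauchy stress
profiles.  Parameters are estimated by minimizing a studentized SSE over
passive and K⁺-activated records jointly with a seeded
differential-evolution global search.  See `docs/methods.md` for the
full account.

## Worked example

Simulate the standard protocol (0–160 mmHg at λ_z = 1.3 and 1.5,
passive and fully activated) with the packaged defaults and look at the
effect of SMC tone at 60 mmHg:

```python
from arterymech import default_model, simulate_protocol

model = default_model()
records = simulate_protocol(model, pressures=[60.0], stretches=[1.3],
                            states=["passive", "full"])
for r in records:
    print(f"{r.state:8s} r_o = {r.outer_radius:.3f} mm, "
          f"F = {r.axial_force:7.2f} mN")
```

which prints

```
passive  r_o = 1.944 mm, F =  -27.34 mN
full     r_o = 1.646 mm, F =   25.52 mN
```

— K⁺ activation contracts the vessel from 1.944 mm to 1.646 mm at the
same pressure and swings the reduced axial force upward, the biaxial
vasoactivity that motivates the triaxial (not merely circumferential)
SMC law.  A full synthetic experiment plus parameter recovery runs from
the shell:

```bash
arterymech generate -o experiment.csv --seed 7      # 36-record dataset
arterymech fit experiment.csv -o fit --seed 7       # joint passive+active fit
arterymech recover --seed 1 -o recovery.json        # generate+refit+score
arterymech profile --pressure 100 -o profile.csv    # transmural stresses
```

The library surface mirrors the physics: `kinematics` (sector-to-
cylinder map), `microstructure` (orientation/recruitment statistics),
`fiber_constitutive` and `smc_active` (constituent laws),
`wall_mechanics` (equilibrium, forward/inverse solves), `estimation`
(objective and global fit), `synthetic_data` (protocol emulation),
`io`/`cli` (configuration, CSV/JSON, console entry points).

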