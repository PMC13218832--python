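# ltu-twin

A digital twin for photoacoustic–photothermal temperature monitoring in
laser-heated ex vivo tissue, for researchers developing noninvasive
thermometry for mild photothermal therapy (PTT). Mild PTT needs the
tumor held at 42–45 °C while sparing surrounding tissue, but the region
producing a photoacoustic (PA) signal is much smaller than the heated
volume, so single-point PA thermometry cannot map the temperature field.
This package couples a light–thermal–ultrasound model of the tissue with
PA temperature sensing through a Kalman filter, reconstructing the
internal temperature everywhere in the region of interest — including
points with no PA signal.

## The model

Inside a voxelized phantom carrying per-region optical (μa, μs, g),
thermal (ρ, cp, kv), and acoustic (vs, Γ) properties:

- **Light:** Monte-Carlo photon transport gives the fluence Φ(r); the
  photothermal source is S = μa Φ. A steady-state diffusion solver
  (∇·(D∇Φ) − μaΦ = −L, D = 1/3(μa+μs′)) is the fast alternative. Under
  matching illumination (pulsed and continuous beams with the same
  surface energy distribution) one Φ serves both the PA excitation and
  the heating source.
- **Heat:** conduction-only bioheat balance ρcp ∂T/∂t = ∇·(kv∇T) + S
  (ex vivo: no perfusion, no metabolism), explicit Euler with the
  stability bound Δt ≤ Δl²ρcp/(6kv), re-expressed for estimation as
  x(n+1) = F x(n) over the stacked state x = [ΔT_ROI; S_TOP] with
  F = [[F_T, F_ST],[0, I]].
- **Sound:** initial pressure p0 = Γ Φ μa with Γ = A + B·T; detection by
  a 128-element 5.5 MHz linear array; universal back-projection of
  b = p′ − t ∂p′/∂t reconstructs p0′ ∝ μaΦ.
- **Sensing and fusion:** the relative PA increment
  α = (p0(T)−p0(T0))/p0(T0) is linear in ΔT with gain B/(A+BT0),
  calibrated from a 30→36 °C water-bath sweep; the Kalman recursion
  P = FP̂Fᵀ+Q, K = PHᵀ(HPHᵀ+R)⁻¹, x̂ = x+K(α−Hx), P̂ = (I−KH)P fuses the
  model with per-frame α observations. Because the source block of the
  state carries a large initial covariance, observations at the PA-visible
  tumor cap re-estimate the heat source and thereby correct temperatures
  at unobserved points.

## Worked example

```python
import numpy as np
from ltu.phantom import preset, build_tumor_phantom
from ltu.optics import BeamSpec, mc_fluence, heat_source
from ltu.thermal import cfl_max_dt
from ltu.thermometry import calibrate

grid = build_tumor_phantom(
    tumor_diameter=5e-3, tumor_depth=3.2e-3,
    background=preset("chicken_breast_808"), tumor=preset("tumor_mimic"),
    dl=0.5e-3, extent=(0.032, 0.032, 0.016))
print(f"grid: {grid.shape} voxels at {grid.dl*1e3:.1f} mm")
print(f"CFL time-step bound: {cfl_max_dt(grid):.3f} s")

beam = BeamSpec(profile="gaussian", diameter=3e-3, wavelength=808e-9,
                power_or_energy=1.0, mode="continuous")
mc = mc_fluence(grid, beam, n_photons=200_000, seed=7)
S = heat_source(grid, mc.fluence)
print(f"absorbed fraction: {mc.absorbed_fraction:.3f} "
      f"(escaped {mc.escaped_fraction:.3f}, transmitted {mc.transmitted_fraction:.3f})")
print(f"peak heat source: {S.S.max():.3e} W/m3 at 1 W")

temps = np.arange(30.0, 36.5, 0.5)
amps = 0.113 * (1 + 0.0354 * (temps - 36.0))
cal = calibrate(temps, amps, T0=36.0)
print(f"calibrated observation gain: {cal.slope_coeff:.4f} 1/K (r = {cal.fit_r:.4f})")
```

prints

```
grid: (64, 64, 32) voxels at 0.5 mm
CFL time-step bound: 0.303 s
absorbed fraction: 0.328 (escaped 0.638, transmitted 0.033)
peak heat source: 1.212e+07 W/m3 at 1 W
calibrated observation gain: 0.0354 1/K (r = 1.0000)
```

The phantom is a 5 mm absorbing sphere 3.2 mm below the surface of a
32 mm tissue block. A 3 mm, 808 nm beam deposits about a third of its
power in the tissue (most of the rest backscatters out of the
illuminated surface), peaking at ~1.2·10⁷ W/m³ per watt on the upper
surface of the sphere. The calibration fit recovers the PA thermometer's
observation gain — the fractional amplitude change per kelvin — from the
water-bath sweep.

The three scripted experiments (light-energy depth attenuation,
heat-source reconstruction, and the full simulated-therapy run with
fusion) are driven by config dataclasses or YAML files:

```bash
ltu experiment depth-attenuation --seed 1 --out-dir out/depth
ltu experiment heat-source-recon --seed 1 --out-dir out/recon
ltu experiment ptt-twin          --seed 1 --out-dir out/ptt
```

Each writes CSV tables, a JSON summary, and a run manifest (config hash,
seed, package version). See `docs/methods.md` for the physics, the
numerical choices, and the exact study conditions.

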