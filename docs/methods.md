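# Methods

This note documents the physical models, the numerical choices, and the
study conditions built into the package's synthetic experiments — what the
digital twin does and does not emulate, and therefore what its passing
tests do and do not demonstrate about a physical system.

## Physical model

The twin couples three fields inside a voxelized soft-tissue phantom.

**Light transport.** The reference solver is voxel Monte-Carlo photon
transport: exponential free paths through the local extinction
μt = μa + μs with exact voxel-boundary ray marching, Henyey–Greenstein
scattering with anisotropy g, implicit-capture weight deposition
(w·μa/μt at each interaction), and Russian roulette below weight 10⁻⁴
(survival 0.1). Boundaries are refractive-index matched; photons leaving
the bottom face are booked as transmitted, all other exits as escaped, so
absorbed + escaped + transmitted = 1 up to roulette bookkeeping noise. A
steady-state diffusion solver (7-point finite differences on
D = 1/3(μa+μs′), Dirichlet Φ = 0 ghost closure, beam mapped to an
isotropic source sheet one transport mean free path below the surface) is
provided as a fast alternative and is cross-checked against the
Monte-Carlo depth profile; the Monte-Carlo solver is authoritative.

Under matching illumination conditions — pulsed and continuous beams with
the same surface energy distribution and wavelength — one fluence
solution serves both the photoacoustic excitation and the continuous
heating, rescaled by pulse energy versus continuous power. The twin
exploits this throughout: the heat source is S = μa·Φ·P and the
photoacoustic deposition is μa·Φ·E_pulse from the same Φ.

**Heat conduction.** Conduction-only bioheat balance
ρcp ∂T/∂t = ∇·(kv∇T) + S; perfusion and metabolic heating are omitted
deliberately: the twin represents ex vivo tissue in a temperature-
controlled bath, where neither term operates. Explicit Euler with a
7-point Laplacian, harmonic-mean face conductivity for heterogeneous
media, and the stability bound Δt ≤ Δl²ρcp/(6kv); the default step is 0.9
of the bound. Outer faces default to Dirichlet at the bath temperature
(the experimental condition); adiabatic closure is available and is used
by the conservation tests. Inside the estimator the state is the
increment ΔT above the bath; absolute temperatures appear only at I/O.

**Acoustics.** The forward model is the analytic point-detector solution
of the photoacoustic wave equation at a single sound speed: each trace is
the time derivative of the isochronous-shell projection of p0 with 1/(4πr)
weighting. The shell projection is band-limited at the voxel scale
(Gaussian, σ = 1 voxel of travel time) before differentiation; a voxel is
a finite volume, and without this the histogram's voxelization noise
dominates the derivative. Reconstruction is universal back-projection of
b = p′ − t·∂p′/∂t at t = |r−d|/vs with per-voxel solid-angle
normalization (point-detector weights cosθ/r²). Full-wave propagation,
attenuation, dispersion, and element directivity are out of scope; the
round-trip tests quantify what this forward/inverse pair preserves —
point localization to one voxel, amplitude linearity to ~5%, and
proportionality p0′ ∝ μaΦ with R² > 0.99 under a wide aperture.

**Thermometry.** The Grüneisen parameter is linear in temperature,
Γ = A + B·T (T in °C; the default pair gives the soft-tissue relative
slope B/Γ(36 °C) = 3.54 %/K). Only the composite observation gain
B/(A+B·T0) is ever calibrated or stored, because A and B never appear
separately in the pipeline; the calibration is an ordinary least-squares
fit of α = (p0(T)−p0(T0))/p0(T0) against T−T0 over a simulated water-bath
sweep, 30→36 °C in 0.5 °C steps.

**Fusion.** The stacked state [ΔT at ROI points; S at source points]
propagates through F = [[FT, FST],[0, I]]; H reads α directly (the gain
sits in H, so the calibration is applied exactly once), and the standard
Kalman recursion updates state and dense covariance. The identity block
on S with a large initial S-covariance is what lets temperature
observations at the visible tumor cap gradually re-estimate the heat
source, which in turn corrects temperatures at points the aperture never
sees — the mechanism the fusion experiments quantify.

The measurement-noise model R accepts a full covariance in addition to
the usual scalar or per-AOP diagonal. This matters because the dominant
observation noise — per-pulse laser-energy fluctuation — is common to
every channel of a frame: with a diagonal R, one coherent fluctuation
across M observable points is weighted like M independent temperature
changes, and the filter converts it into aggressive heat-source
corrections early in a run (we observed ~0.3 K transients at
out-of-plane points from exactly this). :func:`estimate_R` therefore
offers a structured estimate fitted to the same static frames: a
rank-one common-mode variance (the variance of the per-frame mean α)
plus the per-AOP residual variance on the diagonal. The default remains
the per-AOP diagonal.

## Point sets and the reduced fusion lattice

TOPs (theoretically observable points) are voxels whose reconstructed
|p0′| reaches 5% of the field maximum — the same fraction used to delimit
the beam spot; AOPs restrict TOPs to the imaging plane of the linear
array. The covariance recursion is O(N²) memory, so fusion runs on a
decimated sub-box around the tumor (default: stride 2, 20 mm box, 11 mm
deep, ~9900 states). The lateral box size is chosen so that no
evaluation point sits within a few millimetres of the box boundary,
where the Dirichlet closure of the reduced model biases temperatures
low. Restriction from the fine grid is block-pooled: the
TOP mask by block-OR and the source by block means, so the thin
photoacoustic crust of the tumor keeps its membership and its deposited
power on the coarse lattice (point-sampling the crust loses about half
its energy and biases the model cold). Observations are the exception:
an AOP is a fine voxel that itself shows a photoacoustic response, so the
α measurement, its row of H, and the truth it is compared against all
refer to the same physical location. The ROI box half-width snaps to a
multiple of the stride so the lattice always contains the tumor axis and
sampling locations do not move when the box is resized.

## Study conditions of the three experiments

All three run from a config dataclass plus a seed; independent child
seeds are spawned for the Monte-Carlo run, the pulse-energy jitter
stream, and the per-slab channel noise.

**Depth attenuation.** Absorbing-plane phantoms with cover depths 0 and
2–8 mm in 1 mm steps, 0.25 mm voxels, 20 mm lateral extent; a 3 mm
(1/e² diameter) Gaussian beam at 808 nm; 10⁶ photons per depth. The
absorber preset is an ink-loaded gel (μa = 3000 m⁻¹, 300× the cover) that
intercepts essentially all arriving light. Absorbed energy over the
absorber region is normalized to the zero-depth run; the log-linear fit is
over the seven nonzero depths (depth 0 is the normalization anchor). The
lateral energy map at each depth feeds the spot analysis (5% boundary
threshold, centroid center, FWHM by interpolation at half maximum).

**Heat-source estimation.** A 5 mm sphere with its top 3.2 mm below the
surface (moderately absorbing mimic, μa = 300 m⁻¹) in a 20×20×14 mm
phantom at 0.25 mm voxels; Monte-Carlo heat source; p0 = Γ(36 °C)·μaΦ;
a 128-element, 5.5 MHz, 0.3 mm-pitch linear array scanned across the
sphere in 0.5 mm steps with 40 dB channel SNR; per-slab UBP. The
comparison follows the bench procedure: the matched central section,
both fields thresholded at 5% of their section maxima, lateral envelope
profiles, relative amplitude removed by a least-squares fit (a pressure
reconstruction and a W/m³ heat source have no common absolute scale), and
the relative difference of the normalized trapezoidal profile integrals
reported. Out-of-plane envelope profiles are far more sensitive to the
linear array's elevational view loss and are not the quantity compared.

**Simulated photothermal therapy.** A 32×32×16 mm phantom at 0.5 mm
voxels (131k voxels) around the same tumor; truth simulated with the
explicit solver at 0.9× the CFL bound (≈0.25 s substeps); continuous
heating at 0.45 W, sized so the tumor top rises from 36 °C to ≈42.7 °C
over the 150 s run — inside the 42–45 °C mild-therapy window. Protocol
order mirrors the bench: calibration sweep, static frames (reference
amplitude and the structured measurement-noise model R — common-mode
plus diagonal — estimated from the α fluctuation of 30 non-heating
frames), preoperative tomographic scan
(TOP/AOP selection and the model heat source), then heating with one PA
frame per 1 s model step. Pulse energy jitters multiplicatively per frame
with σ = 0.35%, sized so raw PA thermometry shows maximum errors of a few
tenths of a kelvin over a run — the error magnitude reported for such
systems — and the model heat source carries a deliberate +10% amplitude
bias standing in for estimation error. Kalman settings follow the
operating guidance: ΔT process noise 10⁻³ K² per step while heating
(10⁻⁴ quasi-static), R from the static frames with a 10⁻¹² floor,
initial covariance small on ΔT (10⁻⁴ K², the run starts equilibrated)
and large on S (σ = 30% of the peak source). Errors are evaluated at four
virtual thermocouples on the fusion lattice: the observed tumor-top node,
the tumor core, adjacent tissue ≈2 mm beyond the lateral surface in the
imaging plane, and the lateral tumor surface out of plane.

## What the twin does not emulate

Real transducer bandwidth and directivity, acoustic attenuation,
speed-of-sound heterogeneity, optical property uncertainty, tissue
deformation and registration error, and perfused (in vivo) tissue. The
jitter-only observation noise model attributes all thermometry error to
pulse-energy fluctuation; real systems add electronic noise and motion.
Passing twin experiments therefore demonstrate the internal consistency
and noise rejection of the estimation pipeline under its own forward
models, not instrument-level accuracy.

## Numerical and design choices

- Gaussian beams use the 1/e² diameter convention by default (the width
  convention is configurable) — the spot-size convention of the physical
  system is not uniquely determined, and this is the conservative reading.
- Layer thicknesses round to the nearest whole voxel with a one-voxel
  floor; sphere membership is by voxel center. Rebuilding any phantom is
  bit-identical.
- The diffusion system solves with a direct sparse factorization up to
  1.5·10⁵ unknowns and preconditioned conjugate gradients beyond.
- Scan slabs snap onto the voxel lattice (column centers for odd, column
  edges for even numbers of covered columns) with the slab half-width
  pulled 0.1% inside the boundary columns, so slab membership can never
  land on a floating-point tie at a voxel edge.
- The innovation covariance is solved by Cholesky; failure raises with a
  conditioning diagnostic rather than producing a silent pseudo-inverse.
  The covariance is re-symmetrized after every update.
- During a commanded laser-off phase the source block injects no heat but
  keeps its magnitude, so a later switch-on resumes with the converged
  estimate.

## Known limitations

The fused-error margin at the `adjacent_tissue` thermocouple is the
tightest of the four points: it accumulates the residual model bias that
observation-driven source correction cannot fully remove (coarse-lattice
discretization, the ROI boundary closure, and sub-threshold background
heating excluded from the source set). Widening the ROI box trades this
bias against covariance memory and runtime quadratically. The UBP
amplitude fidelity degrades with source depth and surface tilt under a
finite aperture; the proportionality guarantee is stated for a wide
aperture and shallow sources.
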