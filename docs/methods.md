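# Methods

`fustsl` couples six physical sub-models on a reduced one-dimensional radial
geometry: a spherical tumor of radius R (set by the tumor volume at treatment
time) embedded in host tissue, with all fields functions of the distance r
from the tumor center.  This note records the governing equations as
implemented, the parameter defaults and their provenance, the numerical
choices, and what the package's passing tests do and do not demonstrate.

## Geometry and clocks

The full problem this package reduces is three-dimensional (a focused beam, a
tumor octant, a host box ~100× the tumor).  Here the octant symmetry is
replaced by full radial symmetry and the beam by its on-axis profile:

* **acoustic slab**: r ∈ [0, 10 mm], the insonated/absorbing tissue region;
  the effective point source sits on the axis at distance d = |x₀| ≈ 0.208 m.
* **thermal domain**: r ∈ [0, 40 mm], body temperature (310.15 K) clamped at
  the far boundary, zero flux at the center.
* **drug/fluid domain**: r ∈ [0, 2.5 R], zero-concentration far boundary
  (host clearance), zero-pressure far gauge.

Three clocks advance the coupled system (multirate orchestration): a 0.25-day
outer clock for tumor volume, a minute-scale drug clock from injection until
the drug has cleared (600 s steps, 60 s during the injection-to-sonication
lag), and a 9-s fine clock during sonication when the bio-heat equation and
temperature-triggered release are active.  Refining the fine clock from 9 s
to 4 s changes peak temperature and end-of-run internalized drug by < 1%
(tested).  The acoustic field is solved once per exposure window: source and
medium are stationary at the fidelity modeled.

## Acoustics

The time-harmonic pressure is decomposed into the prescribed spherical
incident wave and a computed scattered correction.  The 1D operator is the
spherical-radial Helmholtz operator in the source-centered coordinate
s = d − r, so the spreading incident wave is an exact solution in homogeneous
media and the scattered field carries only heterogeneity effects.  First-order
radiation conditions absorb outgoing scattered waves at both slab ends (the
full model suppresses reflections with a very large domain; a radiation
condition emulates that cheaply).

Two loss conventions are provided.  The printed-equation convention uses a
real wavenumber (lossless propagation) and injects absorption only through
the deposition Q_ex = α_t |p₁|²/(ρ c₀).  The default scenario mode
(`Numerics.lossy_beam = True`) replaces κ by κ − iα_t *inside the tissue
slab only* (the coupling path outside the domain is treated as lossless
water), which makes deposition saturate with frequency in a physically
sensible way: without in-beam attenuation, heating would grow without bound
as α_t ∝ f.

Defaults: ρ_t0 = 1050 kg/m³, c₀ = 1540 m/s (standard soft tissue),
α₀ = 11.5 Np/m at f₀ = 1 MHz (≈1 dB/cm/MHz absorption, mid-range for tumor
tissue), η* = 1 (linear frequency law).  The source amplitude is a protocol
input; following the protocol's own procedure the presets store an amplitude
*calibrated* so the reference exposure reaches its target hyperthermia
temperature (JC preset: 1.25×10⁴ Pa at 1 m, giving a 41.2 °C peak for a
30-min 1-MHz exposure; CWR22 preset: 1.09×10⁵ Pa for 42 °C after 4 min at
40 kHz).  The grid resolves ≥ 8 nodes per wavelength (enforced); scenario
runs use 96 and the analytic-agreement tests 128–256, where the second-order
scheme matches the closed-form spherical wave to < 1%.

## Bio-heat transfer

ρ_t c_t ∂T/∂t = k_t ∇²T + Q_m + Q_ex, integrated with backward Euler
(unconditionally stable) and conservative finite volumes.  The printed
balance carries no perfusion sink; a Pennes-style sink w(T_body − T) is
available and off by default.  Q_m defaults to 0 (negligible next to
hyperthermic deposition).  Base properties: c_t0 = 3600 J/(kg K),
k_t0 = 0.52 W/(m K).

The temperature dependence of ρ_t, c_t, k_t follows quintic polynomial fits
whose argument is the temperature in °C.  This units choice is deliberate and
recorded: evaluated at Kelvin magnitudes the fitted coefficients produce
unphysical (negative) properties, while at °C they reproduce the base values
at 0 °C and plausible deviations at body temperature.  Enabling the fits
lowers ρc and k near 37–42 °C and raises a 10-min heating peak by ~1.5 K on
the reference grid (regression-pinned).

## TSL release

k_rel(T) = A e^{BT} with T in Kelvin — only Kelvin magnitudes give sensible
rates (≈5.0×10⁻³ s⁻¹ at 37 °C, ≈6.7×10⁻² s⁻¹ at 42 °C, ratio ≈13.5); a °C
argument would give ~10⁻⁶⁴ s⁻¹.  The fit is valid on 37–42 °C and clamped to
its boundary values outside — extrapolating a 0.52 K⁻¹ exponential to 44 °C
would overshoot nonphysically.  The fast formulation (A = 4×10⁻⁷³ s⁻¹,
B = 0.5204 K⁻¹) is the fitted baseline; ultra-fast/intermediate/slow are
*surrogate* rescalings (×6, ×0.3, ×0.1 — spanning the slow-to-ultra-fast
spread used in the release-rate sensitivity levels) that preserve the
required speed ordering and are config-replaceable by formulation-specific
fits.

## Hindered transvascular transport

Starling exchange with pore-hindrance coefficients: L_p = γr₀²/(8ηL_vw),
P_er = γHD₀/L_vw, σ_f = 1 − W, D₀ from Stokes–Einstein at 310 K
(η = 6.92×10⁻⁴ Pa s, configurable).  H = 6πF/K_t and
W = F(2−F)K_s/(2K_t) with F = 1 − λ², λ = r_s/r₀.  The two-part asymptotic
series for K_t, K_s uses the Bungay–Brenner *centerline* coefficient
tabulation (the variant consistent with the framework this builds on; a
cross-section-averaged set would differ at large λ).  The series is pinned by
an independently coded term-by-term oracle to 10⁻¹² relative and flagged with
an accuracy warning for λ ≥ 0.95, where the (1−λ)^{−5/2} prefactor amplifies
truncation error.  λ ≥ 1 returns a fully excluded particle (P_er = 0,
σ_f = 1) rather than raising, so size sweeps cross the exclusion threshold
gracefully.  An oxygen mode forces γ = H = 1 (small solute, unhindered).

Wall defaults: r₀ = 100 nm (moderately permeable tumor vasculature; 200 nm
models hyperpermeable vessels), L_vw = 5 µm, γ = 10⁻⁴ (giving
L_p ≈ 3.6×10⁻¹¹ m/(Pa s), in the range of measured tumor wall
conductivities), S_v = 2×10⁴ m⁻¹, p_v = 2.66 kPa (≈20 mmHg).

## Interstitial fluids and the sonication window

Steady source–sink Darcy balance (the standard Baxter–Jain formulation, used
here as a documented surrogate for the full poroelastic fluid problem):
k_th∇²p + L_pS_v(p_v − p) = 0 in the tumor, pure conduction outside, p = 0
far gauge; v = −k_th∇p.  Intratumoral lymphatics are zero; host drainage is
folded into the far boundary.  Osmotic filtration is available but off by
default.  The dimensionless leakiness α_B = R√(L_pS_v/k_th) ≈ 17 at baseline
(k_th0 = 3.1×10⁻¹⁴ m²/(Pa s)) reproduces the classical elevated-IFP profile:
p ≈ p_v in the core, all filtration confined to a rim layer.  The solver
matches the sinh-profile closed form to < 0.5%.

Sonication multiplies k_th ×5 and γ ×1.5 on the half-open window
[t_FUS, t_FUS + persistence) (default 24 h), reverting exactly at the end.
The IFP field is re-solved quasi-statically at each window edge rather than
integrated in time: fluid equilibration is minutes against the day-scale
outer clock.  Lowering IFP widens the filtration rim by √5 and, with the
porosity gain, is the dominant delivery-enhancement mechanism in the model.

## Drug compartments

Four coupled fields, all normalized to the initial plasma carrier
concentration (c_iv(t₀) = 1, decaying as e^{−(t−t₀)/k_d}): carrier c_l
(diffusion D_l, convection, release sink, Starling source), free drug c_f
(diffusion D_f, convection, release source αk_rel c_l, binding sink
(1/φ)k_on c_rec c_f, unbinding source), bound drug c_b (binding −
unbinding − internalization; no transport), internalized drug c_int (pure
accumulation).  The payload α converts carrier counts to drug-equivalents at
release; the mass ledger therefore weights c_l by α and is conservative at
the discrete level (finite volumes, upwinded convection).  Receptors are a
fixed pool; the composite binding rate (1/φ)k_on c_rec is the configurable
quantity to avoid unit ambiguity in k_on itself.

Kinetic defaults: composite binding 10⁻³ s⁻¹ (k_on c_rec = 3×10⁻⁴ s⁻¹,
φ = 0.3), k_off = 10⁻⁴ s⁻¹, k_int = 5×10⁻⁴ s⁻¹.  Particle defaults
(50-nm-radius liposome): α = 10⁴ drug molecules/carrier, D_l = 5×10⁻¹³ m²/s
(interstitial, hindered), D_f = 2×10⁻¹⁰ m²/s (small-molecule drug),
k_d = 2 h for the fast-clearing JC formulation and 24 h for the
long-circulating CWR22 formulation (whose intratumoral accumulation peaks
near the 24-h sonication lag of that protocol).  Size variants scale payload
with r_s³ (encapsulated volume) and D_l with 1/r_s, with a fixed-payload mode
to decouple loading from transport.

Time stepping is a single sparse backward-Euler solve of the full linear
system (positivity-preserving with the upwind M-matrix structure).  In the
well-mixed reduction the reaction system plus the exponential plasma forcing
form an autonomous linear ODE that is advanced *exactly* with a
matrix-exponential propagator; this mode, fed by the same operator assembly
as the PDE path, is verified against an independent tight-tolerance ODE
integration to better than 10⁻⁶ relative over 24 h.

## Pharmacodynamics (surrogate)

The full multi-population cancer/immune balance is out of scope; a
single-compartment surrogate preserves the causal chain this package
exercises: S_f = e^{−κ c_int} (Hill alternative available) modulates
dV/dt = k₁V(1 − V/V_K)S_f − k₁V(1 − S_f), so untreated dynamics are exactly
logistic and survivors/non-survivors separate at the proliferative tempo.
All volume outputs are surrogate-PD results.  The single kill constant
κ = 8.6×10⁻⁵ (per normalized c_int unit) is anchored once so the default
JC combination arm lands on the reported final-volume scale — the same
philosophy as the framework's own single-parameter (k₁) calibration — and is
then held fixed across arms, studies and sweeps; every spread, ordering and
percent reduction is a genuine prediction.  V_K = 2000 mm³ keeps untreated
growth quasi-exponential over the observed 200–500 mm³ window.

k₁ calibration minimizes the sum of squares between the closed-form logistic
solution (anchored at the first observation) and an untreated growth series,
by bounded scalar optimization on [10⁻⁶, 5] d⁻¹; it is deterministic and
recovers 0.51/0.38 d⁻¹ within 10% from 5%-noise synthetic curves on every
replicate of a 100-seed battery.

## Sensitivity statistic

Tot.Var = Σᵢ (1/T)∫(Vᵢ(t) − V̄(t))² dt across the three levels of each
varied parameter (multipliers: k_rel ×{0.1, 1, 6}; r_s ×{0.2, 1, 1.3} with
coupled payload/diffusivity scalings; k₁ ×{1, 1.2, 1.4}; f ×{1, 3, 5};
t_exp ×{0.033, 1, 2}), trapezoidal quadrature over days 10–17 (treatment
onset to end of the strong-response window).  Degenerate (identical) levels
report Tot.Var = 0 with log₁₀ = −inf as a sentinel, never an exception.  The
resulting ranking — k₁ ≫ r_s > k_rel ≫ t_exp ≳ f — reproduces the reported
ordering: proliferation dominates, nanoparticle properties matter, and the
ultrasound operating point is secondary within the studied ranges.

## Synthetic data

`generate_fixture` produces the package's test inputs programmatically:
logistic tumor-growth curves with multiplicative lognormal noise (default
σ = 0.05 in log space, 8 points over 10 days — the cadence of caliper
measurements in the replicated studies) for calibration tests, and small
radial grids with analytic quadratic fields for solver tests.  Both are
byte-reproducible per seed.  The generator emulates measurement noise and
growth kinetics only; it does not emulate inter-animal heterogeneity,
measurement dropout, or treatment-arm variance, so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to real-cohort artifacts.

## Numerical choices

* Conservative finite volumes on uniform radial grids everywhere; exact
  discrete bookkeeping of mass and enthalpy (tested to 0.5%/step).
* Backward Euler for heat and drug PDEs (stability, positivity); RK4 for the
  volume ODE (the untreated limit must match the logistic closed form to
  0.1% at the 0.25-d outer step).
* Helmholtz: direct sparse solve; residual of the discrete equation below
  10⁻⁸ of the field norm by construction.
* Ties/degenerate inputs: excluded particles are flagged results, not
  errors; log₁₀(0) is a −inf sentinel; release-rate clamping is silent by
  design (the clamp band is the fitted validity range).
* Time-to-endpoint (500 mm³) is linearly interpolated between outer steps.

## Known limitations

* **Short exposures under-heat.**  The 1-cm heated slab of the radial
  reduction has a thermal response time of hours, so a 30-s exposure raises
  the peak by < 1 °C where the full 3D focal geometry (small spot,
  fast equilibration) reports ~3.7 °C.  Long-exposure temperatures are
  calibrated/predicted correctly; sub-minute protocol conclusions should not
  be drawn from this model.
* **Late-window washout.**  With the plasma bolus cleared (k_d = 2 h), a
  transport enhancement persisting beyond ~12 h no longer adds influx but
  keeps convecting recycled free drug out of the tumor; the persistence
  benefit therefore saturates and can invert by ~1% between 12 h and 24 h,
  whereas the full model reports monotone (if small) benefit out to 24 h.
  The dominant behavior — most of the benefit accrues in the first hours,
  24 h beats 2 h — is reproduced.
* The tumor geometry is frozen at its treatment-time radius for transport
  (quasi-static); volume evolves only through the surrogate PD.
* Vascular density and pressure are uniform inside the tumor; the coupling
  of functional vascular density to growth/solid stress is out of scope.
* No cavitation, radiation force, nonlinear acoustics or transducer
  geometry; no charge effects, deformable particles or two-pore wall models;
  no immune-mediated killing or resistance evolution.
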