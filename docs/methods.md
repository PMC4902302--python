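# Methods

## The model

`killfrac` simulates chemotherapeutic cell kill in the annular tissue volume
surrounding a single blood vessel. Two coupled fields live on the radial
coordinate `r`: the drug concentration `σ(r, t)` and the tumor cell volume
fraction `φ(r, t)`. Drug diffuses out of the vessel and is taken up by viable
cells at a rate proportional to the local cell density (linear uptake); cells
die at a rate proportional to their *cumulative* drug exposure, which makes
the cell equation an integro-differential one:

    ∂σ/∂t = D ∇²σ − λ_u φ σ
    ∂φ/∂t = −λ_u λ_k φ(r,t) ∫₀ᵗ σ(r,τ) φ(r,τ) dτ

Because drug diffusion and plasma clearance are fast (minutes) compared with
drug-induced apoptosis (hours to days), the drug field is treated as
quasi-steady: at each instant `σ` is the steady solution of the diffusion
equation given the current `φ`. The vessel wall holds a fixed concentration
`σ₀` — for conventional bolus delivery this is the time-averaged plasma
concentration of the regimen, for nano-carrier delivery the roughly constant
level sustained by particles lodged in the vasculature and eluting drug over
several apoptotic cycles.

Nondimensionalizing with the diffusion penetration length
`L = sqrt(D/(φ₀ λ_u))` and the apoptotic-cycle time
`T = (λ_k λ_u φ₀ σ₀)^(−1/2)` leaves a parameter-free system

    ∇′²σ′ − φ′σ′ = 0
    ∂φ′/∂t′ = −φ′ ∫₀^t′ σ′φ′ dτ ,      φ′(t′=0) = 1

on the annulus `r′ ∈ [r_b/L, r_b/(L·√BVF)]`, with `σ′ = 1` at the vessel wall
and zero flux at the outer edge. The outer radius encodes the
influenced-tissue-volume hypothesis: each tissue element is supplied by its
nearest vessel, so at blood volume fraction BVF one vessel of radius `r_b`
serves an annulus whose area is `1/BVF` times the vessel's. Only two
parameters remain, `r_b/L` and `BVF`; all simulation outputs are reported in
units of `L` (length) and `T` (time, "apoptotic cycles"). Dimensional input
is accepted in micrometres and days only; unit conversion is the caller's
responsibility.

The kill fraction — killed volume over initial tumor volume in the annulus —
is

    f_kill(t′) = 1 − 2 ∫ φ′ r′ dr′ / (R′² − (r_b/L)²),   R′ = r_b/(L √BVF).

## Numerics

**Drug solve.** The quasi-steady equation is discretized in conservative flux
form on a uniform radial grid (default 2001 nodes): r-weighted central
differences, second-order accurate, with the outer zero-flux condition
imposed by a second-order ghost-node reflection. The Dirichlet node is
eliminated from the linear system so the wall value is exact. The resulting
tridiagonal system is strictly diagonally dominant and solved in one banded
elimination pass. The scheme is validated against the modified-Bessel closed
form for uniform cell density,
`σ′(r) = [K₁(R)I₀(r) + I₁(R)K₀(r)] / [K₁(R)I₀(a) + I₁(R)K₀(a)]`
(max node error ~4e-8 at 4001 nodes on the reference geometry), with the
measured convergence order ≈ 2.

**Time stepping.** Backward Euler (default `dt = 1e-3` cycles) with the
implicit, positivity-preserving update `φ_{n+1} = φ_n / (1 + dt·E_{n+1})`,
where `E` is the cumulative exposure advanced by the trapezoid rule. The
governing equation evaluated at the new time level contains the history
integral *including* the current step, so each step runs a Picard iteration —
re-solve `σ′`, advance `E`, update `φ′` — to full self-consistency (max node
change < 1e-10, cap 50 sweeps; ~3 sweeps in practice). The drug field is
re-solved every step. Scalar limits of the update are tested against two
closed forms: `φ(t) = exp(−t²/2)` for a frozen unit exposure rate, and
`φ(t) = sech²(t/√2)` for the self-consistent wall dynamics at `σ′ = 1`
(this is also the BVF → 1 limit of the bolus kill, ≈ 0.371 after one cycle —
complete kill is approached only as `t′ → ∞`).

**Kill fraction.** Composite trapezoid on the solver grid. The annulus area
identity `∫ 2r dr = R² − a²` is exact for the trapezoid rule (linear
integrand), so the no-kill state yields zero up to round-off; values within
1e-14 of zero are snapped to zero, and anything outside [0, 1] by more than
1e-12 raises rather than being clipped (the implicit update preserves
positivity by construction).

Resolution defaults (`dt = 1e-3`, 2001 nodes) were chosen by
self-convergence: the end-of-run kill fraction shifts by well under 1e-3 when
the step and mesh are refined further. Property tests run at reduced sizes
(301–801 nodes, `dt` up to 5e-3) chosen the same way.

## Bolus reference and cohort calibration

The bolus ("conventional chemotherapy") kill estimate defaults to the
generalized model's own `f_kill` at `t′ = 1`: sustained release reaches the
bolus kill level within one to two apoptotic cycles, so one cycle of the
dimensionless model is the natural reference point. Any closed-form bolus law
`f(BVF; r_b, L)` can be supplied instead wherever a bolus model is accepted.

Enhancement curves are kill curves normalized pointwise by the bolus value.
At the reference setting (`r_b/L = 0.1`, `BVF = 0.01`) the model gives a
~4.0-fold enhancement after four cycles; at high vascularization
(`BVF = 0.05`), where bolus already kills most cells within a cycle or two,
the maximum enhancement within ten cycles is ~2.9-fold (a ≥ 50% gain).

**Calibration.** `calibrate_cohort` fits the bolus law to per-patient
(BVF, f_kill) pairs by nonlinear least squares (Levenberg–Marquardt on
log-parameters, which enforces positivity), reporting R², standard errors
and t-test p-values under Gaussian residuals. An identifiability caveat
drives the interface: the model-based default reference depends on `r_b` and
`L` only through `r_b/L`, so both cannot be estimated from (BVF, f_kill)
data alone. With the default model the vessel radius is therefore passed as
a fixed value (it is directly measurable from histology) and only `L` is
free; a closed-form law that separates the two parameters may free both.
Optional weighting by per-record `f_kill` standard deviations is available
but off by default.

Each objective evaluation would otherwise cost one PDE integration per
record, so calibration (and the Monte-Carlo studies of it) evaluates a
surrogate: a bicubic spline of the bolus surface in
(log₁₀ r_b/L, log₁₀ BVF), built once from a 20 × 24 grid of direct solves at
reduced resolution (301 nodes, `dt = 5e-3`, which is converged to ~1e-4 for
this quantity). Interpolation error against direct solves is below 1e-4
(measured ~5e-6). Generating synthetic cohorts from the same surrogate makes
zero-noise calibration recover the truth to machine precision, a closed-loop
test of the fitting machinery itself.

**CT correlation.** `fit_ct_bvf` regresses measured BVF on Hounsfield Units
(prediction flows CT → BVF, so HU is the predictor) by ordinary least
squares; `predict_fkill_from_ct` composes the line with the calibrated bolus
law and refuses HU values that map outside BVF ∈ (0, 1).

## Constant-flux nano-carrier law

When particles release drug at constant mass flux `F` (g/day), integrating
the cell equation over the tissue volume gives a tumor volume that shrinks
quadratically, `V_T = V_T0 − λ_k F t²/2`, i.e.
`f_kill = F λ_k t² / (2 V_T0)` — valid while the flux is approximately
constant and the kill fraction is small-to-moderate; beyond `f_kill = 1` the
value is capped with a warning. With the measurable net volumetric death
rate `Λ_k = λ_k F t` (control growth rate minus treated net growth rate,
mm³/day) the same law reads `f_kill = Λ_k t / (2 V_T0)` and inverts to the
kill-time estimate `t_kill = 2 V_T0 f_target / Λ_k`; both forms are exposed
and are exact inverses of each other. The companion growth-curve analysis
fits linear rates to per-arm mean volumes and computes the
control-normalized kill series `f_kill(day) = 1 − (treated fold-change) /
(control fold-change)`, which is invariant to common volume rescaling and
zero at treatment onset. Group aggregation uses the arithmetic mean across
mice (configurable in principle; median was the alternative). Treated-arm
days are stored post-treatment, with a `day_offset` field recording the
post-inoculation day of onset (day 14 by default).

The early-time consistency between the two model tiers is tested: with the
quadratic coefficient matched to the PDE model's early behavior, the
constant-flux law tracks the full model within 10% while `f_kill < 0.1`.

## Synthetic data generators

Neither the patient cohort (21 colorectal-liver-metastasis patients with
histopathology kill fractions and contrast-CT data) nor the mouse experiment
(four arms × 10 mice) is publicly deposited, so seeded generators emulate
their structure:

* **Cohort** (`CohortGenSpec`): BVF log-uniform on [1e-3, 1e-1] (the
  clinically observed range); `f_kill` = bolus law + additive Gaussian noise
  (sd 0.05, truncated to [0, 1] — the sources give only slide-to-slide
  spreads, no distribution); HU tied to BVF by a linear map (default slope
  1e-3 BVF/HU, intercept 0, putting HU in a realistic contrast-enhancement
  range) with 25% multiplicative coefficient of variation emulating
  physiology and injection-protocol variability. Ground-truth parameters
  default to the clinically calibrated `r_b = 15.83 μm`, `L = 155.06 μm`.
* **Mouse arms** (`MouseGenSpec`): control volumes `V₀ + Λt + ε` with
  `V₀ ~ U(100, 200) mm³`, `Λ = 70 mm³/day`, measurement days
  {0, 3, 7, 11, 14, 17} post-treatment, volume noise sd 20 mm³. Treated
  volumes are the control trajectory scaled by `1 − f(t)` with
  `f(t) = (Λ_k/Λ)·min(1, (t/t_p)²)`: quadratic kill onset reaching a plateau
  at `Λ_k/Λ` on day `t_p = 4`. This form makes the post-plateau net growth
  rate exactly `Λ − Λ_k` and makes plateau kill ratios equal death-rate
  ratios, so the rate arithmetic (70 − 35 = 35 mm³/day; plateau kill 0.5;
  3:1 nano-to-free ratio at 3:1 death rates) closes exactly in the noise-free
  limit. Default death rates: 35 mm³/day for both particle arms, a third of
  that for free drug.

Randomness is split per patient/mouse by counter (`default_rng([seed, i])`),
so extending a cohort never perturbs existing records; per-mouse streams are
shared across arms (common random numbers), so an arm with zero death rate is
byte-identical to the control arm.

What the generators do **not** emulate: inter-patient heteroscedasticity and
reader effects in histology, nonlinearity or saturation in the CT–BVF
relation, per-mouse growth-rate heterogeneity, regrowth after treatment, and
attrition/censoring. Passing closed-loop tests therefore demonstrates that
the pipeline recovers parameters under the model's own assumptions — not
that those assumptions hold in real data.

Pre-registered Monte-Carlo tolerances (pilot simulations run before the
tests were frozen): median relative error of recovered `L` < 15% at kill
noise sd 0.05 with 21 patients (measured ~6%); CT slope p < 1e-3 in ≥ 95% of
replicates at n = 18, cv = 0.25 (measured 100%); control growth rate within
10% (measured ≤ 2%).

## Known limitations

* Cylindrical symmetry around an isolated straight vessel; no vessel
  networks, 3-D geometry, or inter-vessel competition beyond the
  influenced-volume partition.
* Linear drug uptake; no saturable kinetics, no drug decay term, no
  time-dependent (non-quasi-steady) transport.
* No tumor regrowth or proliferation during treatment — kill fractions are
  monotone by construction, so long-horizon kill is overestimated for
  proliferative tumors.
* The constant-flux law assumes `dF/dt ≈ 0`; particle-size-dependent release
  kinetics are not modelled.
* The bolus reference at `t′ = 1` is a modelling convention, not a fitted
  pharmacokinetic quantity; swapping in a closed-form bolus law changes the
  absolute enhancement values.
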