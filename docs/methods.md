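# Methods

## Model and assumptions

The tumour is spherical with proliferation confined to a thin outer rim of
constant thickness Δr over a necrotic core. First-order growth of rim cells
at rate α then makes the radius grow linearly, `dr/dt = α·Δr =: g`, so the
volume `4πr³/3` grows cubically (`growth_rate_from_rim` exposes the g = α·Δr
constructor; the rim/core volume algebra itself is not part of the API).
Drug action reduces the radius at a xenograft-specific maximal rate `d`
scaled by a Hill function of the **unbound** plasma concentration; `d` lumps
tumour permeability, stroma content and other emergent in-vivo effects, and
both `g` and `d` are properties of the xenograft (cell line × mouse strain),
reusable across compounds with a similar mode of action. The free-drug
hypothesis is assumed throughout: every concentration, AUC and IC50 in the
package is an unbound quantity (nM, nM·h), and `unbound()` is the single
conversion point from total values.

Pharmacokinetics are one-compartment, dose-linear and in steady state: the
interval profile is `c(t) = c_max·e^(−k t)` with `k = ln(PTR)/τ`. PTR = 1
is allowed and treated as constant infusion via analytic limit branches
(switched at |PTR − 1| < 1e−6, which matches the general branch to better
than 1e−6 relative). Transient accumulation, multi-compartment kinetics and
nonlinear clearance are out of scope.

## Closed forms and numerical hygiene

For hill = 1 the interval integral of the Hill effect (the "effective AUC")
has the closed form `τ/ln(PTR)·ln[(c_max+IC50)/(c_trough+IC50)]`. Setting it
equal to `(g/d)·τ` and solving yields the stasis trough/peak/average triple
and the model efficacy factor MEF. For general hill the same derivation goes
through because powering an exponential only rescales its rate; the
closed form is therefore **exact** for mono-exponential profiles at any
hill, and the quadrature tests confirm it to the integrator's tolerance.

All PTR powers are evaluated as `exp(x·ln PTR)` with `expm1` forms for the
ratios `(PTR^x − 1)/(PTR^h − PTR^x)` and `(PTR − 1)/ln PTR`, so PTR near 1
and g/d near 0 or 1 do not cancel catastrophically. `g/d ≥ 1` raises a typed
resistance error ("tumour idiosyncratic resistance") rather than returning
infinity, so population code can count non-responders explicitly.

The radius simulator floors the radius at 0 (regrowth is allowed if the
instantaneous effect weakens below g/d): the underlying model never
addresses eradication, and the floor prevents negative radii under
aggressive dosing. The drug-free control is the exact line R0 + g·t, never
integrated. Per-interval effect integrals use adaptive quadrature at
relative tolerance 1e−8, computed once per steady-state interval and reused;
the floor is applied at 8 sub-steps per interval by default. TGI is
evaluated from first dose to the last interval boundary, treated and control
sharing R0.

## Absorption relaxation

With first-order absorption k_a and elimination k_e (k_a > k_e; flip-flop
kinetics excluded, and a warning is issued for k_a < 3·k_e where the
separable-phase assumption is strained), the periodic steady-state profile
is the geometric-series sum of shifted Bateman doses,
`A·[e^(−k_e t)/(1−e^(−k_e τ)) − e^(−k_a t)/(1−e^(−k_a τ))]`, continuous at
interval boundaries. Its peak is located numerically (bounded scalar
minimisation, xatol 1e−10 h); the reported t_max, c_max, c_trough and PTR
are those of this realised steady-state profile — at finite τ the peak falls
slightly earlier than the single-dose value `ln(k_a/k_e)/(k_a−k_e)`, to
which it converges for long intervals. Feeding the realised PTR into the
mono-exponential stasis closed forms reproduces the numerically exact stasis
coverage within 5% for k_a/k_e ≥ 10 (validated by a root-finding quadrature
oracle); no analytic inversion of the Bateman stasis condition is attempted.

## IVIVC fitting

The logistic is implemented in offset form
`TGI_min + (TGI_max − TGI_min)/(1 + (PD_inflex/x)^hill_exp)`, which has the
conventional limits (TGI_min at zero coverage, TGI_max at infinite coverage,
midpoint at PD_inflex) and reduces to the classical stasis-dose inversion
`PD_inflex/((TGI_max−TGI_min)/100 − 1)^(1/hill_exp)` when TGI_min = 0 — the
default, since fitted xenograft IVIVCs conventionally return a zero lower
asymptote; fitting TGI_min is opt-in. Coverage can be concentration-based
(c_average,ub/IC50) or AUC-based (AUC_ub/IC50); the two differ only by the
factor τ in the inflection point and give identical predicted curves.

Fitting is unweighted least squares on untransformed TGI with PD_inflex and
hill_exp log-parametrised (positivity without constraints) and coverage
handled on a log axis. Initialisation: TGI_max = 1.1·max(TGI), PD_inflex =
median coverage, hill_exp = 1; five jittered multi-starts with a fixed
internal seed guard against local minima and make the fit deterministic.
At least four records (three with TGI_min fixed) spanning one decade of
coverage are required. Residual stratification near stasis (default band
TGI ∈ [50, 150]) reports per-group SD and IQR; with xenografts differing in
g/d and compounds sharing PTR, the xenograft stratification absorbs more of
the scatter, which is the model's explanation for IVIVC variability.

## Population extension

IC50 and g/d are independent log-normals specified by median and log-sd
(medians because cohort descriptors are reported as medians). The stasis
dose is applied elementwise; g/d ≥ 1 yields a non-responder flag, never an
infinite dose, and dose quantiles are reported among responders only. PTR
and AUC_DN,ub are compound constants across the population. With a
continuous g/d distribution of median 1 the responder fraction is 50%,
independent of the IC50 distribution and of dose — the package's formal
statement of tumour idiosyncratic resistance. Externally supplied joint
(IC50, g/d) tables (e.g. imaging-derived) are accepted in place of sampled
ones; estimating g/d from longitudinal imaging is out of scope.

## Synthetic cohort generator

The generator emulates a pre-clinical kinase-inhibitor cohort: 86 studies,
6 xenografts, 12 compounds; unbound IC50 truncated log-normal on
[0.2, 700] nM with median 7.7; total interval AUC at the reference dose on
[1.84, 4141] nM·h with median 55; unbound fraction on [0.04%, 2.3%] with
median 0.53%; PTR log-uniform on [10, 300] (quoted at τ = 24 h); g/d uniform
on [0.3, 0.7]; ≥14 days of qd or bid dosing with identical daily dose.

Choices the cohort descriptors do not pin down, made once and documented
here:

- **log-sd values** 1.5 (IC50, AUC) and 0.8 (fu): the printed ranges then
  hold essentially all of the untruncated mass. Because the truncation
  bounds are asymmetric about the medians, the truncated-lognormal location
  is recalibrated (bisection on the truncated median) so the **sampled**
  median equals the printed one exactly in distribution.
- **Reference dose 10 mg/kg** defines dose-normalised unbound AUC
  (AUC_total·fu/10); dose linearity is exact in the generator. IC50, AUC
  and fu are sampled independently, so mg/kg dose magnitudes can be extreme
  even though all coverage-based quantities are realistic.
- **Absolute rates**: g uniform on [0.004, 0.008] mm/h and R0 = 2.9 mm
  (~100 mm³), so the drug-free control grows ≥3-fold in volume over 14
  days; the cohort descriptors constrain only the ratio g/d, so magnitudes
  are conventions.
- **bid dosing**: τ = 12 h with half the daily dose; the elimination rate is
  a compound constant, so the 12-h PTR is the square root of the 24-h PTR.
  At hill = 1 this leaves the stasis dose per day unchanged, reproducing the
  observed qd/bid equivalence by construction.
- **Dose placement**: log-uniform factor on [0.03, 30] around each
  compound–xenograft pair's closed-form stasis dose, so realised coverages
  span the whole sigmoid (how doses were chosen in real studies is not
  recorded anywhere; this is a generator convention). Observed TGI adds
  Gaussian noise (sd 10 TGI units by default).

What the generator deliberately does **not** emulate: measurement dropout,
caliper error structure, group sizes, compound–xenograft pairing bias, and
correlations among IC50, fu and AUC. Passing tests on synthetic cohorts
therefore demonstrate internal consistency of the formalism and the
fitting machinery, not agreement with any particular laboratory dataset.

## Problem sizes and determinism

Default test and script workloads use cohorts of 86–300 studies, 50
replicate refits, 10⁴ calibration draws and 10⁵ population draws — sizes at
which Monte-Carlo error is comfortably below the tolerances asserted. Every
stochastic path takes an explicit seed (numpy `default_rng`); the IVIVC
multi-start uses a fixed internal seed so fits are reproducible across
calls.

## Known limitations

- The hill ≠ 1 closed form is derived under mono-exponential PK; with an
  absorption phase it is applied to the realised PTR as an approximation
  (advisory, not exact).
- TGI is undefined when the control volume change is zero; this raises a
  typed error rather than returning a limit.
- The IVIVC logistic is heuristic; no mechanistic interpretation, weighting
  by study size, mixed-effects structure or bootstrap intervals are
  provided.
- The radius floor interacts with the sub-step resolution: eradication and
  regrowth are resolved only at τ/8 granularity by default.
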