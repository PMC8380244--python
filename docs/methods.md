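# Methods

## Structural model

The model is a ten-compartment whole-body description of aluminium
kinetics. All state variables are dimensionless amounts normalised by the
administered dose (fid, fraction of ingested dose). States: a gut depot
(`A_gut`), an explicit unabsorbed-fraction sink (`A_unabs`), two circulating
blood species (`A_addCit`, injected citrate; `A_Mix`, the quasi-steady-state
mixture of all aluminium species including transferrin-bound Al), seven
tissues (`liv, spl, mus, bon, bra, kid, rob`) and cumulative urine
(`A_uri`).

Oral absorption is first order (`k_gut2blo`, default 2.43 h⁻¹) with
bioavailability `F` (default 1.82·10⁻³); the unabsorbed fraction `(1−F)` is
routed into `A_unabs` so that total mass is conserved exactly and testably —
in the source formulation this mass is simply dropped. Tissue exchange is
perfusion-limited with uptake rate `I_tis·Q_tis/V_blo` and release rate
`Q_tis/(K_tis·V_tis)`. Liver, spleen and kidney share one uptake and one
retention coefficient (`I_lsk`, `K_lsk`); the brain is modelled as a sink
(`K_bra = ∞`, release exactly 0 rather than a large number); the
rest-of-body pool has `I_rob = K_rob = 1`. Renal elimination is the only
clearance route:

    fu = (A_addCit·fu_Cit + A_Mix·fu_Mix)/A_blo,
    CL = Q_kid·fu·GFR/(Q_kid + fu·GFR),   dA_uri/dt = CL·A_blo/V_blo,

with `fu_Cit = 1`, `fu_Mix = 0.1`. When blood is empty the value of `fu` is
irrelevant (the clearance flux vanishes); `fu_Mix` is returned by convention
to avoid 0/0. Tissue release redistributes onto the two blood species in
proportion to their current shares, so redistribution does not alter
speciation. Intravenous chloride is dosed directly into `A_Mix`
(instantaneous equilibration of the chloride salt), iv citrate into
`A_addCit` with equilibration rate `k_Cit2Mix = 0.193 h⁻¹`, and oral doses
of either salt into `A_gut`, absorbed into `A_Mix`. Erythrocyte aluminium
is neglected, so the blood-to-plasma ratio is `1 − Hct` and the plasma
amount equals the blood amount. Doses are instantaneous bolus state jumps;
infusion durations are not modelled.

Internal time unit is hours; day/week conversions happen only at I/O.

## Physiology

Species physiology enters exclusively through four fixed reference
individuals (male 73 kg / female 60 kg adult human; young 250 g / old 480 g
adult rat) with literature blood volumes, tissue volumes, densities, organ
blood flows, haematocrit and GFR, shipped as a JSON resource at the printed
precision and overridable by the user. Callers pick the nearest reference
(rats by body weight, midpoint ties to the young reference; humans by sex).
Only GFR is rescaled: `SF·1.31 mL/min·(BW/0.25 kg)^¾` for rats and
`SF·105 mL/min·BSA/1.73 m²` for humans. No additional age effects are
modelled. Whole-organ masses are `V_tis·D_tis` (bone density 1.3 kg/L,
others ≈ 1).

Two printed values in the source tables are internally inconsistent with
these formulas at the stated precision: the old-rat GFR (printed 0.127 L/h;
the formula gives 0.1282) and three rat tissue half-lives (young muscle
5.84 h printed as 5 h, old kidney 4.69 d printed as 4 d, old liver 18.93 d
printed as 18 d, while neighbouring entries round half-up). The package
computes from the formulas and printed inputs; tests check those entries to
within one printed display unit and everything else to exact rounding.

## Numerics

With no injected citrate in circulation the system is linear and
time-invariant; trajectories are then evaluated exactly (to floating point)
by eigendecomposition of the transient block, with absorbing states (urine,
unabsorbed fraction, brain) accumulated through the closed-form integral
`a(t) = a0 + C·P·φ(Λ,t)·P⁻¹x0`, `φ(λ,t) = (e^{λt}−1)/λ` (series limit `t`
as λ→0, which also covers the zero-clearance case). The non-linear citrate
phase after an iv citrate dose is integrated with LSODA (analytic Jacobian)
in 48-h blocks until the circulating citrate falls below 10⁻¹³ of the dose,
whose remainder is then folded into the mixed pool and propagation continues
analytically. Default solver tolerances are rtol 10⁻⁸, atol 10⁻¹² (fid
units); mass balance is asserted to 10⁻⁸ of the dose over 150-week horizons
in the tests. A pure ODE route (`method="ode"`) exists for cross-checking and
is compared against a hand-derived bi-exponential two-compartment solution
in the tests.

## Population layer

Structural parameters vary between studies (rats) or individuals (humans):
transformed-scale random effects are normal, with a log transform for
positive parameters and a logit transform for fractions. Defaults carry
variability only where the calibration estimated it: `k_gut2blo` (ω 1.34),
`F` (1.03), `I_lsk` (1.39), `I_bon` (0.763), `K_bon` (0.556) and GFR with a
species-shared ω (rat 0.894, human 0.381, one ω spanning young/old and
male/female respectively). The source tabulates the GFR random effect as
logit-normal, but GFR in L/h lies outside (0,1) where a logit is undefined;
it is treated as log-normal here. The residual model is additive on the log
scale (log-normal multiplicative on the original scale); its magnitude is
not reported in the source, so the synthetic-data default is σ_res = 0.5
(log scale, ~±65% spread), a typical inter-laboratory tracer-assay scatter,
shared across matrices and always user-settable. Monte-Carlo population
prediction uses 250 samples by default and reports the median and central
20/40/60/80% bands.

### Estimation

`PopulationFitter` maximises a Laplace approximation of the marginal
likelihood: per group, the random-effect posterior mode is found by a damped
Gauss–Newton iteration (finite-difference Jacobians on the log scale,
frozen across accepted steps, warm-started across outer iterations) and the
Gauss–Newton curvature `JᵀJ/σ² + Ω⁻¹` stands in for the Hessian in the
Laplace determinant. The outer problem (selected fixed effects on their
transformed scale, plus log σ) is solved with Nelder–Mead. Random-effect
SDs ω are held fixed at their supplied values; by default every ω > 0
parameter carries a random effect so that the variability model matches the
generating population. Standard errors come from a central
finite-difference Hessian of the marginal negative log-likelihood with step
0.05 on the transformed scale — large enough that the profiled (not joint)
curvature is measured — with spectrum clipping as a fallback when the
optimiser stops on a shallow plateau. Two deliberate approximations trade
bias for speed and are negligible at the default noise level: during the
short non-linear citrate phase the random effects are evaluated at their
population value (their influence there is ≲10⁻⁴ of the dose), and σ is
floored at 10⁻⁴ so that noise-free data remain numerically well-posed.
Empirical-Bayes modes per group are exposed as `eta_`. Estimation
tolerances (ODE rtol 10⁻⁴, Nelder–Mead xatol 0.01/fatol 0.02) are an order
of magnitude below the statistical uncertainty of the estimates.

## Curation

Observation tables follow a CSV dialect with a study identifier
`[Study]-[Salt]-[Route]-[Species]-[BodyWeight]` (zero or more comment
tokens such as `fasted` accepted on either side of the species token, as in
the published identifiers). The pipeline (i) rejects sampling times ≤ 1 s
and incomplete urine collections, logging a reason per row; (ii)
de-aggregates each (N, mean m, sd) summary row into N log-normal
pseudo-observations with σ² = log(sd²/m² + 1), μ = log m − σ²/2, exactly
standardised on the log scale (sample mean μ and sample SD σ with ddof = 1
— the printed standardisation formula scales before centring and is only
approximate; the stated intent, exact moments, is implemented); (iii)
converts units to whole-compartment fid using the reference individual:
concentrations via compartment volume (plasma volume `V_blo·(1−Hct)`),
per-gram and per-kg tissue readings via organ mass `V_tis·D_tis`, urine
concentrations via the recorded collection volume, accumulated across
sequential complete collections; records above one administered dose are
flagged, not dropped. Doses given in moles use the ²⁶Al molar mass
(25.99 g/mol). "Serum" and "plasma" are treated identically.

## Synthetic data

The generator emulates the statistical structure of the curated ²⁶Al
dataset, not any particular study's numbers: 6 rat studies + 8 human
individuals; both routes and both salts with oral fid levels ~F (three
orders of magnitude) below iv; fid as the dominant reporting unit followed
by g/L, with per-gram and per-kg tissue units present; early blood sampling
(0.25–24 h), terminal tissue sampling, long bone follow-up (up to ~7000 h)
in two rat studies; per-study parameter draws for rats (subjects within a
study share them) versus per-individual draws for humans; and mean ± sd
summary rows for about a quarter of the records (two of the six rat
studies), matching the curated dataset's aggregate share. What it does not
emulate: digitisation error, analytical contamination, baseline ²⁷Al,
dropout, or dose-dependent (non-linear) kinetics — so green tests show the
pipeline recovers its own generating process at realistic noise, not that
these field artefacts are handled.

## Known limitations

Clearance is linear; doses above ~3·10⁻⁵ mol/kg iv in rats saturate renal
elimination and are outside the model's domain. Faecal and minor excretion
routes are neglected. Speciation is the two-pool scheme only; colloidal or
insoluble aluminium species (hydroxides, oxides, silicates) would need an
extended absorption model. The estimator is a desk-scale approximate
marginal-likelihood fitter for recovery experiments, not a replacement for
a full stochastic-approximation EM fit; with only fourteen groups carrying
six random effects each, its residual-SD estimate tends to run somewhat
above the generating value while the fixed effects themselves recover
within the tolerances the tests assert.
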