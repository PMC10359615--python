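# Methods

This note documents the models implemented in `apekin`, the assumptions
behind them, the defaults of the synthetic-data generators, and the
numerical choices that matter. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Kinetic models

**Multiple turnover (burst).** With substrate in excess of enzyme, product
formation is biphasic:

    product(t) = A·(1 − e^(−k_obs·t)) + v_ss·t

`A` (nM) is the burst amplitude — the concentration of enzyme that is
productively engaged during the first turnover; `k_obs` (s⁻¹) is the
first-order rate of the exponential phase, interpreted as the chemistry
(incision) rate; `v_ss` (nM·s⁻¹) is the steady-state velocity. The
steady-state rate constant is defined as `k_ss = v_ss/A` and is interpreted
as the product-release rate when chemistry is much faster than release.

**Single turnover.** With enzyme in excess, product formation is a rising
exponential `A(1 − e^(−k_obs·t))`, directly reporting the chemistry rate.
Some enzyme variants produce biphasic single-turnover curves; these are fit
with a double exponential, components stored amplitude-descending, and the
"major rate" is the rate of the larger-amplitude component. When the two
fitted rates collapse (relative difference < 5%) or the minor amplitude
falls below 2% of the major one, the double-exponential description is
unsupported: the fitter attaches a `degenerate-biexp` warning and refits a
single exponential.

**Phase-separation caveat.** When `k_obs/k_ss < 10` the exponential and
linear phases overlap and the two are hard to separate during fitting; the
fitter attaches a `low-separation` warning rather than silently reporting a
fragile `k_obs`. The threshold of 10 operationalizes the qualitative
caveat; it is a convention, not a fitted quantity.

## Mechanistic turnover scheme

The module `mechsim` implements the minimal scheme that produces burst
kinetics:

    E + S →(kon) ES →(k_chem) EP →(k_rel) E + P      (koff = 0 by default)

Under saturating substrate the scheme has the classical closed form with
observed burst rate `k_chem + k_rel`, amplitude `E0·f²` where
`f = k_chem/(k_chem + k_rel)`, and per-enzyme steady-state constant
`k_chem·k_rel/(k_chem + k_rel)` (≈ `k_rel` when chemistry is fast). The
observable is **incised DNA**, i.e. EP + P: a quench assay counts cleaved
substrate whether or not the enzyme has released it, and only with that
observable does the progress curve have the burst form above.

Note a subtlety: the scheme-level steady-state constant equals the fitted
`v_ss/E0`, not `v_ss/A`, because only the fraction `f²` of the enzyme
contributes to the burst amplitude. The two coincide in the
`k_chem ≫ k_rel` limit, which is the regime where the empirical
identification "`k_ss` = product release" is quantitative; outside it the
identification is only qualitative.

Numerics: mass-action ODE integration uses LSODA with rtol 1e−8 and atol
1e−10 nM, because rates of interest span roughly 1e−4 to 1.3e2 s⁻¹. The
stochastic simulator is an exact Gillespie implementation over counts
(bimolecular propensity `kon·nE·nS`); concentration↔count conversion is the
caller's responsibility. Binding is fast by default (`kon` = 100 nM⁻¹s⁻¹,
`koff` = 0) because the empirical burst model contains no binding step;
both are exposed for sensitivity work. Validation (in the test suite): a
burst fit of the ODE curve recovers the closed forms within 5% at
saturating substrate, and the Gillespie trajectory mean matches the ODE
within Monte-Carlo error. The oracle-equivalence tests use S0 = 10·E0 so
the saturating-substrate assumption holds over the fitted window; at
smaller substrate excess free substrate is exhausted before the steady
phase is established and the closed form no longer applies.

## Tight binding

At 5 nM probe DNA, affinities of order 1 nM violate the free ≈ total
approximation, so titrations are fit to the Morrison quadratic with the
DNA concentration fixed. The implementation evaluates the algebraically
equivalent form `2·A_T·B_T/((A_T+B_T+K_D) + √((A_T+B_T+K_D)² − 4·A_T·B_T))`
to avoid catastrophic cancellation as K_D → 0; equality with the textbook
form is property-tested. Two failure modes are surfaced explicitly:

* saturation-only data (all points > 95% bound) make K_D unidentifiable
  and raise an error with guidance;
* an estimated K_D below the probe concentration, or with relative
  standard error above 25%, earns a `tight-binding` warning — at 5 nM DNA
  the titration cannot resolve sub-nanomolar affinities, only bound them.

## FRET analysis

The proximity ratio is `E = I_665/(I_665 + I_563)`. The predicted
no-interaction value sums the component emission spectra channel-wise
before taking the ratio; this equals the ratio of the channel-sum read, an
identity that is property-tested.

**Plateau averaging.** A titration point is accepted once the trace is
stable: the earliest trailing segment (≥ 60 s) whose relative standard
deviation *and* whose fitted linear drift are both ≤ 2% of the mean is
averaged. The drift criterion is required because a slow monotone ramp can
have an arbitrarily small sd over a minute while never settling; sd alone
cannot distinguish "settled" from "drifting slowly". The 60-s window is
the stated protocol; the 2% tolerance is a design choice.

**Normalization and competition.** Exchange titrations are normalized to
[0, 1] between the no-titrant anchor (Y-Max) and the predicted
no-interaction value (Y-Min). Competition titrations are analyzed by
linear interpolation of the 50% crossing on the normalized curve — not a
four-parameter logistic — because the reported quantity is the crossing
ratio itself. The competition generator uses proportional partitioning
with limiting active protein: labeled-bound signal `y = L/(L + ρC)` where
ρ is the competitor's relative affinity. With identical affinities the
50% crossing falls at a competitor fraction of exactly 0.50, which is the
analytic self-consistency check of the approach; a competitor binding
1.5-fold tighter moves it to 0.40. The limiting-protein assumption is the
only regime in which the 0.50 expectation holds exactly; it encodes the
assay's design intent rather than a measured active fraction.

## Mass photometry

Histograms of landing-event masses are fit by nonlinear least squares to
`f(x) = Σ aₙ·exp(−((x − bₙ)/cₙ)²)`. This form is implemented exactly as
written — without the conventional ½ factor in the exponent — so the width
parameter relates to a standard Gaussian σ by `c = σ√2` and the component
area is `a·c·√π`. Population fractions are area ratios `aᵢcᵢ/Σaⱼcⱼ`
(the √π cancels). Component means are initialized from prominence-ranked
peaks of the lightly smoothed histogram, padded with weighted quantiles if
fewer peaks than components are found; fitted components closer than half
the wider width earn a `component-collapse` warning. Contrast-to-mass
calibration regresses mixture-fit peak centers of a known standard against
its known masses (affine least squares; exact interpolation with two
peaks).

The default two-component truth places the 1-RPA and 2-RPA complexes at
150 and 266 kDa (a ~34 kDa junction DNA plus one or two ~116 kDa RPA
heterotrimers) with σ = 12 kDa, typical of mass-photometry peak widths.
The recovered population fractions are insensitive to these choices as
long as the peaks are resolved.

## Fitting contract

All fits use trust-region-reflective least squares (lmfit) with positivity
bounds, data-driven initial guesses (burst: `v_ss` and `A` from a linear
fit of the tail, `k_obs` from a log-linear fit of the early rise; Morrison:
K_D from the half-saturation point), and a deterministic five-step
multiplicative restart ladder (×1, ×0.3, ×3, ×0.1, ×10) keeping the best
residual. Standard errors come from the covariance at the optimum; the
steady-state constant's error uses first-order ratio propagation, as do
fold-change errors.

Residuals are unweighted by default, matching gel/plate quantification
practice where the error structure is unknown. The kinetic fits accept an
optional per-point σ for inverse-variance weighting; the recovery harness
uses it with the generator's known noise model, since weighting by the
true variance is the efficient estimator there. A Wald–Wolfowitz runs test
on residual signs (normal approximation, two-sided p < 0.01) flags
structured residuals after a single-exponential fit — the symptom of
biphasic data forced through a monophasic model. The runs test is a
warning, not an automatic model-selection rule.

## Synthetic-data generators

Generators evaluate the closed-form models (or the ODE scheme) at the
standard designs and add seeded Gaussian noise
`y′ = y(1 + cv·z₁) + floor·z₂`: cv = 3% with a 0.5 nM floor for
concentration signals, 0.005 for dimensionless signals. The 3% figure
reflects typical replicate scatter of quantified band intensities; the
floor models detection/background noise at low signal. Time grids are 30
log-spaced points from the 0.002-s rapid-quench minimum to 10/k_obs,
covering the exponential rise and the linear phase; titrations use 16
enzyme points from 0 to 2000 nM. Every generator is deterministic under
its seed and embeds its truth parameters in the returned container (and in
the `# truth:` CSV header), enabling blind recovery tests.

What the generators do **not** emulate: pipetting/dilution series error
correlated across a titration, gel-lane background and smearing,
photobleaching and spectral crosstalk in FRET traces, instrument dead-time
distortion at the earliest quench points, and day-to-day enzyme-activity
variation. Passing recovery tests therefore demonstrates that the
inference machinery is correct and well-conditioned at realistic noise
levels — not that real instrument data will reach the same precision.

## Problem sizes

Recovery experiments use 3 replicates × 30 time points (kinetics), 3 × 16
titration points (binding), 5000 landing events (mass photometry), and a
201-point noiseless competition curve; the stochastic-vs-ODE comparison
averages 150–200 Gillespie trajectories of ~300 events each. These sizes
match the scale of the corresponding experiments while keeping the full
suite fast.

## Known limitations

* The burst model ignores substrate depletion; generators evaluate it
  as-is, so very long synthetic multiple-turnover curves can exceed the
  nominal substrate pool. Fit windows at the standard designs end well
  before this matters.
* `k_ss` is identified with product release only in the fast-chemistry
  limit (see the mechanistic section).
* Fold-change uncertainties use first-order ratio propagation; published
  uncertainty conventions for such ratios vary, so only central fold
  values should be compared across sources.
* The double- vs single-exponential choice is surfaced via warnings
  (degeneracy, residual structure), not decided by an information
  criterion.
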