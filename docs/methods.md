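# Methods

## Data model

A dose-response table is a set of *G* dose groups (dose *dᵢ*, size *nᵢ*,
events *yᵢ*), sorted ascending by dose, with distinct doses (ties are
rejected rather than pooled, since pooling changes the likelihood). Doses are
opaque numerics in the units of the source study; no unit conversion is
attempted. Group rates *rᵢ = yᵢ/nᵢ* are always derived from the counts and
never trusted from an input column. Groups are treated as binomial
denominators (risk), not person-time (rate); individual-level records are out
of scope. A table may be stored with any *G* ≥ 1, but the posterior
assessment of dose-responsiveness requires *G* ≥ 3, because a dose-response
pattern needs at least three points to be distinguishable from a step or a
fluke.

The built-in paracetamol–asthma cohort stores the five published dose groups
exactly as printed (doses 0, 10, 31.67, 60, 86.67; the non-integer doses are
kept verbatim, not reconstructed as interval midpoints).

## Likelihood

The grouped binomial log-likelihood is evaluated entirely in natural-log
space with `scipy.special.gammaln` for the binomial coefficients (stable to
*n* ~ 10⁹). The 0·ln 0 = 0 convention is applied explicitly for degenerate
groups (*yᵢ* = 0 with *f* = 0, *yᵢ* = *nᵢ* with *f* = 1). A predictor that
assigns probability zero to observed data yields a *flagged* −∞ result rather
than an exception, so that model comparison can proceed. Raw probabilities
(≈ 10⁻¹² for cohort-sized tables) are exponentiated only for display.

The flat-model null uses the least-squares constant k̃ = ⟨r⟩, the arithmetic
mean of the observed rates — the closed-form minimiser of Σ(rᵢ − k)². This
is *not* the pooled binomial MLE Σyᵢ/Σnᵢ; the two generally differ (on the
built-in cohort: 1.1951 × 10⁻³ vs 1.0058 × 10⁻³), and since the pooled MLE
maximises the binomial likelihood over constants it can only score at least
as high. The mean-of-rates definition is the framework's, and is the
default; `null_likelihood(..., estimator="pooled_mle")` exposes the
alternative.

## Candidate families and fitting

Seven shapes are registered: constant (the null), linear, quadratic, cubic,
exponential α·e^{βd}, Emax E₀ + Emax·d/(ED₅₀ + d) and sigmoid Emax with a
Hill exponent. The Emax parameterisations follow dose-finding convention;
they are extensions beyond the four families of the original analysis.

Fitting minimises the unweighted sum of squared residuals on the observed
rates, matching the least-squares derivation that defines the null
(`weighted=True` optionally weights by *nᵢ*). Polynomials use exact linear
least squares on the Vandermonde design; nonlinear families use
`scipy.optimize.least_squares` (Levenberg–Marquardt for the exponential;
trust-region-reflective with positivity bounds on ED₅₀ and the Hill exponent
for the Emax shapes) with analytic starting values — for the exponential, a
log-linear regression of ln rᵢ on dᵢ over the positive rates. Convergence
tolerances are 10⁻¹⁵ on the scaled step, gradient and cost change, capped at
10⁴ function evaluations.

Because the fitted curve is interpreted downstream as a binomial success
probability, a fit whose predictions leave [0, 1] anywhere on a 201-point
grid over the data's dose range is rejected with a domain error; predictions
are never silently clamped.

### Fit criteria

AIC and BIC use the full Gaussian maximum-likelihood convention with the
residual variance counted as a free parameter, so the effective parameter
count is k = p + 1:

    AIC = 2k + n ln(2π·rss/n) + n,  BIC = k ln n + n ln(2π·rss/n) + n

hence BIC − AIC = k(ln n − 2) identically. This convention was chosen
because the published AIC/BIC pairs for the four original families at n = 5
are spaced by exactly k(ln 5 − 2) only under k = p + 1. The published
*absolute* AIC/BIC/R² values are not reproducible from the printed
information — they were computed on an estimation subset that was never
stated — and are not asserted anywhere; on the full five-group table the
quadratic, not the exponential, attains the best score under every
criterion. An interpolating fit (rss = 0) reports NaN information criteria
with a perfect-fit flag rather than −∞.

Selection defaults to lowest AIC, ties broken toward fewer parameters, then
family name; `r2`/`adj_r2` rank higher-is-better. The full ranked table is
always part of the result.

## Posterior of dose-responsiveness

The hypothesis space is binary, {DR, D̄R̄}. P(data|DR) is the plug-in
likelihood of a single selected DR model at its fitted (or externally
supplied) parameters — the printed worked example matches this plug-in
reading, not an integrated marginal likelihood. P(data|D̄R̄) is the flat-model
likelihood at k̃. The posterior is computed by log-sum-exp; degenerate priors
short-circuit (prior 0 → posterior 0, prior 1 → 1), and posterior odds equal
prior odds times exp(Δ log-likelihood) exactly.

The default prior P(DR) = 0.5 is equipoise: the prior is a clinical input
that the framework deliberately leaves to the analyst, and every report
carries the prior it used. Posteriors are reported at full precision plus a
two-decimal display rounding. Prior-sensitivity sweeps evaluate the
posterior on a grid of priors; each curve runs from (0, 0) to (1, 1)
monotonically, and the curve of a higher-likelihood model dominates
pointwise, so curves never cross.

### Trend test

The MCP-style signal-detection step is concretised as the Cochran–Armitage
trend test on the grouped table with the actual dose values as scores:

    Z = Σᵢ (yᵢ − nᵢ·p̄)·dᵢ / sqrt( p̄(1 − p̄)·[Σnᵢdᵢ² − (Σnᵢdᵢ)²/N] )

with pooled rate p̄ and a two-sided normal p-value. Degenerate tables (no
events, all events, exactly flat) return Z = 0, p = 1. The test is validated
against a permutation oracle that redistributes the total event count over
groups by multivariate hypergeometric sampling.

### A known anti-conservativeness

Every non-constant candidate family nests (or effectively nests) the
constant null, and the plug-in likelihood carries no complexity penalty, so
for data generated under a *flat* truth the selected DR model's likelihood
still exceeds the null's in the large majority of replicates: at the
built-in cohort's design, the mean posterior under a flat truth is ≈ 0.78
with four candidate families (≈ 0.63 with the exponential alone), not below
the 0.5 prior. The posterior, in other words, measures how much better the
best dose-response *shape* explains the data than a constant — a quantity
that is biased upward under the null. The trend test reported with every
assessment is the guard for this case (its type-I error is the nominal ~5%
under the flat truth), and the validation suite asserts the honest
comparative property: flat-truth log Bayes factors are small, dose-responsive
ones are large. Held-out evaluation (fitting on one subset of groups and
evaluating the likelihood on another, as the source analysis footnotes but
does not specify) would remove the bias; the default evaluates on the full
table, which is the configuration that reproduces the published numbers.

## Synthetic cohorts

The simulator draws yᵢ ~ Binomial(nᵢ, f(dᵢ|θ)) independently across groups,
after validating f ∈ [0, 1] at every configured dose. One seed governs an
experiment; per-replicate generators are spawned from a `SeedSequence`, so
any replicate is reproducible in isolation and identical configurations give
bit-identical output. Noise-free mode sets yᵢ = round(nᵢ·f(dᵢ)) (round half
to even), giving near-exact recovery targets; note that at group sizes
~10⁴–10⁵ the integer rounding itself perturbs rates at the few-percent level
relative to event probabilities of ~10⁻³, so near-exact recovery checks use
larger groups.

Default experiment scales — 200–500 replicates at five dose groups with
sizes of order 10⁴–10⁵, mirroring the built-in cohort's design — run in
seconds on one CPU. The generator emulates only binomial sampling noise
around a known shape: no confounding, covariates, person-time censoring or
reporting bias. Passing recovery/discrimination experiments therefore shows
the estimation and decision machinery is correct under the stated model,
not that the method is robust to the biases of real observational data.

## Evidence-amalgamation network

The network is a DAG over the framework vocabulary: causal hypothesis C
(root), indicators Δ (difference-making), PD (probabilistic dependence), DR
(dose-response), RoG (rate of growth), M (mechanism), T (time course), an
M → T edge (mechanism entails the right time course), report nodes attached
to the indicator(s) their study design speaks to (RCT → {Δ, T, DR, RoG};
cohort → {T} ∪ Σ; case-control → Σ; case report → {T, Δ}; basic science →
{M}, where Σ = {PD, DR, RoG} is a grouping label, not a node), and
study-quality modulator nodes (sample size, duration, adjustment,
randomisation, blinding, sponsorship bias) as additional report parents.
Edges are epistemic dependence relations, not causal mechanisms; the module
is not a causal-discovery tool. Multiple reports on one indicator are
conditionally independent given that indicator — an assumption, stated here
because the framework does not fix it.

CPTs are user configuration: the framework fixes the structure and three
logical entailments — P(T=1|C=1) = 1, P(M=1|C=1) = 1, and zero joint mass on
DR=1 ∧ PD=0 — which `validate_entailments` checks numerically (violations
reported, not raised; checks for absent nodes are skipped with a notice).
A fully parameterised example configuration satisfying all three ships with
the package, including the canonical diagnostic report rows
P(ES=1|DR=1,T=1) = 1 and P(ES=1|DR=0,T=0) = 0.

Inference is exact enumeration over the joint (networks here are ≤ ~20
nodes; no approximate inference), with conditioning-on-null evidence raising
a domain error. d-separation uses the standard reachability algorithm over
chain/fork/collider rules and is cross-checked in the test suite both
against `networkx.is_d_separator` and for soundness against enumerated
joints. The dose-response posterior bridges into the network as *virtual
(likelihood) evidence* on the DR node — a likelihood-ratio finding rather
than a hard state — since the framework does not specify the coupling;
`infer(..., virtual_evidence=...)` implements it.

Networks serialise to a YAML schema (nodes, states, parents, CPT rows keyed
by parent states) with row-sum validation to 10⁻¹² and entry-precise error
messages.

## Worked-example reproduction

`reproduce_paracetamol_example` defaults to the published exponential
parameters (θ = (1.01266 × 10⁻³, 4.17805 × 10⁻³)) because the goal of that
entry point is reproduction; a `refit` path re-estimates θ by least squares
on the full table (it lands within ~0.25% of the published values, though
the published criteria table itself is not reproducible, see above). The
comparison table reports each computed quantity against its published
reference with the absolute deviation, and flags the one documented
discrepancy: the published predicted rate at dose 86.67 is 1.46 × 10⁻³,
while α·exp(β·86.67) evaluates to 1.4545 × 10⁻³ (rounding to 1.45 × 10⁻³).
The flag is reported; agreement is not forced.

## Limitations

- Risk, not person-time: groups are binomial denominators; the source
  cohort's proportional-hazards adjustments are not modelled.
- Single-model plug-in likelihood for DR (no model averaging, no parameter
  marginalisation); anti-conservative under the flat truth as described.
- Study-quality modulators of the dose-response evidence are a reserved,
  unimplemented field in the posterior report.
- No multiple-testing control across drug–event pairs.
- CPT values, priors and the virtual-evidence bridge are analyst inputs;
  the package validates and propagates them but cannot supply them.
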