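# Methods

## The pathway

The hypothetical adverse outcome pathway has one dose root and 19 biology
nodes: two molecular initiating events (MIE1, MIE2) whose ligand products
BM1–BM4 activate a receptor (KE1); a signalling cascade BM5→BM6→BM7→BM8;
two transduction products — KE2 (chronic phase) and KE3 (acute phase);
chronic key events KE4–KE7 feeding KE8; and the adverse outcome AO
downstream of KE8. Acute-phase nodes (MIEs, BMs, KE1, KE3) respond at
every exposure repetition; chronic-phase nodes (KE2, KE4–KE8, AO) respond
only from a donor-specific onset repetition onward. The wiring gives each
key event a characteristic lag to AO along the directed pathway: 1 for
KE8, 2 for KE4–KE7, 3 for KE2 and KE3. The graph is serializable JSON and
fully overridable; validation enforces acyclicity, a single dose root and
a single childless AO, role/phase consistency, and reachability of every
node from the dose root.

Two wiring choices were genuinely open and are fixed as: ligand
production is MIE-mediated (DOSE feeds only the MIEs), and BM5–BM8 form a
chain rather than a fan-out, which is what produces the lag structure
above.

## Virtual data generator

Study design defaults: doses (0, 50, 100, 200) with 0 the untreated
control (dose units are arbitrary concentration; only the design doses
enter the analyses), 8 donors, 6 exposure repetitions, 3 replicates.
Donor onsets follow the fixed donor table (onsets 4,3,4,3,4,3,none,none
with severity grades severe/severe/moderate/moderate/weak/weak/none/none).

Per donor, node and exposure, mean fold changes follow two uniform-
increment recursions: f̄(d+1) = f̄(d) + U(0,1) across the dose index, and
f̄(e+1, d₁) = f̄(e, d₁) + U(0, 0.2) advancing the first-treatment-dose
baseline across exposures, with the dose recursion rerun outward from
that baseline. Control cells are pinned at f̄ = 1, s = 0. Chronic cells
before onset are indifferent noise 0.8 + 0.4·U(0,1); at onset the dose
recursion restarts from the control anchor. The replicate SD follows
s(d+1) = (f̄(d) + ζ(f̄(d+1) − f̄(d)))/(4 + 6ζ), one fresh ζ ~ U(0,1) per
cell, so larger dose jumps carry larger noise. The same SD recursion is
applied to pre-onset chronic cells (a value is needed for the lognormal
parameterization; the paper-level description leaves it open and the
resulting s is small and positive). The RNG stream order is fixed
(donor → node → exposure → dose), so one seed reproduces the table
bit-for-bit.

Because the exposure recursion advances only the d₁ baseline while dose
increments are redrawn each repetition, mean fold change is *strictly*
monotone in dose everywhere, monotone in exposure at the first treatment
dose, and increasing in exposure in expectation (by +0.1 per repetition)
elsewhere. An overall exposure-monotone variant would instead sacrifice
exact dose monotonicity; the dose axis was prioritized because
dose-response is the pathway's defining structure.

Severity grades are donor metadata by default — the generative recursions
treat every elicited donor identically, which is what the study's
reported probabilities imply. An optional graded mode scales chronic
increments by 1.0/0.6/0.3 (severe/moderate/weak) for users who want
severity to carry magnitude.

## Replicate resampling

Each (donor, exposure, dose) cell is converted to a multivariate
lognormal by exact moment matching on the natural-log scale, with
cross-node correlation taken from the empirical node×node Pearson matrix
of mean fold changes pooled over the exposure's donor×dose cells
(control cells included; a flag excludes them). The assembled covariance
can be indefinite after plugging in an empirical correlation; it is
repaired by eigenvalue clipping at 10⁻¹⁰ with the marginal variances
restored.

Per-node linear-Gaussian conditionals on the pathway parents are learned
from κ = 100 log-scale draws per cell, regressing through the origin
(control cells sit exactly at log 0, and the conjugate-update design
matrix is the parent submatrix). The residual variance is plugged in as
its OLS estimate with denominator κ − |Π|. The conjugate Gaussian update
(posterior precision = prior precision + XᵀX/σ²) is implemented and
exposed; by default each exposure uses its flat-prior limit — the
posterior is the OLS estimate with covariance σ²(XᵀX)⁻¹, i.e. the same
treatment the first exposure always receives. Literal chaining of the
previous exposure's posterior as the prior is available
(`train_network(prior="chained")`) but is not the default: for a chronic
node with an acute parent, the pre-onset exposures constitute a genuinely
informative "no relationship" prior, and chaining shrinks the conditional
of a newly elicited node by roughly the fraction of pre-onset history —
visibly flattening the downstream node fits in a way the study's reported
fit pattern contradicts.

Replicates are drawn from the posterior predictive: each replicate row
starts as a test draw from the cell's moment-matched normal (one shared
row per replicate preserves cross-node coupling), each node with parents
is redrawn from N(xβ̂, σ² + xVxᵀ) given the test values of its parents,
and MIEs (whose only parent is the constant within-cell dose) keep their
marginal draw. Values are exponentiated back to fold changes and
replicate-averaged (R = 3 by default). All downstream analyses use the
log of these replicate means.

This construction localizes estimation distortion to the two
acute-regulated chronic nodes (KE2, KE7): their conditionals regress an
elicited response on a parent whose variation is dose-driven, so their
recorded values are noisy and weakly coupled to the rest of the chronic
block — the intended "information bottleneck" behavior.

## Regression analyses

Dose–response per node and exposure: linear mixed model with donor random
intercept, maximum likelihood (not REML, so likelihood comparisons remain
valid), conditional R² by the Nakagawa–Schielzeth variance partition.
When the donor-intercept variance hits the zero boundary and the solver
fails, the boundary solution (fixed-effects OLS) is used with σ²_donor = 0.
Response–response: the same mixed model on node pairs with all exposures
pooled (recorded in both directions — the model is not symmetric), and a
cubic polynomial alternative with training R². R² quantities are
invariant to the logarithm base.

## Static Gaussian Bayesian networks

One network per exposure repetition, donors and doses pooled (32 rows):
per-node OLS on the pathway parents with dose as a continuous root,
residual variance RSS/(M−p), training R² recorded per node. Activation
probabilities are estimated by logic sampling — ancestral simulation with
the dose root drawn uniformly over [0, max dose] (the sampling dose
distribution is not dictated by the design; uniform is the neutral
choice) — and windowed on dose with half-width ε defaulting to 5% of the
dose range. Probability surfaces are tabulated over a 21-point Δ grid on
[0, 1] and the design doses plus 17 interpolated dose points, and
integrated by the composite trapezoid rule (VUS). The empirical
exceedance is computed by sorted search, so monotonicity in Δ is exact.

## Dynamic Bayesian network

First-order Markov across exposure slices, no within-slice edges, and no
stationarity: coefficients β(e) are learned separately for every pair of
successive slices (e−1, e), per node, by ridge regression on the lagged
pathway parents with the penalty chosen per fit by efficient leave-one-out
cross-validation over 50 log-spaced values in [10⁻⁴, 10²]. Dose is a
stratification variable, not a node: either all doses are pooled (32 rows
per slice fit) or each treatment dose is fit separately (8 donor rows —
flagged as small-sample). Residual variance is RSS/(M−p−1).

Transition probabilities P(AO > Δ at e | KE > Δ at e−τ) are estimated by
resampling whole trajectories from the fitted network — a bootstrap of
the empirical state at the first exposure, then the slice models forward
with Gaussian residual noise — and applying the inequality evidence as
0/1 likelihood weights to the network-resampled state at e−τ. Parentless
nodes (the MIEs) are redrawn at each slice from their empirical marginal,
independently per node, consistent with the absence of within-slice
edges. An evidence-anchored variant (bootstrap of the empirical rows at
e−τ itself) is available; it yields systematically higher long-lag
probabilities because the conditioning state then carries the full
empirical cross-node coupling rather than the network's own τ-step
uncertainty. Binomial standard errors on the conditioning counts are
reported with every estimate.

Estimates conditioned per dose group rest on eight donor rows and are
error prone; they carry their conditioning counts and a small-sample
warning is emitted at fit time.

## Pruning

Per slice and node: multi-parent nodes are refit by lasso with an
LOOCV-selected penalty (predictors standardized for the penalty, exact
zeros at the selected penalty drop the edge); single-parent nodes keep
their edge only if the OLS slope's t-test p-value is below 0.05. Edges
whose child instance has no remaining directed path to any AO instance in
the unrolled slice graph are then culled (this pass is idempotent; note
that on a finite horizon, end-of-horizon instances are culled simply
because their path to AO would overrun the study). Surviving parent sets
are refit by OLS (relaxed lasso) and the transition probabilities are
recomputed on the refit chain; a queried (KE, e−τ, AO, e) pair with no
kept lagged path is reported as conditionally independent rather than
given a number.

## What the virtual data do and do not emulate

The generator reproduces the qualitative anatomy of repeated-exposure
chronic toxicity: dose-monotone acute responses, donor-varying onset,
exposure-dependent growth after onset, jump-driven replicate noise, and
within-exposure response–response correlation. It does not model
pharmacokinetics between exposures, receptor saturation or other
nonlinearity, measurement batch effects, donor covariates, or any real
biological pathway — all increments are independent uniforms. Passing
tests therefore demonstrate that the estimation machinery recovers the
structure this generator encodes at the study's sample sizes (32 pooled
rows per slice, 8 donors per dose), not that the pipeline is validated
on real toxicology data.

Two quantitative limits of the framework are worth knowing. First, the
generator's increment draws are independent across nodes within the
elicited block, which puts an irreducible residual (σ ≈ 0.2 on the
natural-log scale) on any one-step lagged conditional; conditional
exceedance probabilities estimated through the network therefore top out
near 0.85 even where the ground-truth conditional exceedance in the
primary table is ≈0.95. Second, the minimum node-fit R² across all
chronic nodes and exposures is a fragile statistic of a 32-row fit:
typical values are 0.7–0.95, but single cells dip below 0.6 in roughly
half of the realizations.

## Numerical conventions

Δ defaults to log₁₀2 ≈ 0.30103 in log fold-change units; exceedance is
strict. Probabilities are Monte-Carlo fractions at 10⁵ trajectories
(10⁴ per dose group). All randomness flows from named per-stage seeds
derived from one master seed by SHA-256, each below 2³¹. Degenerate
cells (control: all draws identical) fall back to zero-coefficient,
zero-variance conditionals, which back-transform to fold change exactly 1.
The acceptance summaries use ten study realizations; problem sizes are
chosen so the full reproduction runs in minutes on one CPU.
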