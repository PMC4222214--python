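# Methods

## The measure

For two species observed over n surveys, write the 2×2 presence table as
c (both present), d (first only), e (second only), f (neither). The
directed odds ratio of species A indicated by species B is

    OR(A | B) = Odds(A | B present) / Odds(A)
              = (c/e) / ((c+d)/(e+f)),

with the mirrored form for B indicated by A. The denominator is the
*marginal* odds, not the odds given B's absence, which is what makes the
measure asymmetric: it answers "how much does seeing B improve my
bet on A relative to base rates", the question a field observer actually
asks of an indicator species. Equivalently it is the positive likelihood
ratio of the diagnostic test "B present" for the condition "A present",
sensitivity / (1 − specificity); its reciprocal plays the same role for
A's absence, so one statistic serves indication and contraindication.

Structural properties, each verified exhaustively over all small integer
tables in the test suite:

- Both directed ratios always lie on the same side of 1 (their sign is
  the sign of cf − de), so one species can never indicate a partner that
  contraindicates it.
- The two directed ratios coincide exactly when the species are equally
  common (d = e), never co-occur (c = 0, both ratios 0), or are exactly
  independent (cf = de, both ratios 1). The independence case is a
  caveat worth noting: statements of the equal-iff-equally-common-or-
  disjoint rule implicitly exclude the trivial both-equal-1 situation,
  since OR_A/OR_B = 1 iff (e − d)(de − cf) = 0.
- A species with more than 50% presence cannot indicate (OR > 3) a
  species with less than half its presence rate, though the reverse
  indication is possible — the measure deliberately encodes that a very
  common species is a poor indicator of anything rare.

Zero and infinite ratios are returned exactly (never co-occurring /
perfectly co-occurring pairs), not continuity-corrected, because they
are displayed as qualitatively special edges; a Haldane–Anscombe +0.5
correction is available but off by default. Tables may be counts or
percentages — only proportions enter the ratios.

## Estimation and uncertainty

Every directed pair is fitted independently, target presence regressed
on predictor presence:

- **Independent surveys** (`raw`/`logistic`): ordinary logistic
  regression. With a single binary covariate the model is saturated, so
  the maximum-likelihood solution is closed-form — fitted probabilities
  are the cell proportions and the (intercept, slope) covariance is the
  standard inverse Fisher information with entries 1/(n_k p_k q_k). The
  `raw` path computes all n(n−1) pairs at once from vectorised
  contingency counts; `logistic` builds an explicit per-pair fit object.
  Both equal the closed-form contingency ratio to machine precision
  (asserted at 1e-9), and the closed form is verified against
  statsmodels' IRLS in the tests. The point estimate is formed in the
  exact ratio c(n − n_t)/((n_p − c) n_t) so that boundary values such as
  OR = 3 classify exactly under the strict > 3 rule.
- **Repeated surveys per site** (`glmm`): a binomial-logit mixed model
  y_ij ~ Bernoulli(logit⁻¹(β₀ + β₁ x_ij + u_i)), u_i ~ N(0, σ²) per
  site, fitted by maximising the Laplace-approximated marginal
  likelihood (one-dimensional mode/curvature per site, Newton inner
  loop) over (β₀, β₁, log σ) with L-BFGS-B. σ lives on the log scale
  with a floor at exp(−10); when the best mixed fit does not improve on
  the exact σ = 0 (plain logistic) likelihood — identically the case
  with one survey per site, where σ is structurally unidentified along a
  (β, σ) ridge — the fit collapses to the logistic solution. The
  fixed-effect covariance is the inverse finite-difference Hessian of
  the negative marginal log-likelihood. The fit is cross-checked in the
  tests against R lme4::glmer (Laplace) on a fixture (agreement ~2e-3 on
  coefficients, σ and logLik) and the likelihood itself against two
  independent evaluations of the exact marginal likelihood (adaptive
  Gauss–Hermite at 21 nodes, and direct numerical integration). Note the
  Laplace objective differs from the exact likelihood by O(1) for
  Bernoulli responses (≈0.01–0.05 per site here); agreement at 1e-3 is
  asserted between the two exact-likelihood routes, not between Laplace
  and exact.

From any fit with conditional linear predictors z₀ (predictor absent)
and z₁ (predictor present) and predictor prevalence b, the directed odds
ratio is reconstructed as

    OR = exp(z₁ − g(p̄)),   p̄ = (1−b) g⁻¹(z₀) + b g⁻¹(z₁),

g the logit: conditional odds over marginal odds rebuilt from the fit.
For the saturated logistic fit this reduces algebraically to the
contingency formula (a mandatory test). The standard error of log OR
comes from the delta method with the analytic gradient

    ∂/∂β₀ = 1 − [(1−b) p₀q₀ + b p₁q₁] / p̄q̄,
    ∂/∂β₁ = 1 − b p₁q₁ / p̄q̄,

checked against finite differences at 1e-4 relative, and against a
10,000-draw nonparametric survey bootstrap within 10% (the bootstrap
comparison is run at a sample size, n = 400 at the worked-example
proportions, where no resample lands on an empty cell; at n = 100 the
bootstrap SD of the log OR is inflated by near-degenerate resamples and
a robust scale estimate would be needed instead). Intervals and
p-values are Wald on the log scale. Two conventions follow the simplest
reading of the design: z₀, z₁ are conditional (site effect = 0), and b
is the proportion of *surveys* with the predictor present, consistent
with the survey-level contingency definition; marginalising the random
effect out of p̄ would be the main alternative.

Pairs with an empty cell (separation) keep their 0/∞/finite boundary
estimate but carry no SE, interval or p-value, mirroring how such
estimates are reported in practice rather than dropping them.

## Network assembly

Species present in fewer than 10% of the analysed surveys are dropped
before estimation (recomputed within any survey subset). Estimates with
OR strictly above 3 become indication edges, strictly below 1/3
contraindication edges; both thresholds are configurable and the
defaults mark an "ecologically substantial" association — an OR of 3 is
the 10→25→50→75→90% ladder on the percentage scale. Each edge carries an
unadjusted significance flag (Wald p < α) and a conservative Bonferroni
flag at α/n with n the number of retained *species*: the n(n−1) ratios
are derived from only n presence variables, so dividing by the pair
count would overcorrect (available as an option). Non-significant
substantial edges stay in the network with their flags — the diagram is
drawn from the OR criterion with significance reported alongside.

## Null simulation

To calibrate how many substantial associations a pure-noise assemblage
would produce, `simulate_null` draws every species independently
Bernoulli at a specified prevalence profile over a specified survey
count, estimates all directed pairs, and tallies per replicate the
counts above/below the thresholds, total and significant (a count is
"significant" only with a finite OR and defined p-value; 0/∞ estimates
appear only in the threshold-only tallies). Optional per-species site
random intercepts preserve repeated-survey clustering, with a
configurable cross-species correlation representing shared habitat
responses; the default profile matches the packaged woodland-bird study
(38 species at their printed remnant prevalences, 795 surveys).

A finding worth recording: under this independence design the spurious
associations are dominated by *contraindications* between rare species
pairs (at prevalence 0.11/0.11 and n = 795, P(OR < 1/3 and p < .05) ≈
0.007 per directed pair against ≈ 0 for the upper tail), giving a median
of 0 significant spurious indications and a mean near 0.8 significant
spurious contraindications per replicate. Published analyses of this
survey design report the opposite asymmetry (a couple of spuriously
large ratios, none small) from a simulation whose exact protocol is not
public; no independent-presence design matched to these margins
reproduces that asymmetry, with or without site clustering, so the
package reports what its stated design actually yields.

## Synthetic communities

`generate_community` plants known associations: for a designated pair
the co-occurrence cell is solved from the margins and the *directed* OR
(linear in the cell: c = p_B · OR·odds_A/(1 + OR·odds_A); the classical
cross-product ratio is also supported, solving the quadratic
(ψ−1)c² − [1 + (p_a+p_b)(ψ−1)]c + ψ p_a p_b = 0 and taking the root
inside the Fréchet bounds) and surveys are drawn from the resulting
four-cell distribution; all other species are independent. Site
intercepts shift every probability on the logit scale before the cell is
solved, clamping to the Fréchet bounds at sites whose shifted margins
cannot attain the ratio. The generator emulates the structure of a
longitudinal survey programme — ~200 sites, a few surveys per site,
prevalences 0.1–0.85, site heterogeneity on the logit scale — but not
its biology: no detection error, no temporal trend, no cross-species
site correlation unless requested, and associations only between
disjoint pairs. Passing recovery tests therefore demonstrate that the
estimators recover the parameters of this generating process at study
scale, not that real assemblages satisfy the model.

## Visualization

Nodes are banded by prevalence ((0.75, 1] red, (0.50, 0.75] orange,
(0.25, 0.50] light brown, (0.10, 0.25] yellow, (0.036, 0.10] green,
[0, 0.036] blue; upper-inclusive, and cosmetic below the 10% filter —
the 0.036 cut is a plain configurable default). Arrows run predictor →
target, red/blue for indication/contraindication, magenta for infinite
and black for zero ratios; thickness is proportional to the pair's
display weight (the larger qualifying OR, or reciprocal for
contraindications), with infinite-OR edges drawn at the 99th percentile
of finite weights so they are distinguished by colour, not width.
Layout is a seeded force-directed placement attracting only along
substantial edges with weight |ln OR| (capped at ln 1000); any subset of
positions can be pinned, and layouts round-trip through a coordinate CSV
so subset analyses can share an arrangement. Vector output is
byte-stable for fixed inputs (fixed SVG hash salt, stripped timestamps).

## Numerical choices and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `prevalence_min` | 0.10 | species filter, proportion of surveys |
| `or_upper` / `or_lower` | 3, 1/3 | substantial-association thresholds (strict) |
| `alpha` | 0.05 | significance level, Wald two-sided |
| `multiplicity` | α/n species | conservative Bonferroni flag |
| `ci_level` | 0.95 | odds-ratio interval coverage |
| GLMM `tol` | 1e-8 | objective convergence tolerance |
| log σ floor | −10 | variance boundary (σ ≈ 4.5e-5 treated as 0) |
| AGQ nodes | 21 | oracle likelihood evaluation |
| layout weight cap | ln 1000 | infinite-OR attraction cap |

Degenerate inputs: constant species yield flagged `degenerate`
estimates (never abort a batch); ties at classification thresholds are
excluded by the strict inequalities; the 0·∞ symmetric-ratio form and
ubiquitous/absent targets raise explicit undefined-ratio errors.

Problem sizes in the test and acceptance runs — 1,000 fuzzed tables for
the model/closed-form equivalence, exhaustive tables to total 26–30 for
the structural theorems, 120–200 null replicates at 38 species × 795
surveys, 400 replicates for mixed-model interval coverage at 200 sites
× 4 surveys, 10,000 bootstrap draws — were chosen so each Monte-Carlo
check has comfortable resolution for its acceptance band.

## Known limitations

- Associations are marginal co-occurrence patterns; nothing here infers
  causality or separates shared habitat response from interaction.
- Detection error is not modelled (presence means "recorded present").
- The GLMM uses a Laplace approximation; for very small sites-by-
  replication designs adaptive quadrature would be more accurate (it is
  implemented, but only as an oracle evaluation, not a fitting route).
- The "compartment" structure visible in association diagrams is left
  to visual inspection; no clustering algorithm is applied.
- Joint multivariate models of all species simultaneously (MCMC
  multivariate probit/logit) are out of scope; each pair is fitted
  independently.
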