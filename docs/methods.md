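# Methods

## Model

`mmiprobit` fits a cumulative probit mixed model to long-format MMI score
tables. Each observed score Y ∈ {lo, …, hi} (default 3–15, the sum of
three 5-point rubric domains) is treated as the discretisation of a
latent Gaussian variable whose mean is the sum of four crossed random
effects — candidate ability S_i, interviewer severity T_j, station
difficulty U_k, day effect V_t — plus a standard-normal residual. The
random effects are independent, zero-mean Gaussians with free variances
σ²_S, σ²_T, σ²_U, σ²_V; the residual variance is fixed at 1, the usual
probit identification.

**Intercept.** A grand mean μ together with a full set of free thresholds
is not identifiable, so μ is fixed at 0 and absorbed into the thresholds:
reported thresholds are α_h − μ. This matches standard cumulative-link
practice; it changes nothing observable.

**Why ordinal rather than linear.** Scores are bounded and discrete with
visibly non-Gaussian margins; the threshold model uses the ordering
without pretending the 13 categories are equally spaced, and the latent
SD gives all effects a common, cohort-independent scale.

## Estimation

The marginal likelihood integrates over the full crossed random-effect
vector b (one coordinate per level of each factor; ~450 coordinates for a
full cohort). Quadrature is infeasible for crossed designs, so the
package uses a Laplace approximation:

1. **Inner problem.** For fixed thresholds and variances, the joint
   log-density is strictly concave in b (log-concavity of the Gaussian
   interval probabilities). Its maximiser b̂ is found by a damped Newton
   iteration with a dense Cholesky factorisation of the negative Hessian
   H = Z'WZ + D⁻¹ (Z the incidence matrix, W the per-observation
   curvatures, D the prior variances). Tolerance: gradient ∞-norm below
   `inner_tol` × max(1, |f|), default inner_tol 1e−9; the relative factor
   acknowledges that the attainable accuracy at double precision scales
   with the objective's magnitude. If floating-point rounding halts
   progress before the tolerance, the iteration stops there and an error
   is raised only if the residual gradient is material (> 1e−3 relative),
   which distinguishes float saturation from true non-convergence.

2. **Laplace objective.** log∫exp f db ≈ f(b̂) + (d/2)log 2π − ½ log|H|.

3. **Outer problem.** Thresholds are parameterised as a free first
   cut-point plus log-increments (strict monotonicity by construction at
   every iterate); variances as log-σ with a floor of 1e−6. L-BFGS-B
   maximises the Laplace objective with **analytic gradients**: the
   direct terms, the log-determinant terms, and the dependence of b̂ on
   the parameters (implicit function theorem; third derivatives of the
   link enter through the trace terms). The gradient implementation is
   verified against central finite differences in the test suite.

**Convergence criterion.** The fit is declared converged when the
projected gradient ∞-norm on the working scale falls below
max(1e−5, 1e−7 × |loglik|). A fixed absolute 1e−5 is unattainable at
double precision once |loglik| reaches a few thousand (the attainable
norm scales like √(ε·|f|·curvature)); the relative term keeps the
criterion honest across problem sizes while remaining far tighter than
the statistical precision of any component.

**Boundary handling.** A fitted σ below 1e−3 is reported as variance 0
with a boundary flag and its predicted effects set to exactly 0. Under
pure-noise data this typically triggers for several factors.

**Starting values.** Thresholds from Φ⁻¹ of the pooled empirical
cumulative score distribution (tied cut-points from unobserved categories
are separated by a minimum 0.05 gap); log-σ starts at log 0.3 for every
factor. Deterministic, so refits reproduce bit-for-bit. Bootstrap
replicate fits warm-start from the base fit.

**Approximation quality.** On tiny instances (≤ 4 random-effect levels,
≤ 12 observations) where dense tensor-grid Gauss–Hermite quadrature is
exact for practical purposes, the Laplace log-likelihood agrees within
0.05 and the inner mode matches the independently optimised posterior
mode to better than 1e−4 (verified in the test suite). Like all Laplace fits with
few observations per level, variance components for factors with few
levels (9 stations, 7 days) are biased toward zero; candidate and
interviewer components are recovered within a few percent at cohort
scale.

## Variance partition and reliability

Total latent variance is 1 + Σσ²; each factor's share is 100·σ²/total.
Shares are kept at full precision and rounded to 2 dp only in reports.
Cronbach's alpha between stations uses the candidates × stations pivot on
complete cases, α = k/(k−1)·(1 − Σ var_item / var_total) with sample
variances (ddof 1); fewer than two stations, fewer than two complete
profiles, or zero total-score variance are explicit errors.

## Bootstrap

The exchangeable unit of an MMI cohort is the candidate, so the bootstrap
resamples n_candidates whole candidate score-blocks with replacement;
each drawn block keeps its interviewer/station/day labels and receives a
fresh candidate ID so repeated draws stay distinct blocks. Per replicate
the model is refitted and the variances, total, and percentage shares
recorded; summaries are medians and 2.5/97.5 empirical percentiles by
linear interpolation of order statistics (numpy's "linear" rule).
**Percentages are summarised per replicate** — the median share is not
the share of the median variances, and the two conventions genuinely
differ; the per-replicate convention propagates the joint uncertainty of
all components into each share. One master seed spawns a per-replicate
seed stream, so increasing B leaves earlier replicates unchanged.
Non-converged replicates are dropped and counted; more than 20% failures
aborts. Default B = 1000; examples and tests use 50–200 for desk-scale
runtime. Levels absent from a resample are simply absent from that
replicate's fit.

## Ranking, offers, feedback

Candidates are ranked by predicted ability S_i (posterior mode)
descending, ties broken by raw total then ID; a raw-total ranking is kept
alongside because the offer process first ranks by total to set a cut,
then re-ranks by ability. Offers go to the top n by ability; candidates
inside the top n by total but outside it by ability are waitlisted — the
minimal algorithmic form of a process that is narrative in practice.
A standardised ability (S_i divided by the total latent SD √(1 + Σσ̂²))
is emitted alongside the raw latent-scale value, making cohorts with
different overall spread comparable; the raw value remains primary.
Interviewer feedback reports T_j, its percentile among interviewers
(mean-rank convention), score histograms, and a narrative band with
symmetric cut-offs at ±0.5 and ±1.0 latent SD (presentation defaults,
configurable). Stations with |U_k| ≥ 1 latent SD (configurable) are
flagged easy/hard. Effect histograms are exported as binned counts (bin
width 0.25) rather than images.

## Synthetic cohorts

The generator mirrors a real interview season: candidates are split
near-evenly across day × circuit cells; each circuit-day staffs one
interviewer per station; interviewers keep a home station across days
(mirroring how interviewer backgrounds are matched to station content)
and rotate deterministically through their station's circuit-day slots,
so every interviewer in the pool is used. Effects are drawn from their
Gaussian laws, latent values formed and discretised through the
thresholds; the truth (effects and latent draws) is retained.

The **cohort-scale preset** is 352 candidates, 83 interviewers, 9
stations, 7 days × 2 circuits, with true variances
(0.361, 0.1692, 0.035, 0.003) — magnitudes representative of a real
admissions cycle. Thresholds default to "auto": given a target marginal
score distribution, the cut-point at cumulative probability c is
μ + √(1 + Σσ²)·Φ⁻¹(c), so the implied marginal matches the target. The
default target is a mildly left-skewed distribution with mode near 11 —
a realistic shape for rubric totals where most candidates sit above the
scale midpoint; real marginals are not published, so this is a
presentation choice.

What the generator does **not** emulate: sequential "contrast" effects
between consecutive candidates, interviewer drift within a day,
interviewer × candidate interactions, covariates, and missing data.
Passing recovery tests therefore shows the estimator works when the
model's independence assumptions hold, not that real cohorts satisfy
them.

## Study sizes used in tests

The end-to-end suite uses: 25 random tiny instances for the quadrature
oracle; 20 cohort-scale seeds for parameter recovery; 20 repetitions ×
B = 200 on a reduced cohort (100 candidates, 30 interviewers, 3 days × 2
circuits) for bootstrap coverage; and 20 seeds of a 96-candidate, 36-
interviewer, 4 day × 2 circuit design with interviewer SD 1.0 for the
ranking comparison — chosen so each study answers its question at
desk-scale runtime. For the ranking study the interviewer pool must be
genuinely crossed with candidates (interviewers recurring across several
circuit-days): when every cell has its own fixed staff, severity shifts
whole cells uniformly and is absorbed indistinguishably from day effects,
and neither ranking can beat the other.

## Known limitations

- Laplace variance estimates for few-level factors (stations, days) are
  noticeably biased toward zero; bootstrap medians are the more robust
  headline numbers.
- No covariates (candidate background, interviewer role) and no
  interviewer × candidate interaction; all such structure is absorbed
  into the random effects.
- Per-domain sub-scores are not modelled; the station total is the unit
  of analysis.
- The probit scale means components are not directly comparable to
  variance shares from multifaceted Rasch or G-theory analyses.
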