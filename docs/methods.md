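# Methods

## The measurement model

A study consists of k dichotomous moral items; each item's two answers are
*opinions* (issue positions), so the study defines 2k opinions. A respondent
who answers an item judges **both** of its opinions: they tick, from one
randomly drawn argument wording per moral concern, which concerns justify
their own answer, and then which would justify the opposite answer. The unit
of analysis is the *judgment*: (participant, opinion, concern, applies?,
perspective ∈ {own, other}). One response therefore expands to exactly
2 × (number of concerns) judgments.

The **applicability score** of concern c for opinion o in a population is the
proportion of that population's respondents to the item who ticked c as
applying to o. Both perspectives count: the denominator is every respondent
to the item, because the score is defined over individuals, not over
supporters. Scores are kept as exact integer ratios (ticks/judgments) until
export, so pooling identities hold exactly: the pooled score equals the
judgment-count-weighted average of subgroup scores, in rational arithmetic.
A perspective filter (own-only / other-only) exists for the opinion-based
analysis below. The catch-all "some other reason" tick is stored for
completeness but never scored.

## Agreement: concordance, not correlation

Two populations' score vectors are aligned on their pairwise-complete cells
and compared with Lin's concordance correlation coefficient

    CCC = 2 s12 / (s1^2 + s2^2 + (m1 - m2)^2),

using means and biased (1/n) moment estimators, per Lin's original
definition; at the cell counts involved here (hundreds of pairs) the 1/n vs
1/(n−1) choice is numerically immaterial. The CCC measures agreement with
the identity line y = x: a perfectly linear but shrunken or shifted
relationship lowers it, while |CCC| ≤ |Pearson r| ≤ 1 always. Degenerate
conventions: two equal constant vectors give 1, two unequal constant vectors
give 0 (zero covariance over a positive denominator).

The primary confidence interval is the asymptotic one: atanh(CCC) with Lin's
variance formula, a normal interval on the z scale, mapped back through tanh
(always inside [−1, 1]; degenerate at |CCC| = 1). A participant-level
percentile bootstrap is provided as an optional alternative; note that
resampling respondents adds multiplicity noise to every cell, which biases
the bootstrap CCC downward when items have few raters — one reason the
asymptotic interval is the default.

Diagnostics mirror the standard plots for this design: the OLS line of the
second population's scores on the first (slope < 1 indicates the second
population distinguishes less between opinions), per-concern variance ratios
(biased variances, var₂/var₁), and per-concern boxplot summaries (quartiles
by linear interpolation; whiskers to the most extreme values within 1.5 IQR
of the box; outliers between 1.5 and 3 IQR beyond a box edge, extreme
outliers beyond 3 IQR).

## The random-split null

The null hypothesis is perfect *population-level* agreement. Finite samples
never agree perfectly — each cell's score carries binomial error — so the
observed CCC is compared not with 1 but with its distribution under the
null: pool the two samples, repeatedly (default B = 1,000) split the pooled
*participants* (all their judgments moving together, since demographics
attach to persons) uniformly at random into subsamples of the original
sizes, and recompute the CCC between the two halves over pairwise-complete
cells. The mean split CCC is the expected CCC under perfect true agreement;
the p-value is the plain proportion r/B of split CCCs strictly below the
observed CCC (ties count as not lower; a conservative (r+1)/(B+1) variant is
available by flag, default off). Replicates whose paired set is empty are
discarded and logged; if more than 1% are, the run aborts with a diagnostic.
Splitting is implemented with sparse participant × cell tick/count matrices,
so each replicate is two sparse mat-vecs; results are identical to naive
recomputation.

For **opinion-based** comparisons the sample is split separately within each
item, because opinion groupings are not aligned across items. Observed
statistic: for each opinion P, score vector 1 is P's holders' own-side
judgments of P and score vector 2 is the opposite holders' other-side
judgments of P; opinions where either side has fewer than `min_holders`
holders (default 5, always logged — the exclusion rule is a deliberate,
visible knob) are dropped. The stratified null reshuffles each item's
respondents into pseudo-sides of the original holder sizes and rebuilds the
same supporter/opponent pairing from the pseudo-sides' judgments; under the
null (no perspective effect) the two are exchangeable. Items with fewer
than 2 respondents on a side are dropped with a log entry. Cross-population
comparisons default to the unstratified participant split, with the
stratified variant available.

## The synthetic survey generator

The generator exists so every stage is testable with known ground truth; its
defaults emulate the study designs the package targets.

- **Latent truth.** Each (opinion, concern) cell has a latent probability θ
  drawn from `theta_prior`, default Beta(0.8, 1.6): right-skewed, most mass
  below 0.5 with a tail of highly applicable cells, qualitatively matching
  observed applicability-score distributions. Optional per-concern log-odds
  offsets shift whole concerns (e.g. to make fairness and liberty the most
  broadly applicable). Per-item affirmative-answer prevalence is drawn from
  `opinion_prevalence`, default Beta(2, 2) (issues are typically contested,
  rarely lopsided).
- **Group discrepancy τ.** Group g's truth is logit(θ) + N(0, τ_g) per cell
  (θ clamped to [10⁻⁶, 1−10⁻⁶] first). The log-odds scale keeps θ in (0, 1)
  and is symmetric around the base score; τ = 0 returns the base unchanged
  — the perfect-agreement null.
- **Perspective discrepancy κ.** Judging a position from the other side uses
  logit(θ) + δ with δ ~ N(0, κ) drawn **once per cell** and shared by all
  respondents (and groups). A per-respondent draw would average out at the
  population level and could not produce systematically lower
  supporter-vs-opponent agreement; a shared per-cell offset does, which is
  exactly the pattern the opinion-split analysis is designed to detect.
  κ = 0 (the default) makes other-side judgments exchangeable with own-side
  ones.
- **Distinctiveness compression.** A group can be given `compression`
  λ ∈ [0, 1]: its tick probabilities are shrunk toward the grand mean,
  θ_g ← mean + λ(θ_g − mean), emulating a population that distinguishes
  less between opinions (regression slope < 1, all variance ratios < 1).
- **Design.** Every participant answers a fixed number of items (default 19)
  sampled uniformly without replacement; the average-count-only information
  available about real designs does not pin down the dispersion, so a fixed
  count is an explicit simplification. One argument wording per concern is
  drawn uniformly per judgment; optional per-wording log-odds effects
  (`within_concern_argument_sd`, default 0) let tests probe sensitivity to
  wording. Catch-all ticks fire at a nuisance rate (default 0.05). Default
  demographics are simple independent draws (sex and binary ideology and
  education 50/50, age ≈ N(39, 12²) clipped to 18–88, 11-point ideology
  uniform, verbal ability Binomial(10, 0.65)); all are overridable per
  group.
- **Presets.** `us_like` (98 items, 568 participants, 19 items each → ~110
  raters/item), `uk_like` (108 items, 903 participants, 12 each → ~100),
  `shared27` (27 items, 300 participants per country, 9 each → ~100).
- **Determinism.** All randomness flows from one seed through fixed-role
  child streams (truth, prevalence, perspective offsets, wording offsets,
  one per group), so identical configs give byte-identical output files and
  the latent truth is invariant to changes in group sizes — which is what
  lets paired simulation arms share a θ.

What the generator does **not** emulate: item content and real covariance
between demographics and ticking behavior (simulated demographics are
independent of θ, so demographic splits are true null comparisons unless τ
or compression is set); participant drop-out and varying item counts;
order/fatigue effects; wording-by-respondent interactions. Passing tests
therefore validate the estimator and inference machinery under the stated
design, not the substantive claim that real populations agree.

## Numerical and design choices

- Split sizes, counts and scores are validated at construction; scores
  remain exact fractions inside ScoreTable and become floats only in paired
  vectors and exports (6 decimals in score files).
- Paired cells are ordered lexicographically by (item_id, position,
  concern) so every export is deterministic and regression-testable.
- Demographic split rules: sex, binary ideology and education use their
  categorical labels; age splits at the sample median with median-valued
  respondents assigned to the younger side (deterministic in the absence of
  a principled threshold); the 11-point ideology scale splits left 0–3 vs
  right 7–10 with the middle excluded; verbal ability splits at ≥ 8 vs ≤ 7;
  country and population-label splits take an explicit pair. A side with
  fewer than 2 participants is an error; participants missing the attribute
  are excluded and counts are logged.
- Test problem sizes: the calibration and power studies in the test suite
  use 27 items, 2 × 60 participants, 11 items per participant (~50 raters
  per item) and B = 200 splits, with 200 (calibration) and 50 (power, per
  τ) replicate studies — large enough for the binomial bands asserted, small
  enough that the whole suite runs in about a minute on one CPU.

## Known limitations

- The asymptotic CCC interval relies on approximate normality of score
  residuals; scores are proportions and the interval can be slightly
  anticonservative at extreme CCCs with few pairs. The bootstrap alternative
  is biased low at small raters-per-item (see above). Neither interval is
  claimed to reproduce any particular published interval.
- The expected CCC is defined only by simulation; no analytic approximation
  is provided.
- The p-value r/B can be exactly 0; consumers who need strictly positive
  p-values should use the conservative variant.
- Opinion splits drop whole items when one side is rare; with very skewed
  prevalences and small samples the retained set can shrink substantially
  (always reported).
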