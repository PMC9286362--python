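# Methods

`aglearn` implements the analysis pipeline of a visual artificial-grammar-
learning (AGL) experiment in which participants judge whether tile sequences
follow the schema they were exposed to. Three target grammars sit at
ascending levels of the extended Chomsky hierarchy, and the statistical
machinery asks whether yes/no judgments reflect induction of the *target*
grammar rather than a simpler shortcut rule.

## Grammars and stimuli

All grammars operate on category labels `A`/`B`; concrete tile exemplars are
decorative metadata and never affect membership.

| id | level | language (categories) | markers |
|----|-------|----------------------|---------|
| `WARMUP_ABN` | regular | `(AB)^N` | none |
| `ABNA` | regular | `A B^N A` | two, around the B run |
| `MIRROR` | context-free | `w · reverse(w)`, `w ∈ {A,B}^N` | one, central |
| `COPY` | mildly context-sensitive | `w · w` | one, central |

Markers (`|` in the text dialect, black tiles on screen) are structural
separators: they never count toward the dependency length N, and membership
requires them in exactly the grammar-determined positions (a configuration
flag relaxes this). A foil with displaced structure is therefore
*ungrammatical*, not an error.

The membership decision, the string generator, and a brute-force language
enumerator are implemented as three independent routes and tested for
exhaustive agreement for all N ≤ 6. The enumerator doubles as the oracle for
stimulus-set validation. A known ambiguity is intrinsic to the design:
a Copy string whose half is palindromic is also a Mirror string (the overlap
fraction at length N is exactly 2^⌈N/2⌉ / 2^N). Test-set sampling therefore
excludes palindromic halves by default (configurable), while exposure sets
allow all halves.

**Test design.** Only block totals are published for the 87-item test block:
grammatical + incomplete-dependency foils total 30 at N ∈ {2,3}, 20 at
N = 4, 12 at N = 6; incorrect-tile foils total 15 at N ∈ {2,3} and 10 at
N = 4. The per-N split inside each block is this package's choice
(grammatical 8/8/12/8, incomplete 7/7/8/4, incorrect-tile 8/7/10), is
validated against the block totals, and is fully configurable. Exposure
blocks hold 30 grammatical strings at N ∈ {2,3,5} (10 each); the warm-up
block holds 15 items (8 grammatical / 7 foils) under `(AB)^N` with the
12-of-15 exact-binomial pass criterion. Foils derive from grammatical seeds:
*incomplete dependency* deletes one dependency-bearing token (a terminal A
for `ABNA`, a second-half token for `MIRROR`/`COPY`); *incorrect tile* flips
exactly one token's category, preserving length. For these grammars no
single flip can stay grammatical, which the suite asserts exhaustively.

## Synthetic participants

The generator emulates the statistical structure the analysis assumes, not
human cognition. Each simulated participant applies one candidate rule
(target grammar or shortcut) with consistency probability

    P(consistent) = lapse/2 + (1 − lapse) · σ(base_logit + u_i),
    u_i ~ Normal(0, individual_sd),

answering "yes" iff consistency and the rule's verdict agree. Defaults:
`individual_sd = 0.5` (between-participant variance 0.25 on the log-odds
scale, the value used in the power simulation), `lapse = 0`, and operating
points around σ⁻¹(.87)–σ⁻¹(.97), the range of group-level consistency the
task typically yields. A full study is 2 groups × 15 participants × 3
grammar conditions × 87 test trials = 7830 rows, with offsets drawn once per
participant and carried across conditions.

What the generator does **not** emulate: learning dynamics within or across
phases, reaction times, item-level difficulty beyond rule agreement, lapses
correlated with sequence length, or strategy mixtures within a participant.
Passing tests therefore certify the *pipeline* (coding, estimation,
calibration at the design's scale), not claims about human data.

## Consistency coding

Each trial is coded 1 for a rule iff the response matches the rule's verdict
on the stimulus; consistency with the condition's target grammar is
identically ordinary accuracy. The default shortcut registry is `ENDS_A`,
`BEGINS_A`, `EDGE_MATCH`, `HALF_COUNT_MATCH`, `MARKER_OK`, `LEGAL_LENGTH`,
and `BIGRAM_FAMILIAR` (all adjacent category pairs seen in exposure). This
registry is a configurable stand-in for the study's supplementary list,
which is not printed in the main text. Stimulus annotations mark
*generalization* (N ≥ 4, lengths unseen in exposure) and *similarity*
(identified with grammaticality of the stimulus). Warm-up trials are
excluded from all models.

## Frequentist layer

* Exact binomial tails are computed by direct summation
  (`scipy.stats.binom.sf`); individual criteria are the smallest k with
  upper tail ≤ .05 at chance .5, derived per block size rather than
  hard-coded — reproducing 20/30, 15/20, 10/12, 12/15, 9/10.
  Reported p-values are one-tailed (success above chance), which is the
  convention that matches all published criterion values; a two-tailed
  option exists.
* Wilcoxon signed-rank: two-sided, exact null distribution for n ≤ 25, zero
  differences dropped. The reported W is the positive-difference rank sum,
  so 15 uniformly positive differences give W = 120 with p = 2·2⁻¹⁵.
* Paired Cohen's d is computed on difference scores (mean/SD of
  differences); error-free contrasts yield a signed infinity rather than an
  exception.
* d′ = Φ⁻¹(hit) − Φ⁻¹(false alarm) with the 1/(2n) clamp for extreme rates.
  Group d′ is reported both from pooled group rates and as the mean of
  participant-level d′ — published group values are compatible with either
  aggregation, so neither is privileged.

## Bayesian multilevel models

The core model is a random-intercept logistic regression for
rule-consistent responding, with weakly regularizing priors: Normal(0, 2)
on fixed effects, Half-Cauchy(0, 2) on random-effect SDs, LKJ(2) on
correlation matrices. Posteriors are summarized as median, MAD, equal-tailed
90% credible interval, and pp+ (posterior probability above the quantity's
null — .5 for probabilities, 0 for coefficients and LogOR; ties count half).
Directional claims require the 90% CI to exclude the null (pp+ ≥ .95).

**Computation.** Because covariates are constant within participant (or
participant × rule / participant × stimulus cell), Bernoulli likelihoods are
aggregated to binomial counts. The participant effects are then integrated
out of the sampled posterior by Gauss–Hermite quadrature (31 nodes in one
dimension; 15²/7³ grids for the two- and three-dimensional correlated-effect
models), leaving a hyperparameter posterior of 3–14 dimensions that an
affine-invariant ensemble sampler (differential-evolution moves, emcee)
explores efficiently. Participant intercepts are afterwards reconstructed
exactly by inverse-CDF sampling from their conditional posterior given each
hyperparameter draw, on a 121-point grid spanning ±5 prior SDs. Default
budget: ≥ 24 walkers × 1000 burn-in + 1000 retained steps, thinned to
several thousand draws. Split-chain R-hat (walkers as chains) and effective
sample size are attached to every fit; R-hat above 1.01 raises a warning
rather than an exception because walker chains of an interacting ensemble
overestimate the statistic slightly. Degenerate inputs (a constant outcome
column) yield a warning and a prior-regularized, finite posterior.

**LogOR contrasts.** Target-versus-shortcut comparisons are log odds ratios
of consistency for the average participant of each group. The default model
is a *joint* fit with rule as a within-trial factor and correlated
participant intercept + rule slope (2×2 LKJ(2) correlation); a cheaper mode
differences two independent single-rule posteriors, which ignores the
within-participant correlation and is slightly conservative. A contrast of a
rule against itself is detected and returned as exactly zero with a warning.

**Stimulus-property model.** Group × similarity × generalization effects are
estimated from the full set of latent cell means (Normal(0, 2) each) with
correlated participant intercepts and slopes for both properties
(Half-Cauchy(0, 2) SDs, 3×3 LKJ(2) correlation; pairwise correlations are
tanh-parameterized with positive-definiteness enforced by rejection).
Simple effects and interactions are computed as cell-mean contrasts;
standardized effects use the latent-scale Cohen's d = Δ / √(σ²ᵤ + π²/3),
where π²/3 is the residual variance of the logistic distribution.

## Power analysis

Datasets are generated under the model itself: two groups of 15
participants × 87 Bernoulli trials, intercept variance σ² = 0.25, and a
group difference of Cohen's d = 0.3 mapped to the latent scale as
β = d·√(σ² + π²/3) ≈ 0.564 (an alternative mapping against the
between-participant SD alone is available). The reference group's mean
consistency defaults to 0.8, a typical observed operating point; this value
is not published. Power is the share of 200 datasets whose fitted 90%
interval for the group coefficient excludes zero.

Two backends implement the decision: a fast penalized-likelihood
Gauss–Hermite mixed-logit fit with Wald intervals (the penalty mirrors the
Bayesian priors so separated datasets remain finite; validated against
`lme4::glmer` to two decimals), and the full Bayesian model. Per-replicate
sub-seeds are drawn up front so both backends see identical datasets
(common random numbers); the suite checks they agree on ≥ 90% of decisions.
Measured power at the default configuration is ≈ 0.83 (fast mode, 200
datasets), with Monte-Carlo uncertainty ≈ ±0.05.

## Problem sizes and numerical choices

Test-suite simulations run at the study's actual scale (15 per group, 87
trials) with shortened sampler budgets for replicate loops (16 walkers,
400–600 steps, 21 quadrature nodes) — adequate for 3–7-parameter marginal
posteriors, as the recovery and calibration tests confirm. Parameter
recovery uses 100 replicates; backend agreement uses 12; the power analysis
always uses its full 200 datasets. Ties in pp+ count one half; equal-tailed
intervals use direct quantiles; optimizer starts use empirical logits with
a +0.5 continuity correction.

## Known limitations

* The shortcut-rule registry approximates, but cannot claim to match, the
  original study's supplementary list.
* The per-N stimulus splits inside published block totals are constrained
  stand-ins for the original materials.
* Published posterior quantities from the human data (e.g. group
  probabilities .97/.87, empirical LogOR ranges) are not reproducible
  without that data; the pipeline targets them only as synthetic operating
  points.
* Ensemble-sampler R-hat on walker chains is an approximate diagnostic; for
  publication-grade inference on new data, increase the sampler budget
  until the gate passes strictly.
* The warm-up inclusion criterion is implemented but no participant
  exclusion flow is modelled (synthetic cohorts pass by construction).
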