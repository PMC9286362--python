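# aglearn

A reusable, tested pipeline for **visual artificial-grammar-learning (AGL)**
experiments that probe rule learning at several levels of the formal
language hierarchy. It is aimed at cognitive scientists who run (or
simulate) yes/no grammaticality-judgment studies and want the full analysis
chain — stimulus construction, response coding, frequentist summaries,
hierarchical Bayesian inference, and power analysis — as reproducible code.

## The problem and the models

Participants are exposed to strings of `A`/`B` category tiles generated by a
target grammar and then judge novel strings. Targets span three formal
levels: `A Bᴺ A` (regular, one long-distance dependency), the **Mirror**
grammar `w·reverse(w)` (context-free, nested dependencies), and the **Copy**
grammar `w·w` (mildly context-sensitive, crossed dependencies). Above-chance
accuracy alone cannot show induction of the target rule, because simpler
shortcuts (e.g. *"accept strings ending in A"*) agree with the target on
many stimuli. The pipeline therefore codes every trial for consistency with
the target **and** a registry of shortcut rules and fits hierarchical
Bayesian logistic models

&nbsp;&nbsp;&nbsp;&nbsp;yᵢₜ ~ Bernoulli(σ(α + β·groupᵢ + uᵢ)),&nbsp;&nbsp;uᵢ ~ Normal(0, σᵤ),

with priors Normal(0,2) on fixed effects, Half-Cauchy(0,2) on random-effect
SDs, and LKJ(2) on correlations. Rule comparisons are posterior **log odds
ratios** (LogOR > 0 favours the target grammar), reported as median, MAD,
equal-tailed 90% CI and pp+ (posterior probability of exceeding the null).
A frequentist layer provides yes-rate summaries, exact Wilcoxon signed-rank
tests, paired Cohen's d, signal-detection d′, and exact-binomial individual
success criteria (20/30, 15/20, 10/12, 12/15, 9/10). A simulation-based
power analysis reproduces the design's sensitivity for a small latent-scale
group difference (Cohen's d = 0.3). Human data collection is replaced by a
synthetic-participant generator with the statistical structure the models
assume. See `docs/methods.md` for the full account.

## Worked example

Simulate a two-group study on the regular grammar, code it, and ask whether
the "average participant" of each group responds consistently with the
target — and whether the target beats the ends-with-A shortcut:

```python
import aglearn as ag
from aglearn.coding import build_consistency_table
from aglearn.bayes import (fit_consistency_model, group_probability_draws,
                           grammar_logodds_contrast, summarize)

profiles = {
    "deaf": ag.StrategyProfile(base_logit=1.9, individual_sd=0.5),
    "hearing": ag.StrategyProfile(base_logit=2.4, individual_sd=0.5),
}
study = ag.simulate_study(profiles, grammars=("ABNA",), seed=42)
table = build_consistency_table(study.trials)

fit = fit_consistency_model(table, "ABNA")
for grp, draws in group_probability_draws(fit).items():
    s = summarize(draws, null=0.5)
    print(f"{grp:8s} p = {s.median:.2f} [MAD {s.mad:.2f}], "
          f"90% CI [{s.ci90[0]:.2f}, {s.ci90[1]:.2f}], pp+ = {s.pp_positive:.2f}")

con = grammar_logodds_contrast(table, "ABNA", "ENDS_A")
for grp, s in con.by_group.items():
    print(f"LogOR(ABNA vs ENDS_A), {grp}: {s.median:.2f}, "
          f"90% CI [{s.ci90[0]:.2f}, {s.ci90[1]:.2f}], pp+ = {s.pp_positive:.2f}")
```

Output:

```
deaf     p = 0.85 [MAD 0.01], 90% CI [0.82, 0.88], pp+ = 1.00
hearing  p = 0.92 [MAD 0.01], 90% CI [0.90, 0.94], pp+ = 1.00
LogOR(ABNA vs ENDS_A), deaf: 1.39, 90% CI [1.18, 1.61], pp+ = 1.00
LogOR(ABNA vs ENDS_A), hearing: 2.02, 90% CI [1.80, 2.24], pp+ = 1.00
```

The group probabilities recover the generating operating points
(σ(1.9) ≈ .87, σ(2.4) ≈ .92) up to offset-sampling noise, pp+ = 1.00 marks
both groups clearly above chance, and the positive LogOR with pp+ ≥ .95
correctly attributes behaviour to the target grammar rather than the
shortcut.

The same pipeline is scriptable from the shell:

```sh
aglearn generate --seed 1 --outdir out/stimuli     # 3×(30+87)+15 stimulus rows
aglearn simulate --seed 1 --outdir out/study       # 7830-trial synthetic study
aglearn code     --trials out/study/trials.csv     # consistency table
aglearn analyze  --trials out/study/trials.csv     # descriptive + posterior tables
aglearn power    --seed 1 --mode fast              # power ≈ 0.83 at the default design
```

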