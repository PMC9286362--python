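"""Frequentist layer: yes-rate summaries, signed-rank tests, effect sizes,
signal-detection sensitivity, and exact-binomial individual criteria.

Individual above-chance performance is judged per stimulus block against the
smallest success count whose upper binomial tail at chance (p0 = .5) drops
to or below alpha = .05: 20/30 for grammatical + incomplete-foil trials at
N in {2,3}, 15/20 at N = 4, 10/12 at N = 6; 12/15 for incorrect-tile foils
at N in {2,3} and 9/10 at N = 4 (and 12/15 for the warm-up block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CriterionRule",
    "exact_binomial_tail",
    "minimal_criterion",
    "wilcoxon_signed_rank",
    "cohens_d_paired",
    "d_prime",
    "condition_summaries",
    "criterion_tables",
]


# ---------------------------------------------------------------------------
# exact binomial machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriterionRule:
    """Minimal above-chance success criterion for a block of ``n_trials``."""

    k_min: int
    n_trials: int
    alpha_reported: float  # upper-tail probability at k_min, rounded as printed
    tail_probability: float = float("nan")  # exact upper tail at k_min


def exact_binomial_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Upper-tail P(X >= k) under Binomial(n, p0), by exact summation."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, p0))


def minimal_criterion(n: int, alpha: float = 0.05, p0: float = 0.5) -> CriterionRule:
    """Smallest k with P(X >= k | n, p0) <= alpha."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for k in range(n + 1):
        tail = exact_binomial_tail(k, n, p0)
        if tail <= alpha:
            # report at two decimals unless that would round up to alpha itself
            printed = round(tail, 2)
            if printed >= alpha:
                printed = round(tail, 3)
            return CriterionRule(k, n, printed, tail)
    raise ValueError(f"no k in 0..{n} reaches alpha={alpha}")


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Returns ``(W, p)`` where W is the positive-difference rank sum (so 15
    uniformly positive differences give W = 120) and p is exact for n <= 25
    after zero differences are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return w_pos, float(res.pvalue)


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d on difference scores: mean(x-y) / sd(x-y)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    return float(d.mean() / sd)


def d_prime(hit_rate: float, fa_rate: float,
            n_signal: int | None = None, n_noise: int | None = None) -> float:
    """Signal-detection sensitivity Phi^-1(hit) - Phi^-1(fa).

    Extreme rates (0 or 1) are clamped to [1/(2n), 1 - 1/(2n)] when the
    relevant trial count is supplied.
    """
    def adjust(r: float, n: int | None) -> float:
        if n is not None:
            lo = 1.0 / (2 * n)
            return min(max(r, lo), 1 - lo)
        if r <= 0.0 or r >= 1.0:
            raise ValueError("extreme rate needs a trial count for the 1/(2n) correction")
        return r

    return float(stats.norm.ppf(adjust(hit_rate, n_signal))
                 - stats.norm.ppf(adjust(fa_rate, n_noise)))


# ---------------------------------------------------------------------------
# group-level summaries (yes-rates, W, d, d')
# ---------------------------------------------------------------------------

def condition_summaries(trials: pd.DataFrame,
                        n_values: tuple[int, ...] | None = None,
                        foil_types: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per group x grammar: %yes to grammatical vs ungrammatical strings,
    with signed-rank W/p, paired Cohen's d, and d' (pooled-rate and
    participant-mean variants).

    ``n_values`` / ``foil_types`` restrict the trial subset (e.g. N = 4
    generalization only, or incomplete-dependency foils only); grammatical
    trials are filtered by ``n_values`` only.
    """
    t = trials.copy()
    if n_values is not None:
        t = t[t["n_value"].isin(n_values)]
    if foil_types is not None:
        t = t[(t["grammatical"] == 1) | (t["foil_type"].isin(foil_types))]
    rows = []
    for (grp, gram), sub in t.groupby(["group", "grammar"], sort=True):
        per = sub.groupby(["participant_id", "grammatical"])["response_yes"].mean().unstack()
        yes_g = per.get(1)
        yes_u = per.get(0)
        if yes_g is None or yes_u is None or yes_g.isna().any() or yes_u.isna().any():
            raise ValueError("every participant needs grammatical and ungrammatical trials")
        W, p = wilcoxon_signed_rank(yes_g, yes_u)
        diff = np.asarray(yes_g, float) - np.asarray(yes_u, float)
        if diff.std(ddof=1) == 0:
            # degenerate (e.g. error-free responders): report a signed infinity
            d_val = float(np.sign(diff.mean()) * np.inf)
        else:
            d_val = cohens_d_paired(yes_g, yes_u)
        n_sig = int(sub[sub["grammatical"] == 1].groupby("participant_id").size().iloc[0])
        n_noi = int(sub[sub["grammatical"] == 0].groupby("participant_id").size().iloc[0])
        pooled = d_prime(float(yes_g.mean()), float(yes_u.mean()),
                         n_signal=len(yes_g) * n_sig, n_noise=len(yes_u) * n_noi)
        per_part = [d_prime(h, f, n_signal=n_sig, n_noise=n_noi)
                    for h, f in zip(yes_g, yes_u)]
        rows.append({
            "group": grp, "grammar": gram,
            "pct_yes_grammatical": 100 * float(yes_g.mean()),
            "sd_yes_grammatical": 100 * float(yes_g.std(ddof=1)),
            "pct_yes_ungrammatical": 100 * float(yes_u.mean()),
            "sd_yes_ungrammatical": 100 * float(yes_u.std(ddof=1)),
            "W": W, "p": p,
            "cohens_d": d_val,
            "d_prime_pooled": pooled,
            "d_prime_mean": float(np.mean(per_part)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual criterion tables
# ---------------------------------------------------------------------------

#: (label, N values, foil family filter) for the two published table shapes.
_BLOCKS_MAIN = [("N=2 and 3", (2, 3)), ("N=4", (4,)), ("N=6", (6,))]
_BLOCKS_TILE = [("N=2 and 3", (2, 3)), ("N=4", (4,))]


def criterion_tables(trials: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Counts and percentages of participants reaching the exact-binomial
    criterion, per group x grammar x N block.

    Table ``"main"`` covers grammatical strings plus incomplete-dependency
    foils; table ``"incorrect_tile"`` covers the incorrect-tile foils alone.
    The criterion for each block is derived from its trial count via
    :func:`minimal_criterion`, never hard-coded.
    """
    t = trials.copy()
    t["correct"] = (t["response_yes"] == t["grammatical"]).astype(int)
    out: dict[str, pd.DataFrame] = {}
    for name, blocks, keep in (
        ("main", _BLOCKS_MAIN,
         (t["grammatical"] == 1) | (t["foil_type"] == "incomplete_dependency")),
        ("incorrect_tile", _BLOCKS_TILE, t["foil_type"] == "incorrect_tile"),
    ):
        sub = t[keep]
        rows = []
        for label, ns in blocks:
            blk = sub[sub["n_value"].isin(ns)]
            for (grp, gram), cell in blk.groupby(["group", "grammar"], sort=True):
                per = cell.groupby("participant_id")["correct"].agg(["sum", "count"])
                n_trials = int(per["count"].iloc[0])
                if not (per["count"] == n_trials).all():
                    raise ValueError("unbalanced block trial counts across participants")
                rule = minimal_criterion(n_trials, alpha)
                reached = int((per["sum"] >= rule.k_min).sum())
                rows.append({
                    "block": label, "group": grp, "grammar": gram,
                    "n_trials": n_trials, "k_min": rule.k_min,
                    "criterion_p": rule.alpha_reported,
                    "n_participants": len(per),
                    "n_reached": reached,
                    "pct_reached": round(100 * reached / len(per)),
                })
        out[name] = pd.DataFrame(rows)
    return out
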