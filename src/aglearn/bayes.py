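"""Hierarchical Bayesian logistic models for grammar-consistent responding.

The behavioural quantity modelled is the probability that a participant's
yes/no response on a random trial is consistent with a candidate rule.  The
core model is a random-intercept logistic regression

    y_it ~ Bernoulli(sigmoid(alpha + beta * group_i + u_i)),
    u_i ~ Normal(0, sigma_u),

with weakly regularizing priors: Normal(0, 2) on fixed effects, Half-Cauchy
(0, 2) on random-effect SDs, and LKJ(2) on correlation matrices where a
model has multiple random effects.  Because all covariates are constant
within participant (or within participant x rule / participant x stimulus
cell), the Bernoulli likelihood is aggregated to binomial counts per cell,
which makes posterior evaluation cheap without changing the posterior.

Sampling uses an affine-invariant ensemble MCMC (differential-evolution
moves).  For the single-rule and rule-contrast models the participant
effects are marginalized out of the likelihood with Gauss-Hermite
quadrature, so the sampler explores only the low-dimensional hyperparameter
posterior; participant effects are then reconstructed exactly from their
conditional posterior given each hyperparameter draw.  Walker chains are
summarized with split-chain R-hat and effective sample size via ArviZ, and
a gate of R-hat < 1.01 is enforced as a warning.

Posterior quantities are reported the same way throughout: median, median
absolute deviation (MAD), equal-tailed 90% credible interval, and pp+ (the
posterior probability of exceeding the quantity's null value — 0.5 for
probabilities, 0 for coefficients and log odds ratios).

Target-versus-alternate rule comparisons are expressed as log odds ratios
(LogOR): LogOR = 0 means equal odds of responding consistently with target
and alternate rule; LogOR > 0 supports the target grammar.  The default
contrast model is a joint fit with rule as a within-trial factor and
correlated participant intercept + rule slope; a cheaper mode differences
the posteriors of two independent per-rule fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp as _logsumexp

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az
import emcee

__all__ = [
    "SamplerConfig",
    "ModelSpec",
    "PosteriorSummary",
    "LogORContrast",
    "ConsistencyFit",
    "summarize",
    "fit_consistency_model",
    "group_probability_draws",
    "latent_cohens_d",
    "individual_probabilities",
    "grammar_logodds_contrast",
    "fit_property_model",
]

_LOGISTIC_VAR = np.pi ** 2 / 3  # residual variance of the logistic latent scale


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-MCMC settings; defaults keep a single fit at desk scale."""

    n_walkers: int | None = None      # default: max(32, 2*ndim + 2)
    n_steps: int = 1000               # post burn-in steps per walker
    n_burn: int = 1000
    thin: int = 8
    seed: int = 0
    rhat_gate: float = 1.01
    gh_nodes: int = 31                # Gauss-Hermite nodes for marginal likelihoods


@dataclass(frozen=True)
class ModelSpec:
    """Priors for the multilevel logistic models (all overridable)."""

    fixed_sd: float = 2.0             # Normal(0, fixed_sd) on fixed effects
    re_scale: float = 2.0             # Half-Cauchy(0, re_scale) on RE SDs
    lkj_eta: float = 2.0              # LKJ(eta) on RE correlation matrices
    sampler: SamplerConfig = field(default_factory=SamplerConfig)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorSummary:
    median: float
    mad: float
    ci90: tuple[float, float]
    pp_positive: float

    def as_dict(self) -> dict:
        return {"median": self.median, "mad": self.mad,
                "ci90_low": self.ci90[0], "ci90_high": self.ci90[1],
                "pp_positive": self.pp_positive}


def summarize(draws, transform=None, null: float = 0.0) -> PosteriorSummary:
    """Median / MAD / equal-tailed 90% CI / pp+ for (a transform of) draws."""
    draws = np.asarray(draws, float).ravel()
    if draws.size < 1000:
        raise ValueError(f"need >= 1000 draws, got {draws.size}")
    if transform is not None:
        draws = transform(draws)
    med = float(np.median(draws))
    mad = float(np.median(np.abs(draws - med)))
    lo, hi = np.quantile(draws, [0.05, 0.95])
    pp = float(np.mean(draws > null) + 0.5 * np.mean(draws == null))
    return PosteriorSummary(med, mad, (float(lo), float(hi)), pp)


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _binom_loglik(eta, k, n):
    """Sum of binomial log-likelihood terms; eta broadcast over last axis."""
    return np.sum(k * -_softplus(-eta) + (n - k) * -_softplus(eta), axis=-1)


def _halfcauchy_logpdf(sigma, scale):
    return np.log(2.0 / (np.pi * scale)) - np.log1p((sigma / scale) ** 2)


def _run_sampler(log_prob, x0, cfg: SamplerConfig, param_names_for_gate=(0,)):
    """Run the ensemble sampler; return draws (n, ndim) and diagnostics."""
    ndim = x0.shape[0]
    nwalk = max(cfg.n_walkers or 24, 2 * ndim + 2)
    rng = np.random.default_rng(cfg.seed)
    # overdispersed start: the DE moves scale with ensemble spread, so a
    # near-degenerate start mixes slowly
    start = x0[None, :] + 0.4 * rng.standard_normal((nwalk, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalk, ndim, log_prob, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(cfg.seed)
    state = sampler.run_mcmc(start, cfg.n_burn, progress=False, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, cfg.n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(thin=cfg.thin)            # (steps, walkers, ndim)
    sub = chain[:, :, list(param_names_for_gate)]        # gate on key params
    # walkers as chains (transposed to chain-major) for split-chain R-hat
    idata = az.convert_to_dataset(np.moveaxis(sub, 1, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(idata).to_array().max())
        ess = float(az.ess(idata).to_array().min())
    if rhat > cfg.rhat_gate:
        warnings.warn(f"convergence gate failed: max R-hat {rhat:.3f} > {cfg.rhat_gate}",
                      RuntimeWarning)
    draws = chain.reshape(-1, ndim)
    return draws, {"rhat": rhat, "ess": ess, "n_draws": draws.shape[0],
                   "acceptance": float(np.mean(sampler.acceptance_fraction))}


def _empirical_logit(k, n):
    return float(np.log((k + 0.5) / (n - k + 0.5)))


# ---------------------------------------------------------------------------
# consistency model (single rule)
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyFit:
    """Posterior draws and bookkeeping for one rule-consistency model."""

    rule: str
    groups: list[str]                  # 1 or 2 group labels, sorted
    participants: list[str]
    group_of: np.ndarray               # participant -> group index
    alpha: np.ndarray                  # intercept draws (reference group)
    beta: np.ndarray | None            # group-difference draws (2-group fits)
    sigma_u: np.ndarray                # random-intercept SD draws
    u: np.ndarray | None               # (n_draws, P) participant offsets
    diagnostics: dict
    spec: ModelSpec


def _aggregate(table: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    agg = (table.groupby(["participant_id", "group"], sort=True)[outcome]
           .agg(["sum", "count"]).reset_index())
    groups = sorted(agg["group"].unique())
    g_idx = agg["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    return (agg["sum"].to_numpy(float), agg["count"].to_numpy(float),
            g_idx, list(agg["participant_id"]), groups)


def _gh(nodes: int):
    x, w = np.polynomial.hermite.hermgauss(nodes)
    # standard-normal quadrature: integral f(u) phi(u) du ~ sum lw * f(sqrt(2) x)
    return np.sqrt(2.0) * x, np.log(w) - 0.5 * np.log(np.pi)


def _conditional_u_draws(eta0, k, n, sigma, rng, grid_pts: int = 121):
    """Sample participant offsets u_i from p(u_i | theta, k_i) per draw.

    ``eta0``: (D, P) fixed-effect part of the linear predictor; ``sigma``:
    (D,) random-effect SD draws.  Exact inverse-CDF sampling on a fine grid
    of the standard-normal scale, one participant at a time.
    """
    D, P = eta0.shape
    xg = np.linspace(-5.0, 5.0, grid_pts)
    u_out = np.empty((D, P))
    for j in range(P):
        u = sigma[:, None] * xg[None, :]
        eta = eta0[:, j, None] + u
        logw = (k[j] * -_softplus(-eta) + (n[j] - k[j]) * -_softplus(eta)
                - 0.5 * xg[None, :] ** 2)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, -1:]
        idx = (cdf < rng.random((D, 1))).sum(axis=1)
        u_out[:, j] = sigma * xg[np.minimum(idx, grid_pts - 1)]
    return u_out


def fit_consistency_model(table: pd.DataFrame, rule: str,
                          spec: ModelSpec | None = None,
                          participant_effects: bool = True) -> ConsistencyFit:
    """Fit the random-intercept logistic model to one consistency column.

    ``table`` is a coded trial table (one grammar condition) with columns
    ``participant_id``, ``group`` and a 0/1 column named ``rule``.  The
    participant intercepts are integrated out of the sampled posterior by
    Gauss-Hermite quadrature and reconstructed afterwards from their exact
    conditional posterior, so the MCMC runs on (alpha[, beta], log sigma_u)
    only.
    """
    spec = spec or ModelSpec()
    if rule not in table.columns:
        raise KeyError(f"no consistency column {rule!r} in table")
    vals = table[rule].unique()
    if len(vals) < 2:
        warnings.warn(f"degenerate outcome: column {rule!r} is constant "
                      f"({vals[0]}); posterior is prior-regularized", RuntimeWarning)
    k, n, g_idx, participants, groups = _aggregate(table, rule)
    two = len(groups) == 2
    if len(groups) > 2:
        raise ValueError("at most two groups are supported")
    n_fixed = 2 if two else 1
    sd_f, sc = spec.fixed_sd, spec.re_scale
    gx, glw = _gh(spec.sampler.gh_nodes)

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        alpha = theta[:, 0]
        beta = theta[:, 1] if two else 0.0
        sigma = np.exp(theta[:, n_fixed])
        eta0 = alpha[:, None] + (beta[:, None] * g_idx if two else 0.0)   # (W, P)
        eta = eta0[:, :, None] + sigma[:, None, None] * gx                # (W, P, Q)
        terms = (k[None, :, None] * -_softplus(-eta)
                 + (n - k)[None, :, None] * -_softplus(eta))
        ll = np.sum(_logsumexp(terms + glw, axis=2), axis=1)
        lp = -0.5 * (alpha / sd_f) ** 2
        if two:
            lp = lp - 0.5 * (beta / sd_f) ** 2
        lp = lp + _halfcauchy_logpdf(sigma, sc) + theta[:, n_fixed]       # + Jacobian
        return ll + lp

    x0 = np.zeros(n_fixed + 1)
    x0[0] = _empirical_logit(k[g_idx == 0].sum(), n[g_idx == 0].sum())
    if two:
        x0[1] = _empirical_logit(k[g_idx == 1].sum(), n[g_idx == 1].sum()) - x0[0]
    x0[n_fixed] = np.log(0.5)
    draws, diag = _run_sampler(log_prob, x0, spec.sampler,
                               param_names_for_gate=range(n_fixed + 1))
    alpha = draws[:, 0]
    beta = draws[:, 1] if two else None
    sigma_u = np.exp(draws[:, n_fixed])
    if participant_effects:
        eta0 = alpha[:, None] + (beta[:, None] * g_idx if two else np.zeros(len(k)))
        u = _conditional_u_draws(eta0, k, n, sigma_u,
                                 np.random.default_rng(spec.sampler.seed + 1))
    else:
        u = None
    return ConsistencyFit(
        rule=rule, groups=groups, participants=participants,
        group_of=g_idx, alpha=alpha, beta=beta,
        sigma_u=sigma_u, u=u, diagnostics=diag, spec=spec,
    )


def group_probability_draws(fit: ConsistencyFit) -> dict[str, np.ndarray]:
    """Draws of the average participant's consistency probability per group."""
    out = {fit.groups[0]: 1 / (1 + np.exp(-fit.alpha))}
    if fit.beta is not None:
        out[fit.groups[1]] = 1 / (1 + np.exp(-(fit.alpha + fit.beta)))
    return out


def latent_cohens_d(fit: ConsistencyFit) -> np.ndarray:
    """Group difference standardized on the latent logistic scale:
    d = beta / sqrt(sigma_u^2 + pi^2/3)."""
    if fit.beta is None:
        raise ValueError("latent Cohen's d needs a two-group fit")
    return fit.beta / np.sqrt(fit.sigma_u ** 2 + _LOGISTIC_VAR)


def individual_probabilities(fit: ConsistencyFit,
                             pp_threshold: float = 0.95) -> pd.DataFrame:
    """Per-participant trial-consistency probabilities with above-chance flags.

    A participant is flagged above chance when their trial probability
    exceeds .5 with posterior probability >= ``pp_threshold``.
    """
    if fit.u is None:
        raise ValueError("fit was run without participant effects")
    rows = []
    for j, pid in enumerate(fit.participants):
        eta = fit.alpha + fit.u[:, j]
        if fit.beta is not None and fit.group_of[j] == 1:
            eta = eta + fit.beta
        s = summarize(1 / (1 + np.exp(-eta)), null=0.5)
        rows.append({"participant_id": pid, "group": fit.groups[fit.group_of[j]],
                     **s.as_dict(), "above_chance": s.pp_positive >= pp_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LogOR contrast (target vs alternate rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogORContrast:
    target: str
    alternate: str
    by_group: dict                     # group label -> PosteriorSummary
    draws: dict                        # group label -> LogOR draws
    diagnostics: dict


def grammar_logodds_contrast(table: pd.DataFrame, target: str, alternate: str,
                             spec: ModelSpec | None = None,
                             mode: str = "joint") -> LogORContrast:
    """Posterior of log-odds(target consistency) - log-odds(alternate
    consistency) for the average participant of each group.

    ``mode="joint"`` (default) fits one model with rule as a within-trial
    factor and correlated participant intercept and rule slope (LKJ prior on
    the correlation); ``mode="perrule"`` differences two independent
    single-rule fits, which ignores the within-participant correlation and
    is cheaper but more conservative.
    """
    spec = spec or ModelSpec()
    for col in (target, alternate):
        if col not in table.columns:
            raise KeyError(f"no consistency column {col!r} in table")
    if (table[target] == table[alternate]).all():
        warnings.warn(f"coding columns {target!r} and {alternate!r} are identical; "
                      "LogOR is exactly 0", RuntimeWarning)
        groups = sorted(table["group"].unique())
        zeros = np.zeros(2000)
        return LogORContrast(target, alternate,
                             {g: summarize(zeros) for g in groups},
                             {g: zeros for g in groups}, {"degenerate": True})
    if mode == "perrule":
        ft = fit_consistency_model(table, target, spec)
        fa = fit_consistency_model(table, alternate, spec)
        m = min(len(ft.alpha), len(fa.alpha))
        draws = {ft.groups[0]: ft.alpha[:m] - fa.alpha[:m]}
        if ft.beta is not None:
            draws[ft.groups[1]] = (ft.alpha[:m] + ft.beta[:m]) - (fa.alpha[:m] + fa.beta[:m])
        diag = {"target": ft.diagnostics, "alternate": fa.diagnostics}
        return LogORContrast(target, alternate,
                             {g: summarize(d) for g, d in draws.items()}, draws, diag)
    if mode != "joint":
        raise ValueError(f"unknown mode {mode!r}")

    # aggregate per participant x rule: two binomial cells per participant
    agg = table.groupby(["participant_id", "group"], sort=True)[[target, alternate]] \
        .agg(["sum", "count"]).reset_index()
    groups = sorted(agg["group"].unique())
    two = len(groups) == 2
    parts = list(agg["participant_id"])
    gidx = agg["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    k_t = agg[(target, "sum")].to_numpy(float)
    n_t = agg[(target, "count")].to_numpy(float)
    k_a = agg[(alternate, "sum")].to_numpy(float)
    n_a = agg[(alternate, "count")].to_numpy(float)
    # fixed: alpha, (beta), gamma, (delta); hyper: log sig_u, log sig_v, atanh(rho)
    n_fixed = 4 if two else 2
    ndim = n_fixed + 3
    sd_f, sc, eta_lkj = spec.fixed_sd, spec.re_scale, spec.lkj_eta
    # 2-D Gauss-Hermite grid over the correlated participant effects (u, v):
    # u enters both rules' predictors, v only the target rule's
    q1 = min(spec.sampler.gh_nodes, 15)
    gx, glw = _gh(q1)
    X1, X2 = np.meshgrid(gx, gx, indexing="ij")
    X1, X2 = X1.ravel(), X2.ravel()
    LW = (glw[:, None] + glw[None, :]).ravel()

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        i = 0
        alpha = theta[:, i]; i += 1
        beta = theta[:, i] if two else 0.0
        i += two
        gamma = theta[:, i]; i += 1
        delta = theta[:, i] if two else 0.0
        i += two
        su = np.exp(theta[:, i])
        sv = np.exp(theta[:, i + 1])
        rho = np.clip(np.tanh(theta[:, i + 2]), -0.999, 0.999)
        u = su[:, None] * X1[None, :]                                     # (W, Q)
        v = sv[:, None] * (rho[:, None] * X1 + np.sqrt(1 - rho[:, None] ** 2) * X2)
        base = alpha[:, None] + (beta[:, None] * gidx if two else 0.0)    # (W, P)
        shift = gamma[:, None] + (delta[:, None] * gidx if two else 0.0)  # (W, P)
        eta_a = base[:, :, None] + u[:, None, :]                          # (W, P, Q)
        eta_t = eta_a + shift[:, :, None] + v[:, None, :]
        terms = (k_a[None, :, None] * -_softplus(-eta_a)
                 + (n_a - k_a)[None, :, None] * -_softplus(eta_a)
                 + k_t[None, :, None] * -_softplus(-eta_t)
                 + (n_t - k_t)[None, :, None] * -_softplus(eta_t))
        ll = np.sum(_logsumexp(terms + LW, axis=2), axis=1)
        lp = -0.5 * ((alpha / sd_f) ** 2 + (gamma / sd_f) ** 2)
        if two:
            lp = lp - 0.5 * ((beta / sd_f) ** 2 + (delta / sd_f) ** 2)
        lp = lp + _halfcauchy_logpdf(su, sc) + theta[:, i]
        lp = lp + _halfcauchy_logpdf(sv, sc) + theta[:, i + 1]
        # LKJ(eta) on the 2x2 correlation: density prop to (1-rho^2)^(eta-1),
        # plus the tanh-transform Jacobian log(1-rho^2)
        lp = lp + eta_lkj * np.log1p(-rho ** 2)
        return ll + lp

    x0 = np.zeros(ndim)
    x0[0] = _empirical_logit(k_a[gidx == 0].sum(), n_a[gidx == 0].sum())
    gpos = 2 if two else 1
    x0[gpos] = _empirical_logit(k_t[gidx == 0].sum(), n_t[gidx == 0].sum()) - x0[0]
    x0[n_fixed] = x0[n_fixed + 1] = np.log(0.5)
    draws, diag = _run_sampler(log_prob, x0, spec.sampler,
                               param_names_for_gate=range(n_fixed))
    gamma = draws[:, gpos]
    out_draws = {groups[0]: gamma}
    if two:
        out_draws[groups[1]] = gamma + draws[:, 3]
    return LogORContrast(target, alternate,
                         {g: summarize(d) for g, d in out_draws.items()},
                         out_draws, diag)


# ---------------------------------------------------------------------------
# stimulus-property interaction model
# ---------------------------------------------------------------------------

@dataclass
class PropertyFit:
    """Posterior draws for the group x similarity x generalization model."""

    groups: list[str]
    cell_means: np.ndarray             # (n_draws, n_groups*4) latent cell means
    cell_index: pd.DataFrame           # rows: (group, similar, generalization)
    sigma: np.ndarray                  # (n_draws, 3) RE SDs (intercept, sim, gen)
    diagnostics: dict
    spec: ModelSpec

    def _sel(self, **cond) -> np.ndarray:
        mask = np.ones(len(self.cell_index), bool)
        for key, val in cond.items():
            mask &= self.cell_index[key].to_numpy() == val
        cols = np.where(mask)[0]
        return self.cell_means[:, cols].mean(axis=1)

    def contrast(self, a: dict, b: dict) -> PosteriorSummary:
        """Latent-scale contrast mean(cells a) - mean(cells b)."""
        return summarize(self._sel(**a) - self._sel(**b))

    def contrast_d(self, a: dict, b: dict) -> PosteriorSummary:
        """Same contrast standardized as latent Cohen's d."""
        diff = self._sel(**a) - self._sel(**b)
        return summarize(diff / np.sqrt(self.sigma[:, 0] ** 2 + _LOGISTIC_VAR))


def _corr3_chol(t12, t13, t23):
    """Cholesky factors of 3x3 correlation matrices from tanh-parameterized
    pairwise correlations; returns (L, logdet, valid mask)."""
    r12, r13, r23 = np.tanh(t12), np.tanh(t13), np.tanh(t23)
    l11 = np.ones_like(r12)
    l21, l31 = r12, r13
    l22 = np.sqrt(np.clip(1 - r12 ** 2, 1e-12, None))
    l32 = (r23 - r12 * r13) / l22
    rest = 1 - r13 ** 2 - l32 ** 2
    valid = rest > 1e-10
    l33 = np.sqrt(np.clip(rest, 1e-12, None))
    logdet = 2 * (np.log(l22) + np.log(l33))
    return (l11, l21, l22, l31, l32, l33), logdet, valid, (r12, r13, r23)


def fit_property_model(table: pd.DataFrame, spec: ModelSpec | None = None,
                       outcome: str = "accuracy") -> PropertyFit:
    """Fit the stimulus-property interaction model.

    ``table`` is an annotated coded trial table with 0/1 columns ``similar``
    and ``generalization`` plus the outcome column.  Fixed effects are the
    full set of group x similarity x generalization latent cell means (each
    with a Normal(0,2) prior); random effects are correlated participant
    intercepts and slopes for both properties (Half-Cauchy(0,2) SDs, LKJ(2)
    correlation).  Reported simple effects and interaction contrasts are
    computed from the cell means via :meth:`PropertyFit.contrast`.
    """
    spec = spec or ModelSpec()
    for col in ("similar", "generalization", outcome):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    agg = (table.groupby(["participant_id", "group", "similar", "generalization"],
                         sort=True)[outcome].agg(["sum", "count"]).reset_index())
    groups = sorted(agg["group"].unique())
    parts = sorted(agg["participant_id"].unique())
    cells = agg[["group", "similar", "generalization"]].drop_duplicates().reset_index(drop=True)
    cell_key = cells.apply(tuple, axis=1)
    cidx = agg[["group", "similar", "generalization"]].apply(tuple, axis=1).map(
        {kk: i for i, kk in enumerate(cell_key)}).to_numpy()
    pidx = agg["participant_id"].map({p: i for i, p in enumerate(parts)}).to_numpy()
    sim = agg["similar"].to_numpy(float)
    gen = agg["generalization"].to_numpy(float)
    k = agg["sum"].to_numpy(float)
    n = agg["count"].to_numpy(float)
    P, C = len(parts), len(cells)
    # hyperparameters only: C cell means, 3 log-sds, 3 corr transforms; the
    # correlated participant effects (intercept, similarity slope,
    # generalization slope) are marginalized by a 3-D Gauss-Hermite grid
    ndim = C + 6
    sd_f, sc, eta_lkj = spec.fixed_sd, spec.re_scale, spec.lkj_eta
    # order cells within participant for the quadrature sum
    order = np.lexsort((gen, sim, pidx))
    cidx_o, pidx_o = cidx[order], pidx[order]
    sim_o, gen_o = sim[order], gen[order]
    k_o, n_o = k[order], n[order]
    cells_per_part = np.bincount(pidx_o)
    if not (cells_per_part == cells_per_part[0]).all():
        raise ValueError("every participant needs data in every stimulus cell")
    n_cell = int(cells_per_part[0])
    # reshape to (P, n_cell)
    K = k_o.reshape(P, n_cell)
    N = n_o.reshape(P, n_cell)
    CI = cidx_o.reshape(P, n_cell)
    SIM = sim_o.reshape(P, n_cell)
    GEN = gen_o.reshape(P, n_cell)
    q1 = min(spec.sampler.gh_nodes, 7)
    gx, glw = _gh(q1)
    Z1, Z2, Z3 = (a.ravel() for a in np.meshgrid(gx, gx, gx, indexing="ij"))
    LW3 = (glw[:, None, None] + glw[None, :, None] + glw[None, None, :]).ravel()
    Q = Z1.size

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        mu = theta[:, :C]
        sig = np.exp(theta[:, C:C + 3])
        t12, t13, t23 = theta[:, C + 3], theta[:, C + 4], theta[:, C + 5]
        (l11, l21, l22, l31, l32, l33), logdet, valid, (r12, r13, r23) = \
            _corr3_chol(t12, t13, t23)
        # correlated effects at the quadrature nodes: (W, Q)
        u = sig[:, 0, None] * Z1[None, :]
        a = sig[:, 1, None] * (l21[:, None] * Z1 + l22[:, None] * Z2)
        b = sig[:, 2, None] * (l31[:, None] * Z1 + l32[:, None] * Z2 + l33[:, None] * Z3)
        for c in range(n_cell):
            # (W, P, Q) linear predictor for this within-participant cell
            eta = (mu[:, CI[:, c], None]
                   + u[:, None, :] + SIM[0, c] * a[:, None, :] + GEN[0, c] * b[:, None, :])
            term = (K[:, c][None, :, None] * -_softplus(-eta)
                    + (N[:, c] - K[:, c])[None, :, None] * -_softplus(eta))
            acc = term if c == 0 else acc + term
        ll = np.sum(_logsumexp(acc + LW3, axis=2), axis=1)
        lp = -0.5 * np.sum((mu / sd_f) ** 2, axis=-1)
        lp = lp + np.sum(_halfcauchy_logpdf(sig, sc) + theta[:, C:C + 3], axis=-1)
        # LKJ(eta) density prop to det(R)^(eta-1); tanh Jacobians for each rho
        lp = lp + (eta_lkj - 1.0) * logdet
        with np.errstate(divide="ignore"):
            for rr in (r12, r13, r23):
                lp = lp + np.log1p(-np.minimum(rr ** 2, 1.0 - 1e-12))
        return np.where(valid, ll + lp, -np.inf)

    x0 = np.zeros(ndim)
    for i in range(C):
        m = cidx == i
        x0[i] = _empirical_logit(k[m].sum(), n[m].sum())
    x0[C:C + 3] = np.log(0.3)
    draws, diag = _run_sampler(log_prob, x0, spec.sampler,
                               param_names_for_gate=range(C))
    return PropertyFit(groups=groups, cell_means=draws[:, :C], cell_index=cells,
                       sigma=np.exp(draws[:, C:C + 3]), diagnostics=diag, spec=spec)
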