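"""Default-prior (JZS) Bayes factors for the mixed-ANOVA model set, plus
one-sided t-test and regression Bayes factors and the sequential stopping
rule.

Model and priors
----------------
Observations ``y`` (standardized RTs) follow a linear mixed model

    y = mu * 1 + X theta + eps,    eps ~ N(0, sigma^2 I)

where ``X`` concatenates sum-to-zero-projected indicator blocks, one block
per categorical term (fixed effects such as repetition type, target type,
their interactions, and the participant random factor).  Under the default
g-prior structure each term's coefficients are ``theta_t ~ N(0, sigma^2 g_t
I)`` with ``g_t ~ InverseGamma(1/2, r_t^2 / 2)`` — a scaled Cauchy prior on
standardized effects — with ``r = 0.5`` for fixed effects and ``r = 1.0``
for the participant random factor.  ``(mu, sigma^2)`` get the Jeffreys
prior ``1/sigma^2``.

Conditional on the g vector the marginal likelihood is available in closed
form; marginalizing ``theta``, ``mu`` and ``sigma^2`` gives

    m(y | g) = Gamma((n-1)/2) / pi^((n-1)/2)
               * |M_g|^(-1/2) * (1' V^-1 1)^(-1/2) * q_g^(-(n-1)/2)

with ``V = I + X G X'``, ``M_g = I_p + G^(1/2) X'X G^(1/2)`` (so ``|V| =
|M_g|``, evaluated in p x p space via the Woodbury identity) and ``q_g``
the V-metric residual sum of squares about the V-weighted mean.  The
remaining low-dimensional integral over ``g`` is evaluated by adaptive
importance sampling: a Laplace approximation in log-g space provides a
multivariate-t proposal, and the Monte-Carlo standard error of the log
marginal likelihood is reported with every Bayes factor.

Bayes factors between two models are ratios of their marginal likelihoods;
all are computed against the common intercept-only null so log BFs are
exactly transitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, linalg, optimize, stats
from scipy.special import gammaln, logsumexp

from .design import BIAS, OTHER, REP, SWITCH

__all__ = [
    "PriorScales", "ModelSpec", "BfResult", "EffectPosterior",
    "model_set", "analysis_table", "log_marginal", "anova_bf",
    "effect_posterior", "ttest_bf_onesided", "regression_bf",
    "sequential_stop",
]

DEFAULT_SAMPLES = 10_000


@dataclass(frozen=True)
class PriorScales:
    """Cauchy prior scales for standardized effects (Rouder-Morey defaults)."""

    fixed: float = 0.5
    random: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure plus the participant random factor."""

    name: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = ("participant",)


@dataclass(frozen=True)
class BfResult:
    model_a: str
    model_b: str
    log_bf: float  # natural log of BF(a over b)
    mc_se: float
    samples_used: int

    @property
    def bf(self) -> float:
        return float(np.exp(self.log_bf))


@dataclass(frozen=True)
class EffectPosterior:
    contrast: str
    mean: float
    ci_low: float
    ci_high: float
    n_samples: int


def model_set(experiment_id: str) -> dict[str, ModelSpec]:
    """The standard RT model set M1-M4 (plus Mnull) for one experiment.

    Set-size designs include the distractor-number factor in every model.
    """
    extra = ("set_size",) if experiment_id in ("exp2a", "exp2b") else ()
    m1 = ("repetition",) + extra
    return {
        "Mnull": ModelSpec("Mnull", ()),
        "M1": ModelSpec("M1", m1),
        "M2": ModelSpec("M2", m1 + ("target",)),
        "M3": ModelSpec("M3", m1 + ("target:sub_block",)),
        "M4": ModelSpec("M4", m1 + ("target", "target:sub_block")),
    }


# ---------------------------------------------------------------------------
# design-matrix construction

_FACTOR_COLUMNS = {
    "repetition": ("repetition_type", (REP, SWITCH)),
    "target": ("target_type", (BIAS, OTHER)),
    "sub_block": ("sub_block", ("I", "II", "III")),
    "response_rep": ("response_repetition", (REP, SWITCH)),
}


def _factor_levels(data: pd.DataFrame, factor: str):
    if factor == "set_size":
        levels = tuple(sorted(pd.unique(data["set_size"].dropna())))
        if len(levels) < 2:
            raise ValueError("set_size factor needs two levels in the data")
        return "set_size", levels
    if factor == "participant":
        return "participant", tuple(sorted(pd.unique(data["participant"])))
    try:
        return _FACTOR_COLUMNS[factor]
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}") from None


def _sum_zero_basis(k: int) -> np.ndarray:
    """Orthonormal k x (k-1) basis of the sum-to-zero subspace."""
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q[:, : k - 1]


def _factor_block(data: pd.DataFrame, factor: str) -> np.ndarray:
    column, levels = _factor_levels(data, factor)
    vals = data[column].to_numpy()
    level_index = {lev: i for i, lev in enumerate(levels)}
    try:
        codes = np.array([level_index[v] for v in vals])
    except KeyError as exc:
        raise ValueError(f"unexpected level {exc} for factor {factor}") from None
    z = np.zeros((len(vals), len(levels)))
    z[np.arange(len(vals)), codes] = 1.0
    return z @ _sum_zero_basis(len(levels))


def _term_block(data: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one model term; interactions are row-wise products of the
    projected main-effect codings."""
    parts = [_factor_block(data, f) for f in term.split(":")]
    block = parts[0]
    for nxt in parts[1:]:
        block = np.einsum("ni,nj->nij", block, nxt).reshape(len(block), -1)
    return block


@dataclass
class _Prepared:
    """Sufficient statistics of (data, model) for marginal-likelihood work."""

    y: np.ndarray
    X: np.ndarray
    term_slices: dict[str, slice]
    r_by_term: dict[str, float]
    n: int = field(init=False)
    yty: float = field(init=False)
    sum_y: float = field(init=False)
    XtX: np.ndarray = field(init=False)
    Xty: np.ndarray = field(init=False)
    Xt1: np.ndarray = field(init=False)

    def __post_init__(self):
        self.n = len(self.y)
        self.yty = float(self.y @ self.y)
        self.sum_y = float(self.y.sum())
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.Xt1 = self.X.sum(axis=0)

    @property
    def terms(self) -> list[str]:
        return list(self.term_slices)

    def expand(self, g_by_term: np.ndarray) -> np.ndarray:
        g = np.empty(self.X.shape[1])
        for gt, sl in zip(g_by_term, self.term_slices.values()):
            g[sl] = gt
        return g


def _prepare(data: pd.DataFrame, model: ModelSpec,
             priors: PriorScales, response: str) -> _Prepared:
    y = data[response].to_numpy(dtype=float)
    blocks, slices, r_by_term = [], {}, {}
    start = 0
    for term in model.fixed_terms + model.random_terms:
        b = _term_block(data, term)
        blocks.append(b)
        slices[term] = slice(start, start + b.shape[1])
        start += b.shape[1]
        r_by_term[term] = (priors.random if term in model.random_terms
                           else priors.fixed)
    X = np.hstack(blocks) if blocks else np.zeros((len(y), 0))
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design for model {model.name}: some term is "
                f"aliased (rank {rank} < {X.shape[1]} columns)")
    return _Prepared(y=y, X=X, term_slices=slices, r_by_term=r_by_term)


# ---------------------------------------------------------------------------
# marginal likelihood

def _log_m_given_g(prep: _Prepared, g_cols: np.ndarray) -> tuple[float, dict]:
    """Closed-form log m(y|g) via the Woodbury identity (p x p space)."""
    n = prep.n
    const = gammaln((n - 1) / 2.0) - ((n - 1) / 2.0) * np.log(np.pi)
    if prep.X.shape[1] == 0:
        q = prep.yty - prep.sum_y ** 2 / n
        return const - 0.5 * np.log(n) - ((n - 1) / 2.0) * np.log(q), {}
    s = np.sqrt(g_cols)
    M = np.eye(len(s)) + (s[:, None] * prep.XtX) * s[None, :]
    c, low = linalg.cho_factor(M, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    a = s * prep.Xty
    b = s * prep.Xt1
    Ma = linalg.cho_solve((c, low), a)
    Mb = linalg.cho_solve((c, low), b)
    yVy = prep.yty - a @ Ma
    oVo = n - b @ Mb
    oVy = prep.sum_y - b @ Ma
    q = yVy - oVy ** 2 / oVo
    if q <= 0 or oVo <= 0:
        return -np.inf, {}
    logm = (const - 0.5 * logdet - 0.5 * np.log(oVo)
            - ((n - 1) / 2.0) * np.log(q))
    return logm, {"q": q, "chol": (c, low), "s": s}


def _log_g_prior(g: np.ndarray, r: np.ndarray) -> float:
    """Sum of InverseGamma(1/2, r^2/2) log densities."""
    return float(np.sum(0.5 * np.log(r ** 2 / 2.0) - gammaln(0.5)
                        - 1.5 * np.log(g) - r ** 2 / (2.0 * g)))


class _ImportanceFit:
    """Laplace-guided importance-sampling estimate of log m(y) for a model."""

    def __init__(self, prep: _Prepared, n_samples: int, rng: np.random.Generator):
        self.prep = prep
        self.r = np.array([prep.r_by_term[t] for t in prep.terms])
        self.k = len(self.r)
        if self.k == 0:
            self.log_ml, _ = _log_m_given_g(prep, np.zeros(0))
            self.mc_se = 0.0
            self.samples_used = 0
            return

        def neg_target(z):
            g = np.exp(z)
            logm, _ = _log_m_given_g(prep, prep.expand(g))
            return -(logm + _log_g_prior(g, self.r) + z.sum())

        z0 = np.full(self.k, np.log(0.2))
        res = optimize.minimize(neg_target, z0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 2000})
        self.z_mode = res.x
        hess = _numeric_hessian(neg_target, res.x)
        try:
            cov = np.linalg.inv(hess)
            # guard against non-PD curvature far from a clean optimum
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = np.diag(1.0 / np.maximum(np.diag(hess), 1e-2))
        self.chol = np.linalg.cholesky(cov * 1.4)  # mildly overdispersed
        df = 7.0
        # multivariate-t proposal draws
        u = rng.standard_normal((n_samples, self.k))
        w = rng.chisquare(df, n_samples) / df
        self.z_draws = self.z_mode + (u @ self.chol.T) / np.sqrt(w)[:, None]
        log_q = _mvt_logpdf(self.z_draws, self.z_mode, self.chol, df)
        log_f = np.array([-neg_target(z) for z in self.z_draws])
        logw = log_f - log_q
        self.logw = logw
        lse = logsumexp(logw)
        self.log_ml = float(lse - np.log(n_samples))
        wt = np.exp(logw - lse)
        self.wt = wt
        self.mc_se = float(np.sqrt(max(np.sum(wt ** 2) - 1.0 / n_samples, 0.0)))
        self.samples_used = n_samples


def _numeric_hessian(f, x, h=5e-3) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h ** 2)
    return H


def _mvt_logpdf(z, mode, chol, df):
    k = z.shape[1]
    diff = linalg.solve_triangular(chol, (z - mode).T, lower=True).T
    quad = np.sum(diff ** 2, axis=1)
    logdet = np.log(np.diag(chol)).sum()
    return (gammaln((df + k) / 2) - gammaln(df / 2) - 0.5 * k * np.log(df * np.pi)
            - logdet - 0.5 * (df + k) * np.log1p(quad / df))


def analysis_table(corrected: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the RT model comparison: included trials of post-bias
    neutral blocks (those carry sub-block labels) with a defined repetition
    type."""
    mask = corrected["sub_block"].notna() & (corrected["repetition_type"] != "undefined")
    return corrected[mask]


def log_marginal(data: pd.DataFrame, model: ModelSpec,
                 priors: PriorScales = PriorScales(),
                 n_samples: int = DEFAULT_SAMPLES, seed=0,
                 response: str = "zrt_corrected") -> tuple[float, float, int]:
    """Log marginal likelihood of one model (vs nothing), with MC SE."""
    prep = _prepare(data, model, priors, response)
    fit = _ImportanceFit(prep, n_samples, np.random.default_rng(seed))
    return fit.log_ml, fit.mc_se, fit.samples_used


def anova_bf(data: pd.DataFrame, model_a: ModelSpec, model_b: ModelSpec,
             priors: PriorScales = PriorScales(),
             n_samples: int = DEFAULT_SAMPLES, seed=0,
             response: str = "zrt_corrected") -> BfResult:
    """Bayes factor of ``model_a`` over ``model_b`` on the same data."""
    if model_a.name == model_b.name and model_a == model_b:
        return BfResult(model_a.name, model_b.name, 0.0, 0.0, 0)
    ss = np.random.SeedSequence(seed).spawn(2)
    la, sa, na = log_marginal(data, model_a, priors, n_samples, ss[0], response)
    lb, sb, nb = log_marginal(data, model_b, priors, n_samples, ss[1], response)
    return BfResult(model_a.name, model_b.name, la - lb,
                    float(np.hypot(sa, sb)), na + nb)


# ---------------------------------------------------------------------------
# posterior effect summaries

#: contrast name -> (term, faster level, slower level); the reported effect
#: is mean(slower) - mean(faster), positive when the expected facilitation
#: holds
_CONTRASTS = {
    "repetition": ("repetition", REP, SWITCH),
    "target": ("target", BIAS, OTHER),
    "set_size": ("set_size", "low", "high"),
    "response_rep": ("response_rep", REP, SWITCH),
}


def effect_posterior(data: pd.DataFrame, model: ModelSpec, contrast: str,
                     n_samples: int = DEFAULT_SAMPLES, seed=0,
                     priors: PriorScales = PriorScales(),
                     response: str = "zrt_corrected") -> EffectPosterior:
    """Posterior mean and central 95% interval of a standardized contrast.

    Sampling is exact given g: g values are importance-resampled from the
    marginal-likelihood proposal, then ``sigma^2 | g, y`` (inverse-gamma)
    and ``(mu, theta) | sigma^2, g, y`` (Gaussian) are drawn in turn.
    """
    term, fast, slow = _CONTRASTS[contrast]
    if term not in model.fixed_terms:
        raise ValueError(f"contrast {contrast!r} not in model {model.name}")
    prep = _prepare(data, model, priors, response)
    rng = np.random.default_rng(seed)
    fit = _ImportanceFit(prep, max(2000, n_samples // 5), rng)

    _, levels = _factor_levels(data, term)
    if term == "set_size":
        fast_i, slow_i = 0, len(levels) - 1  # sorted ascending: low, high
    else:
        fast_i, slow_i = levels.index(fast), levels.index(slow)
    Q = _sum_zero_basis(len(levels))
    c_term = Q[slow_i] - Q[fast_i]
    c = np.zeros(prep.X.shape[1] + 1)
    sl = prep.term_slices[term]
    c[1 + sl.start: 1 + sl.stop] = c_term

    # importance-resample g draws, group identical ones
    idx = rng.choice(len(fit.wt), size=n_samples, p=fit.wt)
    draws = np.empty(n_samples)
    pos = 0
    n, p = prep.n, prep.X.shape[1]
    for u, count in zip(*np.unique(idx, return_counts=True)):
        g = prep.expand(np.exp(fit.z_draws[u]))
        _, aux = _log_m_given_g(prep, g)
        A = np.empty((p + 1, p + 1))
        A[0, 0] = n
        A[0, 1:] = A[1:, 0] = prep.Xt1
        A[1:, 1:] = prep.XtX + np.diag(1.0 / g)
        cA = np.linalg.cholesky(A)
        rhs = np.concatenate(([prep.sum_y], prep.Xty))
        mean = linalg.cho_solve((cA, True), rhs)
        sig2 = stats.invgamma.rvs((n - 1) / 2.0, scale=aux["q"] / 2.0,
                                  size=count, random_state=rng)
        zdraw = rng.standard_normal((count, p + 1))
        dev = linalg.solve_triangular(cA, zdraw.T, lower=True, trans="T").T
        samples = mean + dev * np.sqrt(sig2)[:, None]
        draws[pos:pos + count] = samples @ c
        pos += count
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return EffectPosterior(contrast, float(draws.mean()), float(lo),
                           float(hi), n_samples)


# ---------------------------------------------------------------------------
# t-test and regression Bayes factors

def ttest_bf_onesided(scores, direction: str = "greater",
                      rscale: float = np.sqrt(2) / 2):
    """JZS one-sample Bayes factor with a direction-truncated Cauchy prior.

    Returns a dict with ``log_bf`` (directional alternative vs point null),
    ``log_bf_two_sided``, and the observed t statistic.  Computed by 1-D
    numerical integration of the noncentral-t likelihood against the prior
    on the standardized effect delta.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 scores")
    if np.std(x, ddof=1) == 0:
        raise ValueError("constant scores: t statistic undefined")
    t_obs = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    df = n - 1

    def integrand(delta):
        return (stats.nct.pdf(t_obs, df, delta * np.sqrt(n))
                * stats.cauchy.pdf(delta, scale=rscale))

    m0 = stats.t.pdf(t_obs, df)
    pos, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    neg, _ = integrate.quad(integrand, -np.inf, 0, limit=200)
    m1 = pos + neg
    m_dir = 2.0 * (pos if direction == "greater" else neg)
    return {
        "log_bf": float(np.log(m_dir) - np.log(m0)),
        "log_bf_two_sided": float(np.log(m1) - np.log(m0)),
        "t": float(t_obs),
        "n": n,
    }


def regression_bf(x, y, rscale: float = np.sqrt(2) / 4) -> BfResult:
    """Bayes factor of the slope-included vs intercept-only linear model.

    Uses the JZS prior on the standardized slope: the BF depends on the data
    only through R^2 and reduces to a 1-D integral over the g parameter.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    r2 = np.corrcoef(x, y)[0, 1] ** 2 if np.std(y) > 0 else 0.0

    # integrate in log-g space for numerical stability at R^2 near 1
    def log_integrand(z):
        g = np.exp(z)
        return ((n - 2) / 2.0 * np.log1p(g)
                - (n - 1) / 2.0 * np.log1p(g * (1 - r2))
                + stats.invgamma.logpdf(g, 0.5, scale=n * rscale ** 2 / 2.0)
                + z)

    shift = max(log_integrand(z) for z in np.linspace(-10, 25, 150))
    bf10, _ = integrate.quad(lambda z: np.exp(log_integrand(z) - shift),
                             -40, 40, limit=300)
    return BfResult("M_beta", "M_0", float(np.log(bf10) + shift), 0.0, 0)


# ---------------------------------------------------------------------------
# sequential stopping rule

def sequential_stop(batches, experiment_id: str, threshold: float = 10.0,
                    priors: PriorScales = PriorScales(),
                    n_samples: int = 4000, seed=0,
                    preprocessor=None) -> dict:
    """Apply the sequential Bayesian stopping rule over participant batches.

    ``batches`` yields analysis-ready trial tables (cumulative preprocessing
    is the caller's business via ``preprocessor``; by default each batch is
    assumed already preprocessed and is concatenated as-is).  After each
    batch the four-model comparison is recomputed on all data so far.  Data
    collection stops when one of M2/M3/M4 beats M1 with BF > threshold *and*
    the winning model attributes the long-term effect to the bias color
    (positive target contrast), or when M1 beats all of them with BF >
    threshold.  An exhausted stream yields status ``inconclusive``.
    """
    models = model_set(experiment_id)
    rng_seed = np.random.SeedSequence(seed)
    accumulated = None
    n_batches = 0
    for batch in batches:
        n_batches += 1
        accumulated = (batch if accumulated is None
                       else pd.concat([accumulated, batch], ignore_index=True))
        data = preprocessor(accumulated) if preprocessor else accumulated
        sub = analysis_table(data)
        seeds = rng_seed.spawn(5)
        lm = {name: log_marginal(sub, models[name], priors, n_samples,
                                 seeds[i])[0]
              for i, name in enumerate(["M1", "M2", "M3", "M4"])}
        n_p = int(sub["participant"].nunique())
        log_thr = np.log(threshold)
        alts = {m: lm[m] - lm["M1"] for m in ("M2", "M3", "M4")}
        best = max(alts, key=alts.get)
        if alts[best] > log_thr:
            sign_model = models[best] if "target" in models[best].fixed_terms \
                else models["M2"]
            post = effect_posterior(sub, sign_model, "target",
                                    n_samples=4000, seed=seeds[4],
                                    priors=priors)
            if post.mean > 0:
                return {"decision": best, "n_participants": n_p,
                        "n_batches": n_batches, "log_bf_vs_M1": alts[best],
                        "target_effect": post.mean, "status": "stopped"}
            # wrong-signed long-term effect: not evidence for priming
        elif all(-v > log_thr for v in alts.values()):
            return {"decision": "M1", "n_participants": n_p,
                    "n_batches": n_batches,
                    "log_bf_vs_best_alt": -max(alts.values()),
                    "status": "stopped"}
    return {"decision": None, "status": "inconclusive",
            "n_batches": n_batches}
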