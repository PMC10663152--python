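"""Bayesian changepoint regression of log-parameters on age.

The headline model is a piecewise-linear hinge: the expected log-parameter
is b0 + b1 * (age - omega) below the changepoint omega and
b0 + b2 * (age - omega) above it, continuous at omega.  A student-t
likelihood makes the regression robust to outlying estimates, and random
intercepts absorb mean offsets between experiments.  Posteriors are drawn
with an affine-invariant ensemble sampler (emcee); approximate
leave-one-out cross-validation (PSIS-LOO via arviz) ranks the changepoint
model against linear and polynomial alternatives.

A separate similarity analysis computes Kendall rank correlations between
participants' (lambda, beta, tau) triples, averaged within and between age
groups, to quantify the convergence of learning strategies with age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kendalltau

logger = logging.getLogger(__name__)


class DiagnosticError(RuntimeError):
    """MCMC convergence diagnostics failed."""


@dataclass(frozen=True)
class ChangepointPriors:
    """Weakly informative priors; the data are log-parameter estimates."""

    b_scale: float = 5.0           # normal(0, b_scale) on b0, b1, b2
    sigma_scale: float = 2.5       # half-student-t(3, 0, sigma_scale) on sigma
    nu_shape: float = 2.0          # gamma(shape, rate) on the t dof
    nu_rate: float = 0.1
    intercept_sd_scale: float = 1.0  # half-normal on the experiment-intercept SD


@dataclass(frozen=True)
class McmcConfig:
    """Ensemble-sampler settings.  Walkers are split into 4 pseudo-chains
    for the R-hat diagnostic; ``strict`` turns diagnostic failure into an
    exception instead of a warning."""

    n_walkers: int = 32
    n_steps: int = 2500
    n_burn: int = 1000
    thin: int = 2
    rhat_threshold: float = 1.01
    strict: bool = False


DEFAULT_PRIORS = ChangepointPriors()
DEFAULT_MCMC = McmcConfig()


def hinge_mean(age: np.ndarray, b0: float, b1: float, b2: float,
               omega: float) -> np.ndarray:
    """Piecewise-linear predictor, continuous at the changepoint."""
    delta = np.asarray(age, dtype=float) - omega
    return b0 + np.where(delta <= 0, b1 * delta, b2 * delta)


def _student_t_loglike(resid: np.ndarray, sigma: float,
                       nu: float) -> np.ndarray:
    z2 = (resid / sigma) ** 2
    return (gammaln((nu + 1) / 2) - gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi) - np.log(sigma)
            - (nu + 1) / 2 * np.log1p(z2 / nu))


@dataclass
class ChangepointPosterior:
    """Posterior draws and diagnostics for the changepoint regression."""

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    loglike_draws: np.ndarray | None = None   # draws x observations
    predictor_range: tuple[float, float] = (0.0, 1.0)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            arr2 = np.atleast_2d(arr.T).T  # draws x dims
            for j in range(arr2.shape[1]):
                col = arr2[:, j]
                rows.append({
                    "parameter": name if arr2.shape[1] == 1 else f"{name}[{j}]",
                    "mean": col.mean(),
                    "ci_low": np.quantile(col, 0.025),
                    "ci_high": np.quantile(col, 0.975),
                    "rhat": self.rhat.get(name, np.nan),
                })
        return pd.DataFrame(rows)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        half = (1 - level) / 2
        col = self.draws[name]
        return float(np.quantile(col, half)), float(np.quantile(col, 1 - half))


def _run_ensemble(log_prob, p0: np.ndarray, mcmc: McmcConfig,
                  seed: int) -> np.ndarray:
    n_walkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    state = sampler.run_mcmc(p0, mcmc.n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.n_steps - mcmc.n_burn, progress=False)
    return sampler.get_chain(thin=mcmc.thin)  # steps x walkers x dim


def _split_rhat(chain: np.ndarray, names: list[str]) -> dict[str, float]:
    """R-hat treating groups of walkers as chains (arviz rank-normalized)."""
    walkers = chain.shape[1]
    groups = np.array_split(np.arange(walkers), 4)
    out = {}
    for j, name in enumerate(names):
        per_chain = np.stack([chain[:, g, j].T.reshape(-1) for g in groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = float(az.rhat(az.convert_to_dataset(per_chain))["x"].values)
    return out


def _check_diagnostics(rhat: dict[str, float], mcmc: McmcConfig,
                       label: str) -> None:
    bad = {k: v for k, v in rhat.items() if np.isfinite(v)
           and v >= mcmc.rhat_threshold}
    if bad:
        msg = f"{label}: R-hat above {mcmc.rhat_threshold}: {bad}"
        if mcmc.strict:
            raise DiagnosticError(msg)
        logger.warning(msg)


def fit_changepoint(ages, estimates, experiment_ids=None,
                    prior_cfg: ChangepointPriors = DEFAULT_PRIORS,
                    mcmc_cfg: McmcConfig = DEFAULT_MCMC,
                    seed: int = 0, log_transform: bool = True,
                    predictor_name: str = "age") -> ChangepointPosterior:
    """Fit the robust changepoint regression.

    ``estimates`` must be strictly positive when ``log_transform`` is on
    (the default): the model regresses log-estimates on age.  The
    changepoint prior is uniform over the observed age range.
    """
    ages = np.asarray(ages, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if ages.size != estimates.size:
        raise ValueError("ages and estimates must align")
    if ages.size < 20:
        raise ValueError("need at least 20 observations")
    if log_transform:
        if np.any(estimates <= 0):
            raise ValueError("estimates must be strictly positive to log-transform")
        y = np.log(estimates)
    else:
        y = estimates.copy()

    if experiment_ids is not None:
        exp_codes, exp_levels = pd.factorize(np.asarray(experiment_ids))
        n_exp = len(exp_levels)
    else:
        exp_codes, n_exp = None, 0

    age_lo, age_hi = float(ages.min()), float(ages.max())
    names = ["b0", "b1", "b2", "omega", "log_sigma", "log_nu"]
    names += [f"u{e}" for e in range(n_exp)] + (["log_sigma_u"] if n_exp else [])
    ndim = len(names)
    pr = prior_cfg

    def log_prob(theta: np.ndarray) -> float:
        b0, b1, b2, omega, log_sigma, log_nu = theta[:6]
        if not age_lo <= omega <= age_hi:
            return -np.inf
        if not (-15 < log_sigma < 10 and -5 < log_nu < 8):
            return -np.inf
        sigma, nu = np.exp(log_sigma), np.exp(log_nu)
        lp = -0.5 * (b0**2 + b1**2 + b2**2) / pr.b_scale**2
        # half-student-t(3) on sigma, with log-scale Jacobian
        lp += -2.0 * np.log1p(sigma**2 / (3 * pr.sigma_scale**2)) + log_sigma
        # gamma prior on nu, log-scale Jacobian
        lp += pr.nu_shape * log_nu - pr.nu_rate * nu
        mu = hinge_mean(ages, b0, b1, b2, omega)
        if n_exp:
            u = theta[6:6 + n_exp]
            log_sigma_u = theta[6 + n_exp]
            if not -15 < log_sigma_u < 5:
                return -np.inf
            sigma_u = np.exp(log_sigma_u)
            lp += (-0.5 * (u**2).sum() / sigma_u**2
                   - n_exp * log_sigma_u
                   - 0.5 * sigma_u**2 / pr.intercept_sd_scale**2 + log_sigma_u)
            mu = mu + u[exp_codes]
        lp += _student_t_loglike(y - mu, sigma, nu).sum()
        return float(lp)

    rng = np.random.default_rng(seed)
    p0 = np.empty((mcmc_cfg.n_walkers, ndim))
    p0[:, 0] = y.mean() + 0.1 * rng.standard_normal(mcmc_cfg.n_walkers)
    p0[:, 1] = 0.05 * rng.standard_normal(mcmc_cfg.n_walkers)
    p0[:, 2] = 0.05 * rng.standard_normal(mcmc_cfg.n_walkers)
    p0[:, 3] = rng.uniform(age_lo + 0.3 * (age_hi - age_lo),
                           age_lo + 0.7 * (age_hi - age_lo),
                           mcmc_cfg.n_walkers)
    p0[:, 4] = np.log(max(y.std(), 0.05)) + 0.1 * rng.standard_normal(
        mcmc_cfg.n_walkers)
    p0[:, 5] = np.log(10.0) + 0.2 * rng.standard_normal(mcmc_cfg.n_walkers)
    if n_exp:
        p0[:, 6:6 + n_exp] = 0.05 * rng.standard_normal(
            (mcmc_cfg.n_walkers, n_exp))
        p0[:, 6 + n_exp] = np.log(0.3) + 0.1 * rng.standard_normal(
            mcmc_cfg.n_walkers)

    chain = _run_ensemble(log_prob, p0, mcmc_cfg, seed)
    rhat = _split_rhat(chain, names)
    _check_diagnostics(rhat, mcmc_cfg, f"changepoint({predictor_name})")

    flat = chain.reshape(-1, ndim)
    draws = {
        "b0": flat[:, 0], "b1": flat[:, 1], "b2": flat[:, 2],
        "omega": flat[:, 3], "sigma": np.exp(flat[:, 4]),
        "nu": np.exp(flat[:, 5]),
    }
    if n_exp:
        draws["u"] = flat[:, 6:6 + n_exp]
        draws["sigma_u"] = np.exp(flat[:, 6 + n_exp])

    # pointwise log-likelihood on a thinned subset, for LOO
    sub = flat[:: max(1, len(flat) // 400)]
    ll = np.empty((len(sub), ages.size))
    for i, theta in enumerate(sub):
        mu = hinge_mean(ages, theta[0], theta[1], theta[2], theta[3])
        if n_exp:
            mu = mu + theta[6:6 + n_exp][exp_codes]
        ll[i] = _student_t_loglike(y - mu, np.exp(theta[4]), np.exp(theta[5]))
    return ChangepointPosterior(draws=draws, rhat=rhat, loglike_draws=ll,
                                predictor_range=(age_lo, age_hi))


# ---------------------------------------------------------------------------
# Model comparison against simpler regressions
# ---------------------------------------------------------------------------


def _design(ages: np.ndarray, kind: str) -> np.ndarray:
    z = (ages - ages.mean()) / max(ages.std(), 1e-9)
    if kind == "intercept":
        return np.ones((ages.size, 1))
    if kind == "linear":
        return np.column_stack([np.ones_like(z), z])
    if kind.startswith("poly"):
        degree = int(kind[4:])
        return np.column_stack([z**d for d in range(degree + 1)])
    raise ValueError(f"unknown regression design {kind!r}")


def _fit_linear_candidate(ages, y, exp_codes, n_exp, kind: str,
                          prior_cfg: ChangepointPriors,
                          mcmc_cfg: McmcConfig, seed: int) -> np.ndarray:
    """Posterior pointwise log-likelihood for a fixed-design candidate."""
    X = _design(ages, kind)
    p = X.shape[1]
    names = [f"b{j}" for j in range(p)] + ["log_sigma", "log_nu"]
    names += [f"u{e}" for e in range(n_exp)] + (["log_sigma_u"] if n_exp else [])
    ndim = len(names)
    pr = prior_cfg

    def log_prob(theta):
        b = theta[:p]
        log_sigma, log_nu = theta[p], theta[p + 1]
        if not (-15 < log_sigma < 10 and -5 < log_nu < 8):
            return -np.inf
        sigma, nu = np.exp(log_sigma), np.exp(log_nu)
        lp = -0.5 * (b**2).sum() / pr.b_scale**2
        lp += -2.0 * np.log1p(sigma**2 / (3 * pr.sigma_scale**2)) + log_sigma
        lp += pr.nu_shape * log_nu - pr.nu_rate * nu
        mu = X @ b
        if n_exp:
            u = theta[p + 2:p + 2 + n_exp]
            log_sigma_u = theta[p + 2 + n_exp]
            if not -15 < log_sigma_u < 5:
                return -np.inf
            sigma_u = np.exp(log_sigma_u)
            lp += (-0.5 * (u**2).sum() / sigma_u**2 - n_exp * log_sigma_u
                   - 0.5 * sigma_u**2 / pr.intercept_sd_scale**2 + log_sigma_u)
            mu = mu + u[exp_codes]
        lp += _student_t_loglike(y - mu, sigma, nu).sum()
        return float(lp)

    rng = np.random.default_rng(seed)
    p0 = 0.1 * rng.standard_normal((mcmc_cfg.n_walkers, ndim))
    p0[:, 0] += y.mean()
    p0[:, p] += np.log(max(y.std(), 0.05))
    p0[:, p + 1] += np.log(10.0)
    if n_exp:
        p0[:, p + 2 + n_exp] += np.log(0.3)
    chain = _run_ensemble(log_prob, p0, mcmc_cfg, seed)
    flat = chain.reshape(-1, ndim)
    sub = flat[:: max(1, len(flat) // 400)]
    ll = np.empty((len(sub), ages.size))
    for i, theta in enumerate(sub):
        mu = X @ theta[:p]
        if n_exp:
            mu = mu + theta[p + 2:p + 2 + n_exp][exp_codes]
        ll[i] = _student_t_loglike(y - mu, np.exp(theta[p]),
                                   np.exp(theta[p + 1]))
    return ll


def _loo_from_loglike(ll: np.ndarray):
    idata = az.from_dict(
        posterior={"dummy": ll[None, :, 0] * 0.0},
        log_likelihood={"y": ll[None, :, :]},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.loo(idata, pointwise=False)


def changepoint_model_comparison(
    ages, estimates, experiment_ids=None,
    prior_cfg: ChangepointPriors = DEFAULT_PRIORS,
    mcmc_cfg: McmcConfig = DEFAULT_MCMC,
    seed: int = 0,
    candidates: tuple[str, ...] = ("changepoint", "intercept", "linear",
                                   "poly2", "poly3", "poly4"),
) -> pd.DataFrame:
    """Rank regression candidates by approximate leave-one-out predictive fit.

    All candidates share the student-t likelihood and experiment intercepts;
    they differ only in the mean function.  Returns a table sorted by
    expected log predictive density (elpd_loo), best first.
    """
    ages = np.asarray(ages, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    y = np.log(estimates)
    if experiment_ids is not None:
        exp_codes, levels = pd.factorize(np.asarray(experiment_ids))
        n_exp = len(levels)
    else:
        exp_codes, n_exp = None, 0

    rows = []
    for i, kind in enumerate(candidates):
        if kind == "changepoint":
            post = fit_changepoint(ages, estimates, experiment_ids,
                                   prior_cfg, mcmc_cfg, seed=seed + i)
            ll = post.loglike_draws
        else:
            ll = _fit_linear_candidate(ages, y, exp_codes, n_exp, kind,
                                       prior_cfg, mcmc_cfg, seed=seed + i)
        loo = _loo_from_loglike(ll)
        rows.append({
            "model": kind,
            "elpd_loo": float(loo.elpd_loo),
            "se": float(loo.se),
            "p_loo": float(loo.p_loo),
            "warning": bool(loo.warning),
        })
    table = pd.DataFrame(rows).sort_values(
        "elpd_loo", ascending=False).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# Parameter similarity across age groups
# ---------------------------------------------------------------------------


def parameter_similarity(fit_table: pd.DataFrame,
                         group_order: tuple[str, ...] | None = None,
                         params: tuple[str, ...] = ("lambda", "beta", "tau"),
                         ) -> pd.DataFrame:
    """Age-group x age-group mean Kendall similarity of parameter triples.

    ``fit_table`` needs one row per participant with an ``age_group`` column
    and the three parameter columns.  For every pair of participants the
    Kendall rank correlation of their (lambda, beta, tau) vectors is
    computed; entries average these over all pairs of the two groups
    (within-group pairs on the diagonal, self-pairs excluded).
    """
    for col in ("age_group", *params):
        if col not in fit_table.columns:
            raise ValueError(f"fit table missing column {col!r}")
    groups = (list(group_order) if group_order is not None
              else list(pd.unique(fit_table["age_group"])))
    values = fit_table[list(params)].to_numpy(float)
    codes = fit_table["age_group"].map({g: i for i, g in enumerate(groups)})
    codes = codes.to_numpy()
    n = len(fit_table)
    sums = np.zeros((len(groups), len(groups)))
    counts = np.zeros((len(groups), len(groups)))
    for i in range(n):
        for j in range(i + 1, n):
            tau = kendalltau(values[i], values[j]).statistic
            if not np.isfinite(tau):
                tau = 0.0  # fully tied vectors carry no rank information
            a, b = codes[i], codes[j]
            sums[a, b] += tau
            counts[a, b] += 1
            if a != b:
                sums[b, a] += tau
                counts[b, a] += 1
    with np.errstate(invalid="ignore"):
        matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(matrix, index=groups, columns=groups)
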