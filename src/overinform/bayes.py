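"""Bayesian mixed-effects logistic regression via Hamiltonian Monte Carlo.

The model, for binary outcome ``y_i`` with fixed-effect row ``x_i`` and
subject ``j(i)``::

    y_i ~ Bernoulli(logistic(x_i' beta + u_{j(i)}))
    beta_k ~ Normal(0, prior_sd^2)          (prior_sd = 2 by default)
    u_j = sigma_u * z_j,  z_j ~ Normal(0, 1)
    sigma_u ~ HalfNormal(group_sd_prior)     (scale 1 by default)

The subject intercepts use the non-centred parameterisation and
``sigma_u`` is sampled on the log scale.  Sampling is plain HMC with a
diagonal mass matrix taken from the curvature at the posterior mode,
dual-averaging step-size adaptation during warm-up, and jittered path
lengths.  Convergence is checked with split R-hat; a fit whose worst
R-hat exceeds 1.05 raises :class:`ConvergenceError`.

Model comparison uses the Laplace approximation to the log marginal
likelihood at the posterior mode (documented as approximate; suitable
for coarse Bayes-factor comparisons, not for precise evidence claims).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "BayesMixedLogit",
    "BayesMixedLogitResults",
    "ConvergenceError",
    "laplace_log_marginal",
]


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics indicate non-convergence."""

    def __init__(self, rhat: pd.Series):
        self.rhat = rhat
        super().__init__(f"MCMC did not converge; worst R-hat = {rhat.max():.3f}")


def _split_rhat(chains: np.ndarray) -> float:
    """Split R-hat for draws of shape (n_chains, n_draws).

    Each chain is split in half and the classic potential-scale-reduction
    statistic is computed over the 2C half-chains.
    """
    chains = np.asarray(chains, dtype=float)
    n_half = chains.shape[1] // 2
    halves = np.concatenate(
        [chains[:, :n_half], chains[:, n_half: 2 * n_half]], axis=0
    )
    m, n = halves.shape
    means = halves.mean(axis=1)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * means.var(ddof=1)
    if within <= 0:
        return np.inf if between > 0 else 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


class _Posterior:
    """Log posterior and gradient for the mixed logistic model."""

    def __init__(self, y, X, groups, prior_sd, group_sd_prior):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.prior_var = float(prior_sd) ** 2
        self.group_scale = float(group_sd_prior)
        if groups is None:
            self.J = 0
            self.g = None
        else:
            codes, _ = pd.factorize(np.asarray(groups))
            self.g = codes
            self.J = int(codes.max()) + 1
        self.dim = self.p + self.J + (1 if self.J else 0)

    def unpack(self, theta):
        beta = theta[: self.p]
        if self.J:
            z = theta[self.p: self.p + self.J]
            tau = theta[-1]
        else:
            z, tau = None, None
        return beta, z, tau

    def eta(self, theta):
        beta, z, tau = self.unpack(theta)
        eta = self.X @ beta
        if self.J:
            eta = eta + np.exp(tau) * z[self.g]
        return eta

    def logp(self, theta):
        beta, z, tau = self.unpack(theta)
        eta = self.eta(theta)
        # Bernoulli log likelihood, numerically stable
        ll = np.sum(self.y * eta - np.logaddexp(0.0, eta))
        lp = ll - 0.5 * np.sum(beta ** 2) / self.prior_var \
            - 0.5 * self.p * np.log(2 * np.pi * self.prior_var)
        if self.J:
            sigma = np.exp(tau)
            lp -= 0.5 * np.sum(z ** 2) + 0.5 * self.J * np.log(2 * np.pi)
            # half-normal prior on sigma_u plus the log-scale Jacobian
            lp += (0.5 * np.log(2.0 / np.pi) - np.log(self.group_scale)
                   - 0.5 * (sigma / self.group_scale) ** 2 + tau)
        return lp

    def grad(self, theta):
        beta, z, tau = self.unpack(theta)
        eta = self.eta(theta)
        r = self.y - expit(eta)
        g = np.empty_like(theta)
        g[: self.p] = self.X.T @ r - beta / self.prior_var
        if self.J:
            sigma = np.exp(tau)
            gz = sigma * np.bincount(self.g, weights=r, minlength=self.J) - z
            g[self.p: self.p + self.J] = gz
            g[-1] = (sigma * np.sum(r * z[self.g])
                     - (sigma / self.group_scale) ** 2 + 1.0)
        return g

    def map_estimate(self):
        theta0 = np.zeros(self.dim)
        if self.J:
            theta0[-1] = np.log(0.5)  # start sigma_u at a moderate value
        res = optimize.minimize(
            lambda t: -self.logp(t), theta0, jac=lambda t: -self.grad(t),
            method="L-BFGS-B", options={"maxiter": 2000},
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-2:
            raise RuntimeError(f"posterior mode search failed: {res.message}")
        return res.x

    def hessian(self, theta, eps=1e-5):
        """Dense Hessian of the log posterior by central differences of the gradient."""
        d = self.dim
        H = np.empty((d, d))
        for k in range(d):
            dt = np.zeros(d)
            dt[k] = eps
            H[:, k] = (self.grad(theta + dt) - self.grad(theta - dt)) / (2 * eps)
        return 0.5 * (H + H.T)


def _hmc_chain(post, theta0, mass_diag, n_warmup, n_draws, L_range, rng,
               target_accept=0.8):
    """One HMC chain with dual-averaging step-size adaptation during warm-up."""
    inv_mass = 1.0 / mass_diag
    sqrt_mass = np.sqrt(mass_diag)
    theta = theta0.copy()
    logp = post.logp(theta)
    grad = post.grad(theta)

    # dual averaging (Nesterov) initialisation
    eps = 0.1 / post.dim ** 0.25
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_draws, post.dim))
    n_total = n_warmup + n_draws
    for it in range(n_total):
        p0 = rng.normal(size=post.dim) * sqrt_mass
        ke0 = 0.5 * np.sum(p0 ** 2 * inv_mass)
        th, p, gr = theta.copy(), p0.copy(), grad.copy()
        L = int(rng.integers(L_range[0], L_range[1] + 1))
        # leapfrog
        p = p + 0.5 * eps * gr
        for step in range(L):
            th = th + eps * inv_mass * p
            gr = post.grad(th)
            if step != L - 1:
                p = p + eps * gr
        p = p + 0.5 * eps * gr
        logp_new = post.logp(th)
        ke_new = 0.5 * np.sum(p ** 2 * inv_mass)
        log_alpha = (logp_new - ke_new) - (logp - ke0)
        alpha = min(1.0, float(np.exp(min(0.0, log_alpha)))) if np.isfinite(log_alpha) else 0.0
        if rng.random() < alpha:
            theta, logp, grad = th, logp_new, gr
        if it < n_warmup:
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta
    return draws


@dataclass
class BayesMixedLogitResults:
    """Posterior summaries of a fitted mixed logistic model.

    ``params`` are posterior means on the log-odds scale; ``bse`` are
    posterior standard deviations (reported as SE); ``conf_int`` gives
    central 95% credible intervals.
    """

    model: "BayesMixedLogit"
    draws: np.ndarray  # (chains, draws, dim)
    exog_names: list

    def __post_init__(self):
        p = len(self.exog_names)
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        self._beta = flat[:, :p]
        self.params = pd.Series(self._beta.mean(axis=0), index=self.exog_names)
        self.bse = pd.Series(self._beta.std(axis=0, ddof=1), index=self.exog_names)
        self.rhat = pd.Series(
            [_split_rhat(self.draws[:, :, k]) for k in range(p)], index=self.exog_names
        )
        if self.model._post.J:
            self.group_sd_draws = np.exp(flat[:, -1])
            self.group_sd = float(self.group_sd_draws.mean())
        else:
            self.group_sd_draws = None
            self.group_sd = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo = np.percentile(self._beta, 100 * alpha / 2, axis=0)
        hi = np.percentile(self._beta, 100 * (1 - alpha / 2), axis=0)
        return pd.DataFrame({"LL": lo, "UL": hi}, index=self.exog_names)

    def beta_draws(self) -> pd.DataFrame:
        return pd.DataFrame(self._beta, columns=self.exog_names)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "Effect": self.exog_names,
            "beta": self.params.values,
            "SE": self.bse.values,
            "LL": ci["LL"].values,
            "UL": ci["UL"].values,
            "rhat": self.rhat.values,
        })

    def summary(self) -> str:
        lines = ["Bayesian mixed-effects logistic regression",
                 f"  observations: {self.model._post.n}"]
        if self.model._post.J:
            lines.append(f"  groups: {self.model._post.J}  "
                         f"(posterior mean intercept SD = {self.group_sd:.3f})")
        lines.append(f"{'Effect':<22}{'beta':>8}{'SE':>8}{'LL':>8}{'UL':>8}{'R-hat':>8}")
        ci = self.conf_int()
        for name in self.exog_names:
            lines.append(
                f"{name:<22}{self.params[name]:>8.2f}{self.bse[name]:>8.2f}"
                f"{ci.loc[name, 'LL']:>8.2f}{ci.loc[name, 'UL']:>8.2f}"
                f"{self.rhat[name]:>8.3f}"
            )
        return "\n".join(lines)


class BayesMixedLogit:
    """Bayesian logistic regression with optional by-group random intercepts.

    Parameters
    ----------
    endog : array of 0/1 responses
    exog : (n, p) fixed-effects design matrix (include the intercept column)
    groups : length-n group labels for by-subject intercepts, or None
    exog_names : column names for reporting
    prior_sd : SD of the Normal(0, prior_sd) coefficient priors
    group_sd_prior : scale of the half-Normal prior on the intercept SD
    """

    def __init__(self, endog, exog, groups=None, exog_names: Optional[Sequence[str]] = None,
                 prior_sd: float = 2.0, group_sd_prior: float = 1.0):
        endog = np.asarray(endog, dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if set(np.unique(endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(endog)) < 2:
            raise ValueError("need both response classes present to fit")
        self._post = _Posterior(endog, exog, groups, prior_sd, group_sd_prior)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{k}" for k in range(exog.shape[1])]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       effects: Sequence[str], group: Optional[str] = None,
                       **kwargs) -> "BayesMixedLogit":
        """Build from a coded dataframe: intercept + named dummy/contrast columns."""
        X = np.column_stack([np.ones(len(data))] +
                            [data[c].to_numpy(dtype=float) for c in effects])
        names = ["intercept"] + list(effects)
        groups = data[group].to_numpy() if group is not None else None
        return cls(data[response].to_numpy(dtype=float), X, groups=groups,
                   exog_names=names, **kwargs)

    def map_laplace(self):
        """Posterior mode, mode curvature, and Laplace log marginal likelihood."""
        mode = self._post.map_estimate()
        H = self._post.hessian(mode)
        sign, logdet = np.linalg.slogdet(-H)
        if sign <= 0:
            raise RuntimeError("Hessian at the mode is not negative definite")
        d = self._post.dim
        log_ml = self._post.logp(mode) + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
        return mode, H, float(log_ml)

    def fit(self, chains: int = 4, draws: int = 1000, warmup: int = 500,
            seed: Optional[int] = None, path_lengths: tuple[int, int] = (8, 24),
            check_convergence: bool = True, rhat_limit: float = 1.05,
            ) -> BayesMixedLogitResults:
        """Sample the posterior with HMC and return a results object."""
        rng = np.random.default_rng(seed)
        mode = self._post.map_estimate()
        # diagonal mass from the curvature at the mode (clipped for safety)
        H = self._post.hessian(mode)
        mass = np.clip(-np.diag(H), 1e-3, None)
        all_draws = np.empty((chains, draws, self._post.dim))
        for c in range(chains):
            theta0 = mode + rng.normal(scale=0.5 / np.sqrt(mass))
            all_draws[c] = _hmc_chain(self._post, theta0, mass, warmup, draws,
                                      path_lengths, rng)
        results = BayesMixedLogitResults(model=self, draws=all_draws,
                                         exog_names=self.exog_names)
        if check_convergence and (results.rhat > rhat_limit).any():
            raise ConvergenceError(results.rhat)
        return results


def laplace_log_marginal(model: BayesMixedLogit) -> float:
    """Laplace-approximate log marginal likelihood of a model."""
    return model.map_laplace()[2]
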