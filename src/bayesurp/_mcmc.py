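"""Gradient-based MCMC for the package's two hierarchical model families.

Implements the No-U-Turn sampler (dynamic Hamiltonian Monte Carlo with
dual-averaging step-size adaptation and a diagonal mass matrix) together with
a :class:`HierarchicalGLM` log-density that covers

* Bernoulli mixed-effects logistic regression with grouped random effects
  (the staged word-order models, random intercepts by genre), and
* Gaussian linear mixed models with correlated grouped random effects
  (the reading-time analyses, by-participant intercepts and slopes with an
  LKJ prior on the random-effect correlation matrix).

All gradients are analytic.  Random-effect vectors use the non-centered
parameterization b_g = diag(tau) * L * z_g with z_g ~ N(0, I); the Cholesky
factor L of the correlation matrix is parameterized by canonical partial
correlations via tanh, with the LKJ density and transform Jacobian folded
into the target.  Scale parameters are sampled on the log scale.

The sampler is deliberately small but standard; tests validate it against
closed-form conjugate posteriors and maximum-likelihood fits from
statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from scipy import optimize
from scipy.special import expit

logger = logging.getLogger("bayesurp.mcmc")

__all__ = ["HierarchicalGLM", "NutsConfig", "sample_nuts", "fit_map"]


# ---------------------------------------------------------------------------
# scalar prior helpers (log densities up to constants, with gradients)

def _t_logp_grad(x: np.ndarray, df: float, loc: float, scale: float):
    """Student-t log density (unnormalized) and gradient; df=inf gives normal."""
    d = x - loc
    if not np.isfinite(df):
        return -0.5 * np.sum((d / scale) ** 2), -d / scale**2
    q = df * scale**2 + d * d
    logp = -0.5 * (df + 1.0) * np.sum(np.log1p(d * d / (df * scale**2)))
    return logp, -(df + 1.0) * d / q


def _half_cauchy_logscale(log_s: np.ndarray, scale: float):
    """Half-Cauchy(0, scale) density for s = exp(log_s), including the
    log-scale Jacobian.  Returns (logp, dlogp/dlog_s)."""
    s2 = np.exp(2.0 * np.minimum(log_s, 170.0))
    logp = np.sum(-np.log1p(s2 / scale**2) + log_s)
    grad = 1.0 - 2.0 * s2 / (scale**2 + s2)
    return logp, grad


def _half_t_logscale(log_s: np.ndarray, df: float, scale: float):
    """Half-Student-t(df, 0, scale) for s = exp(log_s), with Jacobian."""
    s2 = np.exp(2.0 * np.minimum(log_s, 170.0))
    logp = np.sum(-0.5 * (df + 1.0) * np.log1p(s2 / (df * scale**2)) + log_s)
    grad = 1.0 - (df + 1.0) * s2 / (df * scale**2 + s2)
    return logp, grad


# ---------------------------------------------------------------------------
# LKJ / Cholesky-of-correlation via canonical partial correlations

def cpc_to_cholesky(z: np.ndarray, k: int) -> np.ndarray:
    """Build the lower Cholesky factor of a correlation matrix from canonical
    partial correlations z in (-1, 1), row-major lower-triangle order."""
    L = np.zeros((k, k))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, k):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[pos] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            pos += 1
        L[i, i] = np.sqrt(max(rem, 1e-16))
    return L


def _cholesky_backprop(z: np.ndarray, L: np.ndarray, dL: np.ndarray, k: int) -> np.ndarray:
    """Adjoint of cpc_to_cholesky: map dlogp/dL to dlogp/dz."""
    dz = np.zeros_like(z)
    pos = 0
    for i in range(1, k):
        row_z = z[pos:pos + i]
        # prods[j] = prod_{m<j} sqrt(1 - z_m^2); L[i,j] = z_j * prods[j]
        prods = np.ones(i + 1)
        for j in range(i):
            prods[j + 1] = prods[j] * np.sqrt(1.0 - row_z[j] ** 2)
        # suffix[j] = sum_{m=j+1..i} dL[i,m] * L[i,m]
        contrib = dL[i, : i + 1] * L[i, : i + 1]
        suffix = np.concatenate([np.cumsum(contrib[::-1])[::-1], [0.0]])
        for j in range(i):
            dz[pos + j] = (dL[i, j] * prods[j]
                           - row_z[j] / (1.0 - row_z[j] ** 2) * suffix[j + 1])
        pos += i
    return dz


def _lkj_cpc_prior(y: np.ndarray, k: int, eta: float = 1.0):
    """Log density over unconstrained CPC parameters y implied by an
    LKJ(eta) prior on the correlation matrix, including all transform
    Jacobians (tanh and CPC->correlation).  For eta=1 this makes the induced
    correlation matrix uniform.  Returns (logp, grad, z=tanh(y))."""
    z = np.clip(np.tanh(y), -1.0 + 1e-12, 1.0 - 1e-12)
    # coefficient of log(1 - z^2) depends only on the (0-based) column index
    cols = np.concatenate([np.arange(i) for i in range(1, k)]) if k > 1 else np.array([])
    c = 1.0 + 0.5 * (k - 2 - cols)
    logp = float(np.sum(c * np.log1p(-z * z)))
    grad = -2.0 * c * z
    if eta != 1.0:
        # det(Sigma)^(eta-1) term handled by caller through dL adjoint
        pass
    return logp, grad, z


# ---------------------------------------------------------------------------
# the model

@dataclass
class HierarchicalGLM:
    """Log posterior (with gradient) for a GLM with one grouping factor.

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix.
    y : (n,) response; {0,1} for ``family="bernoulli"``, real for "gaussian".
    group : (n,) integer group index in [0, n_groups).
    Z : (n, k) random-effects design (defaults to an all-ones column:
        random intercepts only).
    prior_loc, prior_scale, prior_df : per-column fixed-effect prior
        (Student-t; df=inf for normal).
    re_scale : scale of the half-Cauchy prior on random-effect sds.
    lkj_eta : shape of the LKJ prior on the random-effect correlations.
    sigma_df, sigma_scale : half-Student-t prior on the residual sd
        (gaussian family only).

    Parameter vector layout:
    [beta (p), z_raw (G*k), log_tau (k), cpc (k(k-1)/2), log_sigma (gaussian)]
    """

    X: np.ndarray
    y: np.ndarray
    group: np.ndarray
    family: str = "bernoulli"
    Z: np.ndarray | None = None
    prior_loc: np.ndarray | None = None
    prior_scale: np.ndarray | None = None
    prior_df: np.ndarray | None = None
    re_scale: float = 2.0
    lkj_eta: float = 1.0
    sigma_df: float = 3.0
    sigma_scale: float = 10.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.group = np.asarray(self.group, dtype=np.intp)
        n, p = self.X.shape
        if self.Z is None:
            self.Z = np.ones((n, 1))
        self.Z = np.asarray(self.Z, dtype=float)
        self.n_groups = int(self.group.max()) + 1 if n else 0
        self.k = self.Z.shape[1]
        if self.prior_loc is None:
            self.prior_loc = np.zeros(p)
        if self.prior_scale is None:
            self.prior_scale = np.full(p, 5.0)
        if self.prior_df is None:
            self.prior_df = np.full(p, np.inf)
        self.prior_loc = np.asarray(self.prior_loc, dtype=float)
        self.prior_scale = np.asarray(self.prior_scale, dtype=float)
        self.prior_df = np.asarray(self.prior_df, dtype=float)
        if self.family not in ("bernoulli", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")

    # ---- layout -----------------------------------------------------------
    @property
    def n_cpc(self) -> int:
        return self.k * (self.k - 1) // 2

    @property
    def dim(self) -> int:
        p = self.X.shape[1]
        d = p + self.n_groups * self.k + self.k + self.n_cpc
        if self.family == "gaussian":
            d += 1
        return d

    def param_names(self) -> list[str]:
        p = self.X.shape[1]
        names = [f"beta[{j}]" for j in range(p)]
        names += [f"z[{g},{m}]" for g in range(self.n_groups) for m in range(self.k)]
        names += [f"log_tau[{m}]" for m in range(self.k)]
        names += [f"cpc[{m}]" for m in range(self.n_cpc)]
        if self.family == "gaussian":
            names += ["log_sigma"]
        return names

    def initial_point(self, rng: np.random.Generator | None = None) -> np.ndarray:
        theta = np.zeros(self.dim)
        p = self.X.shape[1]
        theta[:p] = self.prior_loc
        sl_tau = slice(p + self.n_groups * self.k, p + self.n_groups * self.k + self.k)
        theta[sl_tau] = np.log(0.3)
        if self.family == "gaussian":
            sd = float(np.std(self.y)) or 1.0
            theta[-1] = np.log(sd)
        if rng is not None:
            theta = theta + 0.1 * rng.standard_normal(self.dim)
        return theta

    # ---- density ----------------------------------------------------------
    def unpack(self, theta: np.ndarray):
        p = self.X.shape[1]
        G, k = self.n_groups, self.k
        beta = theta[:p]
        z_raw = theta[p:p + G * k].reshape(G, k)
        log_tau = theta[p + G * k: p + G * k + k]
        cpc_y = theta[p + G * k + k: p + G * k + k + self.n_cpc]
        log_sigma = theta[-1] if self.family == "gaussian" else None
        return beta, z_raw, log_tau, cpc_y, log_sigma

    def random_effects(self, theta: np.ndarray) -> np.ndarray:
        """Per-group effect matrix b (G, k) implied by a parameter vector."""
        _, z_raw, log_tau, cpc_y, _ = self.unpack(theta)
        tau = np.exp(log_tau)
        if self.k > 1:
            L = cpc_to_cholesky(
                np.clip(np.tanh(cpc_y), -1.0 + 1e-12, 1.0 - 1e-12), self.k)
            A = tau[:, None] * L
        else:
            A = tau.reshape(1, 1)
        return z_raw @ A.T

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        beta = self.unpack(theta)[0]
        b = self.random_effects(theta)
        return self.X @ beta + np.sum(self.Z * b[self.group], axis=1)

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.X.shape[1]
        G, k = self.n_groups, self.k
        beta, z_raw, log_tau, cpc_y, log_sigma = self.unpack(theta)
        tau = np.exp(np.minimum(log_tau, 170.0))

        if k > 1:
            lkj_logp, d_cpc_prior, z_cpc = _lkj_cpc_prior(cpc_y, k, self.lkj_eta)
            L = cpc_to_cholesky(z_cpc, k)
        else:
            lkj_logp, d_cpc_prior, z_cpc, L = 0.0, np.zeros(0), np.zeros(0), np.ones((1, 1))

        A = tau[:, None] * L                     # (k, k)
        b = z_raw @ A.T                          # (G, k) group effects
        eta = self.X @ beta + np.sum(self.Z * b[self.group], axis=1)

        # likelihood
        if self.family == "bernoulli":
            loglik = float(np.sum(self.y * eta) - np.sum(np.logaddexp(0.0, eta)))
            g_eta = self.y - expit(eta)
            d_lsigma = None
        else:
            sigma2 = np.exp(2.0 * float(np.clip(log_sigma, -170.0, 170.0)))
            r = self.y - eta
            loglik = float(-len(self.y) * log_sigma - 0.5 * np.sum(r * r) / sigma2)
            g_eta = r / sigma2
            d_lsigma = -float(len(self.y)) + float(np.sum(r * r) / sigma2)

        # chain rule
        g_beta = self.X.T @ g_eta
        G_b = np.zeros((G, k))
        np.add.at(G_b, self.group, self.Z * g_eta[:, None])
        g_zraw = G_b @ A
        g_A = G_b.T @ z_raw                      # (k, k)
        g_tau = np.sum(g_A * L, axis=1)
        g_log_tau = g_tau * tau

        # priors
        lp_beta, g_pb = 0.0, np.zeros(p)
        for j in range(p):
            lp_j, g_j = _t_logp_grad(beta[j:j + 1], self.prior_df[j],
                                     self.prior_loc[j], self.prior_scale[j])
            lp_beta += lp_j
            g_pb[j] = g_j[0]
        lp_z = -0.5 * float(np.sum(z_raw * z_raw))
        g_zraw = g_zraw - z_raw
        lp_tau, g_ptau = _half_cauchy_logscale(log_tau, self.re_scale)
        g_log_tau = g_log_tau + g_ptau

        logp = loglik + lp_beta + lp_z + lp_tau + lkj_logp
        grad = np.empty(self.dim)
        grad[:p] = g_beta + g_pb
        grad[p:p + G * k] = g_zraw.ravel()
        grad[p + G * k:p + G * k + k] = g_log_tau

        if k > 1:
            dL = g_A * tau[:, None]
            if self.lkj_eta != 1.0:
                di = np.diag_indices(k)
                dL = dL.copy()
                dL[di] += 2.0 * (self.lkj_eta - 1.0) / np.diag(L)
                logp += 2.0 * (self.lkj_eta - 1.0) * float(np.sum(np.log(np.diag(L))))
            d_zcpc = _cholesky_backprop(z_cpc, L, dL, k)
            grad[p + G * k + k:p + G * k + k + self.n_cpc] = (
                d_zcpc * (1.0 - z_cpc ** 2) + d_cpc_prior)

        if self.family == "gaussian":
            lp_s, g_ps = _half_t_logscale(np.asarray([log_sigma]),
                                          self.sigma_df, self.sigma_scale)
            logp += lp_s
            grad[-1] = d_lsigma + g_ps[0]

        return logp, grad


# ---------------------------------------------------------------------------
# NUTS

@dataclass
class NutsConfig:
    n_warmup: int = 500
    n_samples: int = 500
    n_chains: int = 4
    target_accept: float = 0.8
    max_treedepth: int = 10
    seed: int = 0


@dataclass
class SamplerStats:
    divergences: int = 0
    stepsizes: list[float] = field(default_factory=list)
    mean_accept: list[float] = field(default_factory=list)


def _leapfrog(grad_fn, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = grad_fn(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _find_reasonable_epsilon(grad_fn, theta, inv_mass, rng):
    eps = 1.0
    logp0, grad0 = grad_fn(theta)
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * float(np.sum(inv_mass * r0 * r0))
    _, r1, logp1, _ = _leapfrog(grad_fn, theta, r0, grad0, eps, inv_mass)
    h1 = logp1 - 0.5 * float(np.sum(inv_mass * r1 * r1))
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(grad_fn, theta, r0, grad0, eps, inv_mass)
        h1 = logp1 - 0.5 * float(np.sum(inv_mass * r1 * r1))
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-8)


class _Tree:
    __slots__ = ("theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
                 "theta_prime", "logp_prime", "grad_prime", "n", "stop",
                 "alpha", "n_alpha")


def _build_tree(grad_fn, theta, r, grad, log_u, v, depth, eps, inv_mass,
                h0, state):
    """Recursive doubling for NUTS (slice-sampling variant)."""
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(grad_fn, theta, r, grad, v * eps, inv_mass)
        h1 = logp1 - 0.5 * float(np.sum(inv_mass * r1 * r1))
        if not np.isfinite(h1):
            h1 = -np.inf
        t = _Tree()
        t.theta_m = t.theta_p = t.theta_prime = theta1
        t.r_m = t.r_p = r1
        t.grad_m = t.grad_p = t.grad_prime = grad1
        t.logp_prime = logp1
        t.n = int(log_u <= h1)
        t.stop = (log_u - 1000.0) >= h1
        if t.stop and (h0 - h1) > 1000.0:
            state["divergent"] = True
        t.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        t.n_alpha = 1
        return t

    t = _build_tree(grad_fn, theta, r, grad, log_u, v, depth - 1, eps, inv_mass, h0, state)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(grad_fn, t.theta_m, t.r_m, t.grad_m, log_u, v,
                             depth - 1, eps, inv_mass, h0, state)
            t.theta_m, t.r_m, t.grad_m = t2.theta_m, t2.r_m, t2.grad_m
        else:
            t2 = _build_tree(grad_fn, t.theta_p, t.r_p, t.grad_p, log_u, v,
                             depth - 1, eps, inv_mass, h0, state)
            t.theta_p, t.r_p, t.grad_p = t2.theta_p, t2.r_p, t2.grad_p
        total = t.n + t2.n
        if total > 0 and state["rng"].random() < t2.n / total:
            t.theta_prime, t.logp_prime, t.grad_prime = (
                t2.theta_prime, t2.logp_prime, t2.grad_prime)
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n = total
        dtheta = t.theta_p - t.theta_m
        t.stop = (t2.stop
                  or float(dtheta @ (inv_mass * t.r_m)) < 0
                  or float(dtheta @ (inv_mass * t.r_p)) < 0)
    return t


def _nuts_chain(grad_fn, theta0, n_warmup, n_samples, rng, target_accept,
                max_treedepth, stats):
    dim = theta0.size
    inv_mass = np.ones(dim)
    theta = np.asarray(theta0, dtype=float)
    logp, grad = grad_fn(theta)

    eps = _find_reasonable_epsilon(grad_fn, theta, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # warmup schedule: [step-size | metric-collection | step-size re-adapt]
    w1 = max(int(0.4 * n_warmup), 10)
    w2 = max(int(0.8 * n_warmup), w1 + 10)
    metric_draws: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    accepts = []
    divergences = 0

    for it in range(n_warmup + n_samples):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float(np.sum(inv_mass * r0 * r0))
        log_u = h0 + np.log(rng.random())
        state = {"rng": rng, "divergent": False}

        theta_m = theta_p = theta
        r_m = r_p = r0
        grad_m = grad_p = grad
        theta_new, logp_new, grad_new = theta, logp, grad
        n = 1
        depth = 0
        alpha_sum, n_alpha = 0.0, 0
        stop = False
        while not stop and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(grad_fn, theta_m, r_m, grad_m, log_u, v, depth,
                                eps, inv_mass, h0, state)
                theta_m, r_m, grad_m = t.theta_m, t.r_m, t.grad_m
            else:
                t = _build_tree(grad_fn, theta_p, r_p, grad_p, log_u, v, depth,
                                eps, inv_mass, h0, state)
                theta_p, r_p, grad_p = t.theta_p, t.r_p, t.grad_p
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n):
                theta_new, logp_new, grad_new = t.theta_prime, t.logp_prime, t.grad_prime
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            n += t.n
            dtheta = theta_p - theta_m
            stop = (t.stop
                    or float(dtheta @ (inv_mass * r_m)) < 0
                    or float(dtheta @ (inv_mass * r_p)) < 0)
            depth += 1

        theta, logp, grad = theta_new, logp_new, grad_new
        if state["divergent"] and it >= n_warmup:
            divergences += 1
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            power = adapt_count ** (-kappa)
            log_eps_bar = power * log_eps + (1.0 - power) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                metric_draws.append(theta.copy())
            if it == w2 - 1 and len(metric_draws) >= 10:
                var = np.var(np.asarray(metric_draws), axis=0)
                n_m = len(metric_draws)
                # regularized like Stan's diagonal metric update
                var = (n_m / (n_m + 5.0)) * var + 1e-3 * (5.0 / (n_m + 5.0))
                inv_mass = np.maximum(var, 1e-8)
                eps = _find_reasonable_epsilon(grad_fn, theta, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta
            accepts.append(accept_stat)

    stats.divergences += divergences
    stats.stepsizes.append(eps)
    stats.mean_accept.append(float(np.mean(accepts)) if accepts else float("nan"))
    return draws


def sample_nuts(model, config: NutsConfig,
                init: np.ndarray | None = None) -> tuple[np.ndarray, SamplerStats]:
    """Run NUTS; returns draws of shape (n_chains, n_samples, dim) and stats.

    Deterministic given the config seed: chain RNGs are spawned from a
    ``SeedSequence`` so results are reproducible and chain-order independent.
    """
    grad_fn = model.logp_and_grad
    stats = SamplerStats()
    seq = np.random.SeedSequence(config.seed)
    chains = []
    for child in seq.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        theta0 = model.initial_point(rng) if init is None else np.asarray(init, float)
        draws = _nuts_chain(grad_fn, theta0, config.n_warmup, config.n_samples,
                            rng, config.target_accept, config.max_treedepth, stats)
        chains.append(draws)
    if stats.divergences:
        logger.warning("NUTS reported %d divergent transitions", stats.divergences)
    return np.asarray(chains), stats


# ---------------------------------------------------------------------------
# penalized-MAP / Laplace fast path (approximation, used for quick checks)

def fit_map(model, x0: np.ndarray | None = None,
            laplace_draws: int = 0, seed: int = 0):
    """Posterior mode via L-BFGS on the exact log density; optionally returns
    draws from the Laplace (Gaussian) approximation around the mode.

    This is an approximation to the full posterior and is exposed for fast
    smoke-testing; the reference path is :func:`sample_nuts`.
    """
    x0 = model.initial_point() if x0 is None else np.asarray(x0, float)

    def negative(theta):
        logp, grad = model.logp_and_grad(theta)
        return -logp, -grad

    res = optimize.minimize(negative, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000})
    mode = res.x
    if laplace_draws <= 0:
        return mode, None
    hess = _numerical_hessian(model, mode)
    # symmetrize and regularize
    hess = 0.5 * (hess + hess.T)
    w, v = np.linalg.eigh(hess)
    w = np.maximum(w, 1e-8)
    cov = (v / w) @ v.T
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mode, cov, size=laplace_draws,
                                    method="cholesky" if mode.size < 500 else "svd")
    return mode, draws


def _numerical_hessian(model, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    dim = theta.size
    hess = np.empty((dim, dim))
    for j in range(dim):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        gp = model.logp_and_grad(tp)[1]
        gm = model.logp_and_grad(tm)[1]
        hess[:, j] = -(gp - gm) / (2.0 * h)
    return hess
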