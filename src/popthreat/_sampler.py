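"""Collapsed MCMC for the hierarchical Gaussian trend model.

The model is conditionally Gaussian: given the scale hyperparameters
(observation sigma, the three random-slope sigmas) and the AR(1) coefficient
rho, the fixed effects beta and all noncentered random-slope variables z have
standard-normal priors and enter the mean linearly.  The sampler exploits
this:

1. the Gaussian coefficient block is integrated out analytically (matrix
   determinant lemma / Woodbury), leaving a 4-5 dimensional marginal
   posterior over (sigma, sigma_S, sigma_P, sigma_L[, rho]);
2. that marginal is sampled with an adaptive random-walk Metropolis chain
   (Haario covariance adaptation plus Robbins-Monro step-size tuning during
   warmup, frozen afterwards);
3. at every retained iteration the coefficients are drawn from their *exact*
   Gaussian conditional given the current hyperparameters.

The composition (marginal Metropolis then exact conditional) yields draws
from the joint posterior; no gradient information or approximation of the
coefficient block is involved.

AR(1) residuals are handled by whitening: with observations sorted by series
and year, u_t = r_t - rho * r_{t-1} within a series (u_1 = r_1) is iid
Normal(0, sigma), so the whitening operator is unit-lower-bidiagonal per
series and costs O(n) to apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

RHO_PRIOR_SD = 0.25
TARGET_ACCEPT = 0.30


@dataclass
class CollapsedProblem:
    """Precomputed quantities shared by every likelihood evaluation.

    ``base`` holds the unscaled regressor matrix ``[X | t*Z_S | t*Z_P |
    t*Z_L L_Sigma]``; block scales (1, sigma_S, sigma_P, sigma_L) are applied
    per evaluation.  ``lag_mask`` flags observations that have a predecessor
    within their series (everything but the first point of each series).
    """

    y: np.ndarray                 # (n,) centered response
    base: np.ndarray              # (n, p) unscaled regressors
    block_slices: tuple[slice, slice, slice, slice]  # fixed, species, pop, site
    lag_mask: np.ndarray          # (n,) bool, True where a lagged residual exists
    ar1_enabled: bool = True

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_coef(self) -> int:
        return self.base.shape[1]

    def whiten(self, arr: np.ndarray, rho: float) -> np.ndarray:
        """Apply the per-series AR(1) whitening operator along axis 0."""
        out = arr.copy()
        if rho != 0.0:
            m = self.lag_mask
            if arr.ndim == 1:
                out[m] -= rho * arr[np.flatnonzero(m) - 1]
            else:
                out[m] -= rho * arr[np.flatnonzero(m) - 1, :]
        return out

    def scale_vector(self, sig_s: float, sig_p: float, sig_l: float) -> np.ndarray:
        s = np.ones(self.n_coef)
        _, sl_s, sl_p, sl_l = self.block_slices
        s[sl_s] = sig_s
        s[sl_p] = sig_p
        s[sl_l] = sig_l
        return s


@dataclass
class _State:
    """Cached factorization at one hyperparameter point."""

    x: np.ndarray                 # unconstrained vector
    log_post: float
    sigma: float
    chol_m: np.ndarray            # Cholesky factor of M = sigma^2 I + G_s
    mean_c: np.ndarray            # conditional posterior mean of coefficients


def _unpack(x: np.ndarray, ar1: bool) -> tuple[float, float, float, float, float]:
    sig, sig_s, sig_p, sig_l = np.exp(x[:4])
    rho = float(x[4]) if ar1 else 0.0
    return float(sig), float(sig_s), float(sig_p), float(sig_l), rho


def _log_prior_unconstrained(x: np.ndarray, ar1: bool) -> float:
    # Exponential(1) priors on the four sigmas, with log-Jacobian of exp;
    # Normal(0, RHO_PRIOR_SD) on rho (sampled on its natural scale).
    sigmas = np.exp(x[:4])
    lp = float(np.sum(-sigmas + x[:4]))
    if ar1:
        lp += -0.5 * (x[4] / RHO_PRIOR_SD) ** 2
    return lp


def evaluate(problem: CollapsedProblem, x: np.ndarray) -> _State:
    """Marginal log posterior and conditional-Gaussian factorization at x."""
    ar1 = problem.ar1_enabled
    sig, sig_s, sig_p, sig_l, rho = _unpack(x, ar1)
    n, p = problem.n_obs, problem.n_coef

    bt = problem.whiten(problem.base, rho)
    yt = problem.whiten(problem.y, rho)
    s = problem.scale_vector(sig_s, sig_p, sig_l)

    g = bt.T @ bt
    g *= np.outer(s, s)
    b = s * (bt.T @ yt)
    yty = float(yt @ yt)

    m = g + (sig ** 2) * np.eye(p)
    chol = np.linalg.cholesky(m)
    half = solve_triangular(chol, b, lower=True)
    quad = (yty - float(half @ half)) / sig ** 2
    logdet_m = 2.0 * float(np.sum(np.log(np.diag(chol))))
    log_marg = (
        -0.5 * n * np.log(2.0 * np.pi)
        - (n - p) * np.log(sig)
        - 0.5 * logdet_m
        - 0.5 * quad
    )
    mean_c = cho_solve((chol, True), b)
    return _State(
        x=x.copy(),
        log_post=log_marg + _log_prior_unconstrained(x, ar1),
        sigma=sig,
        chol_m=chol,
        mean_c=mean_c,
    )


def _draw_coefficients(state: _State, rng: np.random.Generator) -> np.ndarray:
    # c | theta, y  ~  N(M^-1 b, sigma^2 M^-1)
    xi = rng.standard_normal(state.mean_c.size)
    return state.mean_c + state.sigma * solve_triangular(
        state.chol_m, xi, lower=True, trans="T"
    )


def run_chain(
    problem: CollapsedProblem,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
    init_x: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """One adaptive Metropolis chain; returns post-warmup draws."""
    ar1 = problem.ar1_enabled
    dim = 5 if ar1 else 4

    if init_x is None:
        y_sd = max(float(np.std(problem.y)), 1e-3)
        init_x = np.array([np.log(0.5 * y_sd), *np.log([0.05, 0.05, 0.05])])
        if ar1:
            init_x = np.append(init_x, 0.0)
        init_x = init_x + 0.1 * rng.standard_normal(dim)

    state = evaluate(problem, init_x)
    log_step = np.log(0.2)
    mean_hist = state.x.copy()
    cov_hist = 0.01 * np.eye(dim)
    chol_prop = np.linalg.cholesky(cov_hist)

    keep = iterations - warmup
    hyper = np.empty((keep, dim))
    coefs = np.empty((keep, problem.n_coef))
    accepts = 0

    for it in range(iterations):
        proposal = state.x + np.exp(log_step) * (chol_prop @ rng.standard_normal(dim))
        try:
            cand = evaluate(problem, proposal)
            log_alpha = cand.log_post - state.log_post
        except np.linalg.LinAlgError:
            log_alpha = -np.inf
            cand = None
        accepted = np.log(rng.random()) < log_alpha
        if accepted and cand is not None:
            state = cand
            accepts += 1

        if it < warmup:
            # Robbins-Monro scale tuning toward the target acceptance rate,
            # Haario empirical-covariance proposal after a short burn-in.
            eta = (it + 1) ** -0.6
            log_step += eta * ((1.0 if accepted else 0.0) - TARGET_ACCEPT)
            delta = state.x - mean_hist
            mean_hist += delta / (it + 2)
            cov_hist += (np.outer(delta, state.x - mean_hist) - cov_hist) / (it + 2)
            if it >= 50 and (it % 25 == 0):
                prop_cov = (2.38 ** 2 / dim) * (cov_hist + 1e-8 * np.eye(dim))
                chol_prop = np.linalg.cholesky(prop_cov)
        else:
            j = it - warmup
            hyper[j] = state.x
            coefs[j] = _draw_coefficients(state, rng)

    return {
        "hyper": hyper,
        "coefs": coefs,
        "accept_rate": np.array(accepts / iterations),
    }


def sample_posterior(
    problem: CollapsedProblem,
    chains: int,
    iterations: int,
    warmup: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Run ``chains`` independent chains; returns stacked (chain, draw, ...)
    arrays of the hyperparameters (natural scale) and coefficients."""
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    keep = iterations - warmup
    dim = 5 if problem.ar1_enabled else 4

    hyper = np.empty((chains, keep, dim))
    coefs = np.empty((chains, keep, problem.n_coef))
    acc = np.empty(chains)
    for c, sq in enumerate(seqs):
        rng = np.random.default_rng(sq)
        res = run_chain(problem, iterations, warmup, rng)
        hyper[c] = res["hyper"]
        coefs[c] = res["coefs"]
        acc[c] = res["accept_rate"]

    out = {
        "sigma": np.exp(hyper[:, :, 0]),
        "sigma_species": np.exp(hyper[:, :, 1]),
        "sigma_population": np.exp(hyper[:, :, 2]),
        "sigma_site": np.exp(hyper[:, :, 3]),
        "rho": hyper[:, :, 4] if problem.ar1_enabled else np.zeros((chains, keep)),
        "coefs": coefs,
        "accept_rate": acc,
    }
    return out
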