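"""Convergence diagnostics and posterior predictive checks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import PosteriorDraws

RHAT_THRESHOLD = 1.01


@dataclass
class ConvergenceReport:
    """Split-Rhat and effective sample sizes per monitored parameter.

    ``flagged`` lists parameters with split-Rhat above 1.01.  The Metropolis
    sampler has no divergent transitions; ``divergences`` is zero and the
    per-chain acceptance rates are reported instead.
    """

    table: pd.DataFrame
    flagged: tuple[str, ...]
    accept_rate: np.ndarray = field(default_factory=lambda: np.empty(0))
    divergences: int = 0

    @property
    def converged(self) -> bool:
        return len(self.flagged) == 0


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    r = rankdata(x, axis=None).reshape(x.shape)
    return norm.ppf((r - 0.375) / (x.size + 0.25))


def split_rhat(samples: np.ndarray) -> float:
    """Rank-normalized split-Rhat for (chain, draw) samples."""
    c, d = samples.shape
    half = d // 2
    if half < 2:
        return float("nan")
    z = _rank_normalize(samples)
    halves = np.concatenate([z[:, :half], z[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def effective_sample_size(samples: np.ndarray) -> float:
    """Bulk ESS via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(samples)[None, ...] if samples.ndim == 1 else samples))


def compute_convergence(samples: dict[str, np.ndarray]) -> ConvergenceReport:
    """Diagnostics for a dict of (chain, draw[, k]) sample arrays.

    Vector-valued entries are expanded to one row per component.  With a
    single chain, Rhat is omitted (NaN) with a warning.
    """
    import arviz as az

    rows = []
    single_chain = any(v.shape[0] < 2 for v in samples.values())
    if single_chain:
        warnings.warn("Rhat requires at least 2 chains; omitted", UserWarning, stacklevel=2)
    for name, arr in samples.items():
        arr = np.asarray(arr)
        comps = [(name, arr)] if arr.ndim == 2 else [
            (f"{name}[{k}]", arr[:, :, k]) for k in range(arr.shape[2])
        ]
        for label, series in comps:
            rhat = split_rhat(series) if series.shape[0] >= 2 else float("nan")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess_bulk = float(az.ess(series))
                ess_tail = float(az.ess(series, method="tail"))
            rows.append(
                {"parameter": label, "rhat": rhat, "ess_bulk": ess_bulk, "ess_tail": ess_tail}
            )
    table = pd.DataFrame(rows)
    flagged = tuple(table.loc[table["rhat"] > RHAT_THRESHOLD, "parameter"])
    return ConvergenceReport(table=table, flagged=flagged)


def diagnostics(draws: PosteriorDraws) -> ConvergenceReport:
    """Convergence report for the hyperparameters and fixed effects."""
    samples: dict[str, np.ndarray] = {
        "sigma": draws.sigma,
        "rho": draws.rho,
        "sigma_species": draws.sigma_species,
        "sigma_population": draws.sigma_population,
        "sigma_site": draws.sigma_site,
    }
    for j, label in enumerate(draws.beta_labels):
        samples[f"beta[{label}]"] = draws.beta[:, :, j]
    report = compute_convergence(samples)
    report.accept_rate = draws.accept_rate
    return report


@dataclass
class PosteriorPredictiveReport:
    """Replicated responses and residual summaries.

    ``raw`` residuals are y - Xb - year*slopes (before the AR term);
    ``whitened`` residuals subtract the AR(1) carry-over and should be white
    when the model is well specified.  ``variance_slope`` is the OLS slope of
    squared raw residuals on centered year (near zero under constant
    variance).
    """

    replicated: np.ndarray          # (n_rep, n_obs)
    observed: np.ndarray
    residual_mean: float
    residual_sd: float
    lag1_raw: float
    lag1_whitened: float
    variance_slope: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "residual_mean": self.residual_mean,
                    "residual_sd": self.residual_sd,
                    "lag1_raw": self.lag1_raw,
                    "lag1_whitened": self.lag1_whitened,
                    "variance_slope": self.variance_slope,
                }
            ]
        )


def _lag1_corr(u: np.ndarray, lag_mask: np.ndarray) -> float:
    idx = np.flatnonzero(lag_mask)
    a, b = u[idx], u[idx - 1]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def posterior_predictive(
    draws: PosteriorDraws, model, n_rep: int = 200, seed: int = 0
) -> PosteriorPredictiveReport:
    """Simulate replicated log abundances and summarize residual behaviour."""
    rng = np.random.default_rng(seed)
    idx = draws.subsample(n_rep, seed=seed)

    slope = (
        draws.r_species()[:, model.species_of_obs]
        + draws.r_population()[:, model.population_of_obs]
        + draws.r_site()[:, model.site_of_obs]
    )
    mu_struct = draws.beta_flat() @ model.design.matrix.T + slope * model.centered_year[None, :]

    mean_m = mu_struct.mean(axis=0)
    resid = model.y - mean_m
    rho_hat = float(draws.hyper_flat("rho").mean())
    lag = ~model.first_obs
    white = resid.copy()
    white[lag] -= rho_hat * resid[np.flatnonzero(lag) - 1]

    t = model.centered_year
    sq = resid**2
    var_slope = float(np.polyfit(t, sq, 1)[0]) if t.size > 2 else 0.0

    sigma = draws.hyper_flat("sigma")
    rho = draws.hyper_flat("rho")
    n = model.y.size
    replicated = np.empty((idx.size, n))
    prev = np.flatnonzero(lag) - 1
    for r, i in enumerate(idx):
        eps = np.empty(n)
        innov = rng.normal(0.0, sigma[i], size=n)
        eps[model.first_obs] = innov[model.first_obs]
        # AR(1) recursion along each series (observations are sorted)
        for pos, pv in zip(np.flatnonzero(lag), prev):
            eps[pos] = rho[i] * eps[pv] + innov[pos]
        replicated[r] = mu_struct[i] + eps

    return PosteriorPredictiveReport(
        replicated=replicated,
        observed=model.y,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std()),
        lag1_raw=_lag1_corr(resid, lag),
        lag1_whitened=_lag1_corr(white, lag),
        variance_slope=var_slope,
    )
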