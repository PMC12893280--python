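"""The multilevel Bayesian trend model.

Log abundance y (centered per series) is modelled as Gaussian:

    y_t ~ Normal(mu_t, sigma)
    mu_t = X beta + year_t * (r_S + r_P + r_L) + rho * eps_{t-1}

where X is the threat-combination design matrix (intercept, year, one
indicator and one indicator-times-year column per threat combination), r_S,
r_P, r_L are random slopes for species, population and site, and eps_{t-1}
is the previous within-series residual (AR(1); the first observation of each
series has no lagged term).  Site slopes are spatially correlated through the
Cholesky factor of the normalized Haversine proximity matrix.  All random
slopes are noncentered: r = sigma_group * z (times the Cholesky factor for
sites) with z ~ Normal(0, 1).

Priors: beta ~ Normal(0, 1); z ~ Normal(0, 1); sigma and the three group
sigmas ~ Exponential(1); rho ~ Normal(0, 0.25).

:class:`ThreatTrendModel` assembles the data; ``fit`` returns a
:class:`~popthreat.results.ThreatTrendResults` carrying posterior draws and
all downstream analyses (trends, interaction classification,
counterfactuals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import expon, norm

from . import _sampler
from .data_io import (
    PopulationSeries,
    PreparedSeries,
    filter_series,
    prepare_all,
    read_lpd_table,
)
from .draws import PosteriorDraws
from .spatial import SpatialCovariance, build_site_proximity, linear_proximity, round_coordinates
from .threat_design import ThreatDesign, build_design, enumerate_combinations


@dataclass(frozen=True)
class ModelSpec:
    """Sampler configuration.  Defaults are the full-scale setting (4 chains
    of 5000 iterations, 2500 warmup); :meth:`desk` gives a reduced profile
    suitable for interactive work and simulation studies."""

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    seed: int = 0
    ar1_enabled: bool = True

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "ModelSpec":
        return cls(chains=2, iterations=1500, warmup=750, seed=seed, **kw)


def noncentered_transform(
    z: np.ndarray, sigma: float, chol_factor: np.ndarray | None = None
) -> np.ndarray:
    """Random slopes from standard-normal draws: r = sigma * (L @ z) when a
    correlation Cholesky factor is supplied (site slopes), else r = sigma * z."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    z = np.asarray(z, dtype=float)
    if chol_factor is not None:
        chol_factor = np.asarray(chol_factor)
        if chol_factor.shape[1] != z.shape[-1]:
            raise ValueError(
                f"chol_factor width {chol_factor.shape[1]} does not match z length {z.shape[-1]}"
            )
        return sigma * (z @ chol_factor.T)
    return sigma * z


class ThreatTrendModel:
    """Hierarchical trend model bound to a set of population series.

    Parameters
    ----------
    series:
        Populations to model (already filtered; see :meth:`from_series` for
        the standard inclusion filters).
    zero_policy, centering:
        Passed to :func:`popthreat.data_io.prepare_series`.
    observed_only:
        Restrict design columns to observed combinations (plus their
        sub-combinations).
    """

    def __init__(
        self,
        series: Sequence[PopulationSeries],
        *,
        zero_policy: float = 0.01,
        centering: str = "log",
        labels: Sequence[str] | None = None,
        observed_only: bool = True,
        nugget: float = 1e-6,
        proximity_transform=linear_proximity,
        ar1_enabled: bool = True,
    ) -> None:
        if len(series) == 0:
            raise ValueError("no series supplied")
        self.series = tuple(series)
        self.prepared: tuple[PreparedSeries, ...] = tuple(
            prepare_all(series, zero_policy, centering)
        )
        self.ar1_enabled = ar1_enabled

        threat_sets = [s.threats for s in series]
        if labels is None:
            labels = enumerate_combinations(threat_sets, observed_only=observed_only)
        self.labels = tuple(labels)
        self.design: ThreatDesign = build_design(self.prepared, threat_sets, self.labels)

        # Grouping structures.  Sites are integer-degree grid cells: series
        # whose rounded coordinates coincide share a site (and a site slope).
        self.population_ids = tuple(s.population_id for s in series)
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValueError("duplicate population ids")
        self.species_ids = tuple(sorted({s.species_id for s in series}))
        site_keys: list[tuple[int, int]] = []
        for s in series:
            key = round_coordinates(*s.site)
            if key not in site_keys:
                site_keys.append(key)
        self.site_keys = tuple(site_keys)
        self.site_ids = tuple(f"{la}_{lo}" for la, lo in site_keys)

        self.species_of_population = np.array(
            [self.species_ids.index(s.species_id) for s in series]
        )
        self.site_of_population = np.array(
            [site_keys.index(round_coordinates(*s.site)) for s in series]
        )
        self.proximity: SpatialCovariance = build_site_proximity(
            [(float(a), float(b)) for a, b in site_keys],
            nugget=nugget,
            site_ids=self.site_ids,
            transform=proximity_transform,
        )

        lengths = [len(p.centered_year) for p in self.prepared]
        self.population_of_obs = np.repeat(np.arange(len(series)), lengths)
        self.species_of_obs = self.species_of_population[self.population_of_obs]
        self.site_of_obs = self.site_of_population[self.population_of_obs]
        self.y = np.concatenate([p.centered_log_abundance for p in self.prepared])
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite response after preparation")
        self.centered_year = self.design.centered_year
        first = np.zeros(self.y.size, dtype=bool)
        first[np.cumsum([0] + lengths[:-1])] = True
        self.first_obs = first

        self._problem = self._build_problem()

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_series(
        cls,
        series: Sequence[PopulationSeries],
        min_span_years: int = 10,
        min_points: int = 5,
        require_threat_status: bool = True,
        **kw,
    ) -> "ThreatTrendModel":
        """Apply the standard inclusion filters, then build the model."""
        return cls(
            filter_series(series, min_span_years, min_points, require_threat_status), **kw
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "ThreatTrendModel":
        filter_kw = {
            k: kw.pop(k)
            for k in ("min_span_years", "min_points", "require_threat_status")
            if k in kw
        }
        return cls.from_series(read_lpd_table(path), **filter_kw, **kw)

    @classmethod
    def submodels(
        cls, series: Sequence[PopulationSeries], by: str = "system", **kw
    ) -> dict[str, "ThreatTrendModel"]:
        """One model per system or taxon subset, each with its own proximity
        matrix and (when fitted) its own rho."""
        if by not in ("system", "taxon"):
            raise ValueError("by must be 'system' or 'taxon'")
        out: dict[str, ThreatTrendModel] = {}
        for level in sorted({getattr(s, by) for s in series}):
            subset = [s for s in series if getattr(s, by) == level]
            out[level] = cls(subset, **kw)
        return out

    # ---------------------------------------------------------------- internals
    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_fixed(self) -> int:
        return len(self.design.column_labels)

    def _build_problem(self) -> _sampler.CollapsedProblem:
        n = self.n_obs
        t = self.centered_year
        n_s, n_p, n_l = len(self.species_ids), len(self.population_ids), len(self.site_ids)

        zs = np.zeros((n, n_s))
        zs[np.arange(n), self.species_of_obs] = t
        zp = np.zeros((n, n_p))
        zp[np.arange(n), self.population_of_obs] = t
        zl = self.proximity.cholesky[self.site_of_obs, :] * t[:, None]

        base = np.hstack([self.design.matrix, zs, zp, zl])
        p_f = self.n_fixed
        slices = (
            slice(0, p_f),
            slice(p_f, p_f + n_s),
            slice(p_f + n_s, p_f + n_s + n_p),
            slice(p_f + n_s + n_p, p_f + n_s + n_p + n_l),
        )
        return _sampler.CollapsedProblem(
            y=self.y,
            base=base,
            block_slices=slices,
            lag_mask=~self.first_obs,
            ar1_enabled=self.ar1_enabled,
        )

    # -------------------------------------------------------------- densities
    def _mu_and_resid(self, params: dict) -> tuple[np.ndarray, np.ndarray]:
        beta = np.asarray(params["beta"], dtype=float)
        r_s = noncentered_transform(
            np.asarray(params["z_species"], float), float(params["sigma_species"])
        )
        r_p = noncentered_transform(
            np.asarray(params["z_population"], float), float(params["sigma_population"])
        )
        r_l = noncentered_transform(
            np.asarray(params["z_site"], float),
            float(params["sigma_site"]),
            self.proximity.cholesky,
        )
        slope = r_s[self.species_of_obs] + r_p[self.population_of_obs] + r_l[self.site_of_obs]
        m = self.design.matrix @ beta + self.centered_year * slope
        return m, self.y - m

    def loglikelihood(self, params: dict) -> float:
        """Exact data log likelihood at a fixed parameter point.

        ``params`` maps names (beta, z_species, z_population, z_site, sigma,
        rho, sigma_species, sigma_population, sigma_site) to values.  The
        AR(1) term uses the previous within-series residual; the first
        observation of every series has no lagged term.
        """
        sigma = float(params["sigma"])
        rho = float(params.get("rho", 0.0)) if self.ar1_enabled else 0.0
        _, resid = self._mu_and_resid(params)
        u = resid.copy()
        lag = ~self.first_obs
        u[lag] -= rho * resid[np.flatnonzero(lag) - 1]
        return float(np.sum(norm.logpdf(u, 0.0, sigma)))

    def logprior(self, params: dict) -> float:
        lp = float(np.sum(norm.logpdf(np.asarray(params["beta"], float), 0.0, 1.0)))
        for key in ("z_species", "z_population", "z_site"):
            lp += float(np.sum(norm.logpdf(np.asarray(params[key], float), 0.0, 1.0)))
        for key in ("sigma", "sigma_species", "sigma_population", "sigma_site"):
            lp += float(expon.logpdf(float(params[key])))
        if self.ar1_enabled:
            lp += float(norm.logpdf(float(params.get("rho", 0.0)), 0.0, _sampler.RHO_PRIOR_SD))
        return lp

    def logposterior(self, params: dict) -> float:
        return self.loglikelihood(params) + self.logprior(params)

    # ------------------------------------------------------------------- fit
    def fit(self, spec: ModelSpec | None = None, **overrides):
        """Sample the posterior; returns :class:`ThreatTrendResults`."""
        from .results import ThreatTrendResults

        if spec is None:
            spec = ModelSpec(**overrides) if overrides else ModelSpec()
        elif overrides:
            spec = replace(spec, **overrides)
        if spec.ar1_enabled != self.ar1_enabled:
            spec = replace(spec, ar1_enabled=self.ar1_enabled)

        raw = _sampler.sample_posterior(
            self._problem, spec.chains, spec.iterations, spec.warmup, spec.seed
        )
        sl_f, sl_s, sl_p, sl_l = self._problem.block_slices
        coefs = raw["coefs"]
        draws = PosteriorDraws(
            beta=coefs[:, :, sl_f],
            beta_labels=self.design.column_labels,
            z_species=coefs[:, :, sl_s],
            z_population=coefs[:, :, sl_p],
            z_site=coefs[:, :, sl_l],
            sigma=raw["sigma"],
            rho=raw["rho"],
            sigma_species=raw["sigma_species"],
            sigma_population=raw["sigma_population"],
            sigma_site=raw["sigma_site"],
            species_ids=self.species_ids,
            population_ids=self.population_ids,
            site_ids=self.site_ids,
            site_cholesky=self.proximity.cholesky,
            accept_rate=raw["accept_rate"],
        )
        return ThreatTrendResults(self, draws, spec)


def fit_model(
    prepared: Sequence[PreparedSeries],
    design: ThreatDesign,
    proximity: SpatialCovariance,
    spec: ModelSpec,
    *,
    species_of_population: Sequence[int],
    site_of_population: Sequence[int],
    population_ids: Sequence[str],
    species_ids: Sequence[str],
) -> PosteriorDraws:
    """Functional fitting interface over pre-assembled pieces.

    Most users should prefer :class:`ThreatTrendModel`; this entry point
    exists for callers that build designs and proximity matrices themselves.
    """
    lengths = [len(p.centered_year) for p in prepared]
    n = sum(lengths)
    if design.matrix.shape[0] != n:
        raise ValueError("design rows do not align with observations")
    pop_of_obs = np.repeat(np.arange(len(prepared)), lengths)
    species_of_population = np.asarray(species_of_population)
    site_of_population = np.asarray(site_of_population)
    if species_of_population.size != len(prepared) or site_of_population.size != len(prepared):
        raise ValueError("grouping vectors do not match series count")
    if site_of_population.max(initial=-1) >= proximity.n_sites:
        raise ValueError("unmatched site id in grouping structure")

    y = np.concatenate([p.centered_log_abundance for p in prepared])
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response")
    t = design.centered_year
    n_s, n_p, n_l = len(species_ids), len(prepared), proximity.n_sites
    zs = np.zeros((n, n_s))
    zs[np.arange(n), species_of_population[pop_of_obs]] = t
    zp = np.zeros((n, n_p))
    zp[np.arange(n), pop_of_obs] = t
    zl = proximity.cholesky[site_of_population[pop_of_obs], :] * t[:, None]
    base = np.hstack([design.matrix, zs, zp, zl])
    p_f = len(design.column_labels)
    first = np.zeros(n, dtype=bool)
    first[np.cumsum([0] + lengths[:-1])] = True
    problem = _sampler.CollapsedProblem(
        y=y,
        base=base,
        block_slices=(
            slice(0, p_f),
            slice(p_f, p_f + n_s),
            slice(p_f + n_s, p_f + n_s + n_p),
            slice(p_f + n_s + n_p, p_f + n_s + n_p + n_l),
        ),
        lag_mask=~first,
        ar1_enabled=spec.ar1_enabled,
    )
    raw = _sampler.sample_posterior(problem, spec.chains, spec.iterations, spec.warmup, spec.seed)
    sl_f, sl_s, sl_p, sl_l = problem.block_slices
    coefs = raw["coefs"]
    return PosteriorDraws(
        beta=coefs[:, :, sl_f],
        beta_labels=design.column_labels,
        z_species=coefs[:, :, sl_s],
        z_population=coefs[:, :, sl_p],
        z_site=coefs[:, :, sl_l],
        sigma=raw["sigma"],
        rho=raw["rho"],
        sigma_species=raw["sigma_species"],
        sigma_population=raw["sigma_population"],
        sigma_site=raw["sigma_site"],
        species_ids=tuple(species_ids),
        population_ids=tuple(population_ids),
        site_ids=proximity.site_ids,
        site_cholesky=proximity.cholesky,
        accept_rate=raw["accept_rate"],
    )
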