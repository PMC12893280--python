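"""Posterior draw container for the hierarchical trend model."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PosteriorDraws:
    """MCMC draws of every model parameter, shaped (chain, draw, ...).

    Noncentered variables are stored as drawn (``z_*``); the implied random
    slopes (``r_*``, units: Delta log abundance per year) are derived on
    demand:  r_S = z_S * sigma_S, r_P = z_P * sigma_P, and the site slopes
    r_L = sigma_L * (L_Sigma @ z_L) with L_Sigma the Cholesky factor of the
    site proximity matrix.
    """

    beta: np.ndarray              # (C, D, n_fixed)
    beta_labels: tuple[str, ...]
    z_species: np.ndarray         # (C, D, n_species)
    z_population: np.ndarray      # (C, D, n_population)
    z_site: np.ndarray            # (C, D, n_site)
    sigma: np.ndarray             # (C, D)
    rho: np.ndarray               # (C, D)
    sigma_species: np.ndarray
    sigma_population: np.ndarray
    sigma_site: np.ndarray
    species_ids: tuple[str, ...]
    population_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    site_cholesky: np.ndarray     # (n_site, n_site)
    accept_rate: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.beta.shape[2] != len(self.beta_labels):
            raise ValueError("beta width does not match labels")

    # ------------------------------------------------------------------ shape
    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        """Post-warmup draws per chain."""
        return self.beta.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(self.n_total, *arr.shape[2:])

    # --------------------------------------------------------------- flat views
    def beta_flat(self) -> np.ndarray:
        return self._flat(self.beta)

    def beta_series(self, label: str) -> np.ndarray:
        """All draws of one fixed-effect coefficient, flattened over chains."""
        try:
            j = self.beta_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown fixed-effect label {label!r}") from None
        return self.beta_flat()[:, j]

    def hyper_flat(self, name: str) -> np.ndarray:
        return self._flat(getattr(self, name))

    # ------------------------------------------------------------ random slopes
    def r_species(self) -> np.ndarray:
        """(total_draws, n_species) species random slopes."""
        return self._flat(self.z_species) * self.hyper_flat("sigma_species")[:, None]

    def r_population(self) -> np.ndarray:
        return self._flat(self.z_population) * self.hyper_flat("sigma_population")[:, None]

    def r_site(self) -> np.ndarray:
        correlated = self._flat(self.z_site) @ self.site_cholesky.T
        return correlated * self.hyper_flat("sigma_site")[:, None]

    def subsample(self, n: int, seed: int = 0) -> np.ndarray:
        """Indices of a random subsample of flattened draws (reporting uses
        1000 by convention)."""
        rng = np.random.default_rng(seed)
        n = min(n, self.n_total)
        return np.sort(rng.choice(self.n_total, size=n, replace=False))

    # ------------------------------------------------------------- conversions
    def to_inference_data(self):
        """arviz InferenceData view (hyperparameters and fixed effects)."""
        import arviz as az

        data = {
            "sigma": self.sigma,
            "rho": self.rho,
            "sigma_species": self.sigma_species,
            "sigma_population": self.sigma_population,
            "sigma_site": self.sigma_site,
            "beta": self.beta,
        }
        return az.from_dict(
            posterior=data, coords={"coef": list(self.beta_labels)}, dims={"beta": ["coef"]}
        )

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "beta_labels": list(self.beta_labels),
            "z_species": self.z_species.tolist(),
            "z_population": self.z_population.tolist(),
            "z_site": self.z_site.tolist(),
            "sigma": self.sigma.tolist(),
            "rho": self.rho.tolist(),
            "sigma_species": self.sigma_species.tolist(),
            "sigma_population": self.sigma_population.tolist(),
            "sigma_site": self.sigma_site.tolist(),
            "species_ids": list(self.species_ids),
            "population_ids": list(self.population_ids),
            "site_ids": list(self.site_ids),
            "site_cholesky": self.site_cholesky.tolist(),
            "accept_rate": self.accept_rate.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PosteriorDraws":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta=np.array(d["beta"]),
            beta_labels=tuple(d["beta_labels"]),
            z_species=np.array(d["z_species"]),
            z_population=np.array(d["z_population"]),
            z_site=np.array(d["z_site"]),
            sigma=np.array(d["sigma"]),
            rho=np.array(d["rho"]),
            sigma_species=np.array(d["sigma_species"]),
            sigma_population=np.array(d["sigma_population"]),
            sigma_site=np.array(d["sigma_site"]),
            species_ids=tuple(d["species_ids"]),
            population_ids=tuple(d["population_ids"]),
            site_ids=tuple(d["site_ids"]),
            site_cholesky=np.array(d["site_cholesky"]),
            accept_rate=np.array(d["accept_rate"]),
        )
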