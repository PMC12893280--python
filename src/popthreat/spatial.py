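"""Site proximity matrices from Haversine distances.

Correlation between the site-level random slopes is induced by geographic
proximity: pairwise great-circle (Haversine) distances between integer-rounded
site coordinates are normalized to [0, 1] and flipped so that 1 means
coincident sites and 0 the most distant pair in the data.  Because the linear
transform 1 - D/max(D) is not guaranteed positive semidefinite, a small
diagonal nugget plus eigenvalue clipping repairs the matrix into a usable
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def round_coordinates(lat: float, lon: float) -> tuple[int, int]:
    """Round to the nearest integer degree, halves away from zero
    (10.65 -> 11, 0.5 -> 1, -0.5 -> -1)."""
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} out of range")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} out of range")
    return _half_away(lat), _half_away(lon)


def _half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def haversine_distance(
    a: tuple[float, float], b: tuple[float, float], radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(h))))


def _pairwise_haversine(coords: np.ndarray, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    h = (
        np.sin((lat - lat.T) / 2.0) ** 2
        + np.cos(lat) * np.cos(lat.T) * np.sin((lon - lon.T) / 2.0) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(np.maximum(h, 0.0))))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class SpatialCovariance:
    """Normalized site proximity matrix with its Cholesky factor.

    ``proximity`` has diagonal 1 + nugget and off-diagonal entries in [0, 1];
    it is positive semidefinite after repair, so ``cholesky`` always exists.
    """

    site_ids: tuple[str, ...]
    proximity: np.ndarray
    nugget: float
    cholesky: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.site_ids)
        return pd.DataFrame(self.proximity, index=ids, columns=ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def linear_proximity(d: np.ndarray) -> np.ndarray:
    """The minimal normalization 1 - D/max(D): 1 for coincident sites, 0 for
    the most distant pair."""
    dmax = d.max()
    if dmax == 0.0:
        return np.eye(d.shape[0])
    return 1.0 - d / dmax


def exponential_proximity(length_km: float) -> Callable[[np.ndarray], np.ndarray]:
    """Alternative kernel transform exp(-D / length_km) (always PSD)."""

    def _transform(d: np.ndarray) -> np.ndarray:
        return np.exp(-d / length_km)

    return _transform


def build_site_proximity(
    sites: Sequence[tuple[float, float]],
    nugget: float = 1e-6,
    site_ids: Sequence[str] | None = None,
    transform: Callable[[np.ndarray], np.ndarray] = linear_proximity,
    round_coords: bool = True,
) -> SpatialCovariance:
    """Build the normalized proximity matrix for a list of (lat, lon) sites.

    Coordinates are integer-rounded, pairwise Haversine distances computed,
    the distance matrix pushed through ``transform`` (default
    :func:`linear_proximity`), negative eigenvalues clipped to restore
    positive semidefiniteness, the diagonal re-normalized to 1, and the nugget
    added to the diagonal.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    if site_ids is None:
        site_ids = tuple(f"site_{i}" for i in range(len(sites)))
    coords = np.array(
        [round_coordinates(*s) if round_coords else s for s in sites], dtype=float
    )
    d = _pairwise_haversine(coords)
    prox = transform(d)
    prox = 0.5 * (prox + prox.T)
    prox = _repair_psd(prox)
    prox = prox + nugget * np.eye(prox.shape[0])
    chol = _safe_cholesky(prox)
    return SpatialCovariance(tuple(site_ids), prox, nugget, chol)


def _repair_psd(m: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and restore a unit diagonal."""
    w, v = np.linalg.eigh(m)
    if w.min() >= 0.0:
        return m
    w = np.clip(w, 0.0, None)
    m = (v * w) @ v.T
    dd = np.sqrt(np.clip(np.diag(m), 1e-12, None))
    m = m / np.outer(dd, dd)
    m = np.clip(0.5 * (m + m.T), 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def _safe_cholesky(m: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(8):
        try:
            return np.linalg.cholesky(m + jitter * np.eye(m.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
    raise np.linalg.LinAlgError("proximity matrix not repairable to PSD")
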