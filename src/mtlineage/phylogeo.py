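"""Motif searches over haplotype databases and kriged frequency surfaces.

The database search implements the range rule used when mixing records of
different sequencing extents: a motif variant outside a record's sequenced
range neither matches nor excludes that record.  Masked hotspot variants
are ignored on both sides, so e.g. a 16183C carrier still matches a motif
that does not list it.

Frequency surfaces use ordinary kriging (weights constrained to sum to 1)
on great-circle distances with an exponential variogram by default; with a
zero nugget the surface interpolates the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit

from .variants import (
    DEFAULT_MASK,
    Haplotype,
    HotspotMask,
    Variant,
)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Haplotype database
# ---------------------------------------------------------------------------

class HaplotypeDB:
    """Indexed collection of haplotypes with a position inverted index."""

    def __init__(self, haplotypes: Iterable[Haplotype] = ()):
        self._records: Dict[str, Haplotype] = {}
        self._index: Dict[int, set] = {}
        for h in haplotypes:
            self.add(h)

    def add(self, h: Haplotype) -> None:
        if h.sample_id in self._records:
            raise ValueError(f"duplicate sample id {h.sample_id!r}")
        self._records[h.sample_id] = h
        for v in h.variants:
            self._index.setdefault(v.position, set()).add(h.sample_id)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def get(self, sample_id: str) -> Haplotype:
        return self._records[sample_id]

    def samples_with_position(self, position: int) -> set:
        return set(self._index.get(position, set()))

    def search_motif(
        self,
        required: Iterable[Variant],
        backbone: Iterable[Variant] = (),
        mask: HotspotMask = DEFAULT_MASK,
    ) -> List[Haplotype]:
        """Records carrying all backbone and required variants within range.

        Masked variants are ignored entirely; a motif variant outside a
        record's range is skipped for that record (range rule).  Results are
        ordered by sample id.
        """
        motif = [v for v in list(backbone) + list(required) if not mask.matches(v)]
        matches = []
        for h in self._records.values():
            usable = {v for v in h.variants if not mask.matches(v)}
            ok = True
            for v in motif:
                if not h.range.contains_variant(v):
                    continue  # outside sequenced range: neither match nor exclude
                if v not in usable:
                    ok = False
                    break
            if ok:
                matches.append(h)
        return sorted(matches, key=lambda h: h.sample_id)


def expand_from_root(h: Haplotype, root_motif: Iterable[Variant]) -> Haplotype:
    """Compose a root-relative haplotype with its root's cumulative motif.

    Motif variants outside the record's sequenced range are dropped; a
    back-mutation in the record cancels the corresponding motif variant.
    """
    variants = set(v for v in h.variants if not v.back_mutation)
    for v in root_motif:
        if h.range.contains_variant(v) and replace(v, back_mutation=True) not in h.variants:
            variants.add(v)
    return h.with_variants(variants)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float
    frequency: float
    sample_size: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")


@dataclass(frozen=True)
class Variogram:
    """Isotropic variogram model over great-circle kilometres."""

    model: str = "exponential"
    range_km: float = 1000.0
    sill: float = 0.05
    nugget: float = 0.0

    def __post_init__(self):
        if self.range_km <= 0 or self.sill <= 0 or self.nugget < 0:
            raise ValueError("variogram parameters must be positive (nugget >= 0)")
        if self.model not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram model {self.model!r}")

    def gamma(self, h):
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / self.range_km)
        elif self.model == "gaussian":
            struct = 1.0 - np.exp(-((h / self.range_km) ** 2))
        else:  # spherical
            x = np.clip(h / self.range_km, 0.0, 1.0)
            struct = 1.5 * x - 0.5 * x ** 3
        out = self.nugget + self.sill * struct
        return np.where(h == 0.0, 0.0, out)


@dataclass
class FrequencySurface:
    latitudes: np.ndarray
    longitudes: np.ndarray
    values: np.ndarray          # shape (nlat, nlon), clipped to [0, 1]
    weight_sums: np.ndarray     # kriging weight sums per node (== 1)
    variogram: Variogram

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lat in enumerate(self.latitudes):
            for j, lon in enumerate(self.longitudes):
                rows.append({"latitude": lat, "longitude": lon,
                             "frequency": self.values[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def fit_variogram(points: Sequence[GeoPoint], model: str = "exponential",
                  n_bins: int = 12) -> Variogram:
    """Method-of-moments empirical semivariogram with a least-squares fit."""
    pts = list(points)
    lats = np.array([p.latitude for p in pts])
    lons = np.array([p.longitude for p in pts])
    freqs = np.array([p.frequency for p in pts])
    d, g = [], []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d.append(haversine_km(lats[i], lons[i], lats[j], lons[j]))
            g.append(0.5 * (freqs[i] - freqs[j]) ** 2)
    d, g = np.array(d), np.array(g)
    bins = np.linspace(0, d.max(), n_bins + 1)
    centers, gammas = [], []
    for k in range(n_bins):
        sel = (d >= bins[k]) & (d < bins[k + 1])
        if sel.any():
            centers.append(d[sel].mean())
            gammas.append(g[sel].mean())
    centers, gammas = np.array(centers), np.array(gammas)
    sill0 = max(float(np.var(freqs)), 1e-6)
    range0 = max(float(d.max()) / 3.0, 1.0)

    def f(h, rng, sill):
        return Variogram(model, rng, sill, 0.0).gamma(np.where(h == 0, 1e-9, h))

    try:
        popt, _ = curve_fit(f, centers, gammas, p0=[range0, sill0],
                            bounds=([1e-6, 1e-9], [np.inf, np.inf]), maxfev=5000)
        rng_fit, sill_fit = float(popt[0]), float(popt[1])
    except RuntimeError:
        rng_fit, sill_fit = range0, sill0
    return Variogram(model, rng_fit, sill_fit, 0.0)


class KrigingError(ValueError):
    pass


def kriging_weights(points: Sequence[GeoPoint], lat: float, lon: float,
                    variogram: Variogram) -> Tuple[np.ndarray, float]:
    """Ordinary-kriging weights (and Lagrange multiplier) for one target."""
    system, lu = _kriging_system(points, variogram)
    lats = np.array([p.latitude for p in points])
    lons = np.array([p.longitude for p in points])
    rhs = np.empty(len(points) + 1)
    rhs[:-1] = variogram.gamma(haversine_km(lats, lons, lat, lon))
    rhs[-1] = 1.0
    sol = lu_solve(lu, rhs)
    return sol[:-1], sol[-1]


def _kriging_system(points: Sequence[GeoPoint], variogram: Variogram):
    n = len(points)
    lats = np.array([p.latitude for p in points])
    lons = np.array([p.longitude for p in points])
    for i in range(n):
        for j in range(i + 1, n):
            if lats[i] == lats[j] and lons[i] == lons[j]:
                raise KrigingError(
                    f"coincident points {i} and {j} at ({lats[i]}, {lons[i]}) "
                    "make the kriging system singular"
                )
    gamma_mat = variogram.gamma(
        haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    )
    a = np.ones((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[n, n] = 0.0
    return a, lu_factor(a)


def krige_frequencies(
    points: Sequence[GeoPoint],
    grid: Tuple[float, float, float, float],
    shape: Tuple[int, int] = (25, 25),
    variogram: Optional[Variogram] = None,
) -> FrequencySurface:
    """Ordinary-kriging interpolation of haplogroup frequencies.

    ``grid`` is (lat_min, lat_max, lon_min, lon_max); ``shape`` the number
    of grid nodes per axis.  The variogram is fitted from the data when not
    supplied.  Output frequencies are clipped to [0, 1].
    """
    pts = list(points)
    if len({(p.latitude, p.longitude) for p in pts}) < 2:
        raise KrigingError("need at least 2 distinct points")
    if variogram is None:
        variogram = fit_variogram(pts)
    _, lu = _kriging_system(pts, variogram)
    lats = np.array([p.latitude for p in pts])
    lons = np.array([p.longitude for p in pts])
    freqs = np.array([p.frequency for p in pts])
    glats = np.linspace(grid[0], grid[1], shape[0])
    glons = np.linspace(grid[2], grid[3], shape[1])
    values = np.empty(shape)
    wsums = np.empty(shape)
    rhs = np.empty(len(pts) + 1)
    for i, la in enumerate(glats):
        for j, lo in enumerate(glons):
            rhs[:-1] = variogram.gamma(haversine_km(lats, lons, la, lo))
            rhs[-1] = 1.0
            sol = lu_solve(lu, rhs)
            w = sol[:-1]
            values[i, j] = float(w @ freqs)
            wsums[i, j] = float(w.sum())
    return FrequencySurface(glats, glons, np.clip(values, 0.0, 1.0), wsums, variogram)


def read_geopoints(path) -> List[GeoPoint]:
    """CSV with columns latitude, longitude, frequency[, n]."""
    df = pd.read_csv(path, comment="#")
    out = []
    for r in df.itertuples():
        out.append(GeoPoint(float(r.latitude), float(r.longitude),
                            float(r.frequency), int(getattr(r, "n", 0) or 0)))
    return out
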