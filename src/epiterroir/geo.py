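"""Geographic and environmental pairwise-difference matrices.

Builds the explanatory distance matrices for isolation-by-distance Mantel
analysis: great-circle distances between vineyard sites (optionally on the
log(1 + km) scale) and absolute differences in environmental scalars such as
altitude, rainfall or growing-season temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix

EARTH_RADIUS_KM = 6371.0

SITE_COLUMNS = ("lat", "lon")


def validate_sites(sites: pd.DataFrame) -> None:
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"site table lacks required column {col!r}")
    bad_lat = sites.index[(sites["lat"].abs() > 90) | sites["lat"].isna()]
    bad_lon = sites.index[(sites["lon"].abs() > 180) | sites["lon"].isna()]
    if len(bad_lat) or len(bad_lon):
        raise ValueError(
            f"out-of-range coordinates at sites: {sorted(set(bad_lat) | set(bad_lon))}"
        )
    if sites.index.duplicated().any():
        raise ValueError("site table must have one row per vineyard")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geographic_distance_matrix(
    sites: pd.DataFrame, transform: str = "none"
) -> DistanceMatrix:
    """Pairwise great-circle distances between sites.

    ``transform="log1p_km"`` returns log(1 + km) elementwise, the scale used
    when correlating geographic separation against molecular distances
    (kilometre-scale vineyard layouts are strongly right-skewed).
    """
    validate_sites(sites)
    if transform not in ("none", "log1p_km"):
        raise ValueError(f"unknown transform {transform!r}")
    lat = sites["lat"].to_numpy()
    lon = sites["lon"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    if transform == "log1p_km":
        d = np.log1p(d)
    return DistanceMatrix(d, list(sites.index.astype(str)), kind="geographic")


def env_difference_matrix(sites: pd.DataFrame, variable: str) -> DistanceMatrix:
    """|x_i - x_j| matrix for one environmental variable (altitude, rainfall, ...)."""
    if variable not in sites.columns:
        raise ValueError(f"variable {variable!r} not in site table")
    x = pd.to_numeric(sites[variable], errors="coerce")
    if x.isna().any():
        raise ValueError(
            f"missing {variable!r} values at vineyards: {list(sites.index[x.isna()])}"
        )
    v = x.to_numpy(dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(d, list(sites.index.astype(str)), kind="environmental")


def expand_to_samples(dm: DistanceMatrix, sample_to_site: pd.Series) -> DistanceMatrix:
    """Expand a vineyard-level matrix to sample level.

    Samples inherit their vineyard's coordinates, so co-located samples are
    at distance zero.  Used when correlating against sample-level molecular
    distances instead of vineyard-level PhiPT.
    """
    sites = list(dm.labels)
    pos = {s: i for i, s in enumerate(sites)}
    try:
        idx = np.array([pos[str(v)] for v in sample_to_site])
    except KeyError as e:
        raise ValueError(f"sample maps to unknown site {e.args[0]!r}") from None
    vals = dm.values[np.ix_(idx, idx)]
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, list(sample_to_site.index.astype(str)), kind=dm.kind)
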