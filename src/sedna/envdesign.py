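"""Environmental design-matrix preparation.

Covers the covariate bookkeeping a gradient study needs before
modelling: the decadal sea-surface-temperature trend from an annual
series, nearest-cell extraction from gridded layers with missing
cells, iterative variance-inflation-factor (VIF) pruning of collinear
covariates with an ecological preference order, and centring/scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# decadal SST trend

def decadal_trend(years, values) -> float:
    """OLS slope of annual values on year, in units per decade.

    Emulates deriving an SST-change covariate from a 1980–2016 annual
    mean series: fit value ~ year by least squares, multiply the slope
    by 10.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must have equal length")
    if years.size < 3:
        raise ValueError("need at least 3 annual points for a trend")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    slope = np.polyfit(years, values, 1)[0]
    return float(slope * 10.0)


# ---------------------------------------------------------------------------
# gridded layers

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float),
                                              np.asarray(lat2, float), np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class AsciiGrid:
    """Minimal ESRI-style ASCII grid: header then a nrows x ncols matrix.

    Header keys (one per line, ``key value``): ncols, nrows, xllcorner,
    yllcorner, cellsize, nodata_value. Row 0 of the matrix is the
    northernmost row, matching the on-disk convention.
    """

    values: np.ndarray       # nrows x ncols, NaN = missing
    xllcorner: float
    yllcorner: float
    cellsize: float

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a cell center; row 0 is the top (north)."""
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return lat, lon

    def containing_cell(self, lat: float, lon: float) -> tuple[int, int] | None:
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        lines = Path(path).read_text().strip().splitlines()
        header: dict[str, float] = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        nodata = header.get("nodata_value", -9999.0)
        vals = np.loadtxt(lines[i:]).reshape(nrows, ncols)
        vals = np.where(vals == nodata, np.nan, vals)
        return cls(values=vals, xllcorner=header["xllcorner"],
                   yllcorner=header["yllcorner"], cellsize=header["cellsize"])

    def write(self, path, nodata: float = -9999.0) -> None:
        out = np.where(np.isnan(self.values), nodata, self.values)
        header = (f"ncols {self.ncols}\nnrows {self.nrows}\n"
                  f"xllcorner {self.xllcorner:g}\nyllcorner {self.yllcorner:g}\n"
                  f"cellsize {self.cellsize:g}\nnodata_value {nodata:g}\n")
        body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out)
        Path(path).write_text(header + body + "\n")


def nearest_cell_extract(grid: AsciiGrid, lat: float, lon: float) -> float:
    """Value at the containing cell, or the nearest non-missing cell.

    Nearness is great-circle distance between the point and cell
    centers; exact ties resolve to the smallest (row, col).
    """
    valid = ~np.isnan(grid.values)
    if not valid.any():
        raise ValueError("grid has no non-missing cells")
    cell = grid.containing_cell(lat, lon)
    if cell is not None and valid[cell]:
        return float(grid.values[cell])
    rows, cols = np.nonzero(valid)
    lats = grid.yllcorner + (grid.nrows - rows - 0.5) * grid.cellsize
    lons = grid.xllcorner + (cols + 0.5) * grid.cellsize
    d = haversine_km(lat, lon, lats, lons)
    best = np.lexsort((cols, rows, np.round(d, 9)))[0]
    return float(grid.values[rows[best], cols[best]])


# ---------------------------------------------------------------------------
# collinearity pruning

def _vif_single(X: np.ndarray, k: int) -> float:
    """VIF of column k: 1 / (1 - R^2) regressing it on the others (with
    intercept). Returns inf for (near-)perfect collinearity."""
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid ** 2) / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def compute_vifs(X: pd.DataFrame) -> pd.Series:
    arr = X.to_numpy(dtype=float)
    if X.shape[1] < 2:
        return pd.Series(1.0, index=X.columns)
    return pd.Series([_vif_single(arr, k) for k in range(arr.shape[1])], index=X.columns)


def vif_prune(X: pd.DataFrame, threshold: float = 4.0,
              preference: list[str] | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop covariates with VIF above ``threshold``.

    One covariate is removed per round: among those exceeding the
    threshold, the least preferred goes (preferred labels listed first
    in ``preference``; unlisted covariates rank after all listed ones,
    later columns dropping first on ties). The audit records each
    round's VIFs and the removal.
    """
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more samples than covariates to compute VIFs")
    preference = list(preference or [])

    def pref_rank(name: str) -> tuple[int, int]:
        cols = list(X.columns)
        if name in preference:
            return (preference.index(name), cols.index(name))
        return (len(preference) + cols.index(name), cols.index(name))

    kept = X.copy()
    audit: list[dict] = []
    for _ in range(X.shape[1]):
        vifs = compute_vifs(kept)
        offenders = vifs[vifs > threshold]
        round_rec = {"vifs": {c: (None if np.isinf(v) else float(v)) for c, v in vifs.items()},
                     "removed": None}
        if offenders.empty:
            audit.append(round_rec)
            break
        drop = max(offenders.index, key=pref_rank)
        if np.isinf(offenders[drop]) and all(o in preference for o in offenders.index):
            warnings.warn(
                f"perfectly collinear covariates all preferred; removing later-listed {drop!r}")
        round_rec["removed"] = drop
        audit.append(round_rec)
        kept = kept.drop(columns=[drop])
    return kept, audit


# ---------------------------------------------------------------------------
# centring and scaling

@dataclass
class Scaling:
    mean: pd.Series
    sd: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean) / self.sd

    def inverse(self, Xs: pd.DataFrame) -> pd.DataFrame:
        return Xs * self.sd + self.mean


def center_scale(X: pd.DataFrame) -> tuple[pd.DataFrame, Scaling]:
    """Centre each column to mean 0 and scale to sample SD 1 (n-1)."""
    sd = X.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance columns: {zero.index.tolist()}")
    scaling = Scaling(mean=X.mean(), sd=sd)
    return scaling.transform(X), scaling


# ---------------------------------------------------------------------------
# assembled design

#: Preference order reflecting covariates previously related to Arctic
#: marine fauna: keep bottom temperature over ice cover, primary
#: productivity over nitrate, SST change over distance to land.
DEFAULT_PREFERENCE = [
    "bottom_temperature", "sst_change", "par", "primary_productivity",
    "water_depth", "ice_cover", "nitrate", "distance_to_land",
]


@dataclass
class EnvDesign:
    """Centred/scaled covariate matrix with its VIF and scaling audit."""

    X: pd.DataFrame
    scaling: Scaling
    vif_audit: list[dict] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)


def prepare_design(metadata: pd.DataFrame, covariates: list[str],
                   samples=None, vif_threshold: float = 4.0,
                   preference: list[str] | None = None) -> EnvDesign:
    """Build the design matrix from sample metadata.

    Selects ``covariates`` columns for the given samples (default: all
    rows with complete covariate data), VIF-prunes at ``vif_threshold``
    with the ecological ``preference`` order, then centres and scales.
    """
    X = metadata.loc[samples if samples is not None else metadata.index, covariates]
    X = X.dropna(axis=0, how="any").astype(float)
    pruned, audit = vif_prune(X, threshold=vif_threshold,
                              preference=preference if preference is not None else DEFAULT_PREFERENCE)
    scaled, scaling = center_scale(pruned)
    dropped = [c for c in covariates if c not in pruned.columns]
    return EnvDesign(X=scaled, scaling=scaling, vif_audit=audit, dropped=dropped)
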