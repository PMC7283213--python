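"""Empirical orthogonal function decomposition of basin SST anomaly fields.

Each basin's anomaly field is decomposed into spatial modes and principal
component (PC) time series via an SVD of the sqrt(cos latitude)-weighted
data matrix, so explained variance fractions are area-true. The leading two
standardized PCs per basin serve as the oceanic columns of the forcing
matrix; the standard deviation divided out (sigma_forcing) is kept so
feedback responses can be reported per one standard deviation of forcing.

Sign convention: each mode is flipped, together with its PC, so the
pattern's area-weighted spatial mean is non-negative — EOF signs are
otherwise arbitrary and this makes results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .preprocess import anomalize

__all__ = [
    "EOFResult",
    "StandardizedForcing",
    "compute_eof",
    "standardize",
    "basin_forcings",
    "build_forcing_matrix",
]


@dataclass
class EOFResult:
    patterns: xr.DataArray          # (mode, lat, lon); orthonormal under cos-lat weights
    pcs: pd.DataFrame               # (time, mode)
    explained_variance_fraction: np.ndarray
    basin: str
    weights: xr.DataArray = field(repr=False, default=None)  # cos(lat) per cell

    def reconstruct(self) -> xr.DataArray:
        """Sum of pattern_k * pc_k over all computed modes."""
        p = self.patterns.values.reshape(self.patterns.sizes["mode"], -1)
        rec = self.pcs.values @ p
        nt = len(self.pcs)
        out = self.patterns.isel(mode=0, drop=True).expand_dims(
            time=self.pcs.index.to_timestamp()
        ).copy(data=rec.reshape((nt,) + self.patterns.shape[1:]))
        return out


@dataclass
class StandardizedForcing:
    """Unit-variance forcing series and the sigma divided out (native units)."""

    values: pd.Series
    label: str
    sigma: float


def compute_eof(afield: xr.DataArray, k: int = 2) -> EOFResult:
    """Leading ``k`` area-weighted EOFs of an anomaly field.

    The input must already be deseasonalized and detrended. Cells missing at
    any time are excluded from the decomposition entirely (and are NaN in
    the returned patterns). Modes are ordered by descending explained
    variance; PCs are mutually uncorrelated by construction.
    """
    da = afield.transpose("time", "lat", "lon")
    vals = da.values.astype(float)
    nt = vals.shape[0]
    flat = vals.reshape(nt, -1)
    valid = np.isfinite(flat).all(axis=0)
    if valid.sum() == 0:
        raise ValueError("no cells with complete records")

    w_cell = np.broadcast_to(
        np.cos(np.deg2rad(da["lat"].values))[:, None], vals.shape[1:]
    ).ravel()[valid]
    x = flat[:, valid]
    x = x - x.mean(axis=0)
    xw = x * np.sqrt(w_cell)

    u, s, vt = np.linalg.svd(xw, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"requested {k} modes but field has rank {rank}")

    total_var = (s**2).sum()
    frac = s[:k] ** 2 / total_var

    pcs = u[:, :k] * s[:k]
    # physical patterns: unweight so that sum_x w_x p_i p_j = delta_ij
    pats = vt[:k] / np.sqrt(w_cell)

    # sign convention: non-negative area-weighted spatial mean of the pattern
    smean = (pats * w_cell).sum(axis=1)
    flip = np.where(smean < 0, -1.0, 1.0)
    pats = pats * flip[:, None]
    pcs = pcs * flip[None, :]

    pat_full = np.full((k, flat.shape[1]), np.nan)
    pat_full[:, valid] = pats
    patterns = xr.DataArray(
        pat_full.reshape((k,) + vals.shape[1:]),
        coords={"mode": np.arange(1, k + 1), "lat": da["lat"], "lon": da["lon"]},
        dims=("mode", "lat", "lon"),
        name="eof_pattern",
    )
    idx = pd.PeriodIndex(da["time"].values, freq="M")
    pcs_df = pd.DataFrame(pcs, index=idx, columns=np.arange(1, k + 1))
    weights = xr.DataArray(
        np.broadcast_to(np.cos(np.deg2rad(da["lat"].values))[:, None], vals.shape[1:]),
        coords={"lat": da["lat"], "lon": da["lon"]},
        dims=("lat", "lon"),
    )
    return EOFResult(patterns, pcs_df, frac, str(afield.name or "field"), weights)


def standardize(result: EOFResult, mode: int) -> StandardizedForcing:
    """Scale a PC to unit sample variance, recording sigma_forcing."""
    pc = result.pcs[mode]
    sigma = float(pc.std(ddof=1))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError(f"mode {mode} has zero-variance PC")
    label = f"{result.basin}-PC{mode}"
    return StandardizedForcing(values=pc / sigma, label=label, sigma=sigma)


def basin_forcings(sst_anomalies: xr.DataArray, basin_name: str, k: int = 2):
    """Leading-k standardized PCs of one basin's anomaly field."""
    res = compute_eof(sst_anomalies, k=k)
    res.basin = basin_name
    return [standardize(res, m) for m in range(1, k + 1)], res


def build_forcing_matrix(
    sst_anomaly_fields: dict[str, xr.DataArray],
    lai: pd.Series,
    sm: pd.Series,
    k: int = 2,
    preprocessed: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the forcing matrix O: 2 PCs per basin + standardized LAI and SM.

    Terrestrial series are anomalized/detrended here unless ``preprocessed``.
    Returns (O, sigma) where sigma holds the native-unit standard deviation
    divided out of each column.
    """
    cols: dict[str, pd.Series] = {}
    sigmas: dict[str, float] = {}
    for name, afield in sst_anomaly_fields.items():
        forcings, _ = basin_forcings(afield, name, k=k)
        for f in forcings:
            cols[f.label] = f.values
            sigmas[f.label] = f.sigma
    for label, series in (("LAI", lai), ("SM", sm)):
        anom = series if preprocessed else anomalize(series)
        sigma = float(anom.std(ddof=1))
        if sigma == 0:
            raise ValueError(f"{label} series has zero variance")
        cols[label] = anom / sigma
        sigmas[label] = sigma
    o = pd.DataFrame(cols)
    return o, pd.Series(sigmas, name="sigma_forcing")
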