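"""Synthetic ocean/land/fire data with known feedback structure.

The generator produces the statistical world the feedback estimator assumes:
slowly evolving forcings with AR(1) (red-noise) memory and prescribed
instantaneous cross-correlations, basin SST fields carrying two leading
spatial modes, and a fire series that responds instantaneously to the
standardized forcings through a known response vector plus short-memory
(i.i.d. Gaussian) noise, on top of a seasonal cycle and linear trend.
Ground-truth parameters travel with the bundle so recovery can be tested.

Cross-forcing correlation is induced by applying a Cholesky factor to the
AR(1) innovations; the innovation covariance is memory-adjusted
(S_ij = corr_ij * (1 - a_i a_j)) so the stationary series hit the target
correlation matrix exactly while keeping each forcing's marginal lag-1
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .preprocess import DEFAULT_BASINS, BasinSpec

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "FORCING_LABELS",
    "default_true_response",
    "gen_forcings",
    "gen_sst_field",
    "gen_fire_series",
    "gen_predictor_suite",
    "make_bundle",
    "write_fixture",
    "read_fixture",
]

#: 16 ocean PC labels (two per basin) + the two terrestrial forcings.
FORCING_LABELS: tuple[str, ...] = tuple(
    f"{b.name}-PC{m}" for b in DEFAULT_BASINS for m in (1, 2)
) + ("LAI", "SM")

ATMOS_LABELS = ("lightning", "low_level_temperature", "low_level_moisture", "wind_speed")
SOCIO_LABELS = ("population_density", "land_cover_change")


def default_forcing_corr(n: int = 18) -> np.ndarray:
    """Default cross-forcing correlation, decaying as 0.5^distance.

    For the canonical 18-forcing layout the two PCs of one basin are kept
    uncorrelated (EOF PCs are orthogonal by construction); correlations act
    within the PC1+terrestrial group and within the PC2 group, each decaying
    as 0.5^|rank difference|. For other widths a plain 0.5^|i-j| matrix is
    used. Both forms are positive definite.
    """
    if n != 18:
        return 0.5 ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    corr = np.eye(18)
    group1 = [0, 2, 4, 6, 8, 10, 12, 14, 16, 17]   # PC1s + LAI + SM
    group2 = [1, 3, 5, 7, 9, 11, 13, 15]           # PC2s
    for group in (group1, group2):
        for a, i in enumerate(group):
            for b, j in enumerate(group):
                corr[i, j] = 0.5 ** abs(a - b)
    return corr


def default_true_response(n: int = 18) -> np.ndarray:
    """Three nonzero responses: tropical Pacific PC1 (+1.0, ENSO-like warming
    enhances burning), tropical Atlantic PC1 (+0.5, Atlantic warm events), and
    soil moisture (-0.7, wetter soils inhibit burning)."""
    r = np.zeros(n)
    r[0] = 1.0                   # TP-PC1
    if n > 2:
        r[2] = 0.5               # TA-PC1
    r[n - 1] = -0.7              # SM
    return r


def _default_fire_cycle() -> np.ndarray:
    # dry-season (boreal winter) burning peak, units kg C m^-2 month^-1
    m = np.arange(12)
    return 0.05 + 0.04 * np.cos(2 * np.pi * (m - 0.5) / 12)


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror a 20-year (240-month) study period
    with 18 forcings of red-noise memory 0.6-0.9 and neighbor correlations
    decaying as 0.5^|i-j|."""

    n_years: int = 20
    start: str = "1997-01"
    n_forcings: int = 18
    ar1_coeffs: np.ndarray | None = None          # per-forcing lag-1 autocorrelation
    forcing_corr: np.ndarray | None = None        # target instantaneous correlation
    true_response: np.ndarray | None = None       # fire units per sigma of forcing
    response_lag: int = 0                         # generative lag (0 = instantaneous)
    fire_noise_sd: float = 1.0
    seasonal_cycle: dict[str, np.ndarray] = dc_field(default_factory=dict)
    trend_slope: dict[str, float] = dc_field(default_factory=dict)
    grid_step: float = 10.0                       # degrees, basin SST grids
    sst_mode_shares: tuple[float, float] = (0.6, 0.25)
    atmos_fire_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        k = self.n_forcings
        if self.ar1_coeffs is None:
            self.ar1_coeffs = np.linspace(0.6, 0.9, k)
        self.ar1_coeffs = np.asarray(self.ar1_coeffs, float)
        if np.any(np.abs(self.ar1_coeffs) >= 1):
            raise ValueError("ar1_coeffs must each satisfy |a| < 1")
        if self.forcing_corr is None:
            self.forcing_corr = default_forcing_corr(k)
        self.forcing_corr = np.asarray(self.forcing_corr, float)
        if not np.allclose(self.forcing_corr, self.forcing_corr.T):
            raise ValueError("forcing_corr must be symmetric")
        if np.linalg.eigvalsh(self.forcing_corr).min() < -1e-10:
            raise ValueError("forcing_corr must be positive semidefinite")
        if self.true_response is None:
            self.true_response = default_true_response(k)
        self.true_response = np.asarray(self.true_response, float)
        if len(self.true_response) != k:
            raise ValueError("true_response length must match n_forcings")
        if self.fire_noise_sd < 0:
            raise ValueError("fire_noise_sd must be >= 0")
        self.seasonal_cycle.setdefault("fire", _default_fire_cycle())
        self.seasonal_cycle.setdefault("sst", 2.0 * np.sin(2 * np.pi * np.arange(12) / 12))
        self.seasonal_cycle.setdefault("lai", 1.5 + 0.5 * np.sin(2 * np.pi * np.arange(12) / 12))
        self.seasonal_cycle.setdefault("sm", 0.2 + 0.05 * np.sin(2 * np.pi * np.arange(12) / 12))
        self.trend_slope.setdefault("fire", -2e-5)   # gentle burned-area decline
        self.trend_slope.setdefault("sst", 1e-3)     # warming trend, K per month
        self.trend_slope.setdefault("lai", 5e-5)
        self.trend_slope.setdefault("sm", 0.0)

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def time_index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")

    def labels(self) -> tuple[str, ...]:
        if self.n_forcings == 18:
            return FORCING_LABELS
        return tuple(f"F{i + 1}" for i in range(self.n_forcings))


@dataclass
class SynthBundle:
    """All generated variables on one monthly time axis, plus the truth."""

    sst_fields: dict[str, xr.DataArray]
    lai: pd.Series
    sm: pd.Series
    fire: pd.Series                    # kg C m^-2 month^-1 (cycle + trend + anomalies)
    burned_area: pd.Series             # fraction per month, in [0, 1]
    atmos: pd.DataFrame
    socio: pd.DataFrame                # annual cadence, constant within year
    forcings: pd.DataFrame             # truth: standardized forcing series
    fire_noise: pd.Series              # truth: realized internal noise
    truth: SynthConfig


# ---------------------------------------------------------------------------


def gen_forcings(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Zero-mean, unit-variance AR(1) forcings with prescribed memory and
    instantaneous cross-correlation. Deterministic given the config seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    a = config.ar1_coeffs
    corr = config.forcing_corr
    k, n = config.n_forcings, config.n_months
    innov_cov = corr * (1.0 - np.outer(a, a))
    # PSD guard: tiny jitter only if needed (exact for valid configs)
    try:
        chol = np.linalg.cholesky(innov_cov)
    except np.linalg.LinAlgError as exc:
        w = np.linalg.eigvalsh(innov_cov).min()
        if w < -1e-8:
            raise ValueError("forcing_corr incompatible with ar1_coeffs (non-PSD innovations)") from exc
        chol = np.linalg.cholesky(innov_cov + (1e-10 - min(w, 0)) * np.eye(k))
    x = np.empty((n, k))
    burn = 200
    z = rng.standard_normal((n + burn, k)) @ chol.T
    state = np.linalg.cholesky(corr + 1e-12 * np.eye(k)) @ rng.standard_normal(k)
    for t in range(n + burn):
        state = a * state + z[t]
        if t >= burn:
            x[t - burn] = state
    return pd.DataFrame(x, index=config.time_index(), columns=list(config.labels()))


def _orthonormal_patterns(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two spatial patterns orthonormal under cos-lat area weights."""
    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, len(lon)))
    p1 = np.ones((len(lat), len(lon)))
    p2 = np.sin(2 * np.pi * (lon[None, :] - lon[0]) / max(np.ptp(lon), 1.0)) * np.ones((len(lat), 1))
    # Gram-Schmidt under the weighted inner product
    p1 = p1 / np.sqrt((w * p1 * p1).sum())
    p2 = p2 - (w * p1 * p2).sum() * p1
    nrm = np.sqrt((w * p2 * p2).sum())
    if nrm < 1e-12:
        raise ValueError("degenerate basin grid: mode-2 pattern vanishes")
    p2 = p2 / nrm
    return p1, p2, w


def gen_sst_field(
    basin: BasinSpec,
    pcs: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
    mode_shares: tuple[float, float] | None = None,
) -> xr.DataArray:
    """Basin SST field = pattern1*pc1 + pattern2*pc2 + white noise + cycle + trend.

    ``mode_shares`` are the fractions of (area-weighted) anomaly variance
    carried by the two modes; the remainder is spatially white noise, so the
    EOF decomposition can be checked against known explained variances.
    """
    shares = config.sst_mode_shares if mode_shares is None else mode_shares
    s1, s2 = shares
    if not (s1 > s2 >= 0 and s1 + s2 <= 1):
        raise ValueError("mode shares must satisfy s1 > s2 >= 0, s1 + s2 <= 1")
    step = config.grid_step
    lat = np.arange(basin.lat_min + step / 2, basin.lat_max, step)
    lon0 = basin.lon_min
    span = (basin.lon_max - basin.lon_min) % 360 or 360
    lon = np.mod(np.arange(lon0 + step / 2, lon0 + span, step), 360.0)
    p1, p2, w = _orthonormal_patterns(lat, np.arange(len(lon)) * step)

    n = config.n_months
    pc1 = pcs.iloc[:, 0].to_numpy()
    pc2 = pcs.iloc[:, 1].to_numpy()
    field = np.sqrt(s1) * pc1[:, None, None] * p1 + np.sqrt(s2) * pc2[:, None, None] * p2
    noise_share = 1.0 - s1 - s2
    if noise_share > 1e-12:
        cell_sd = np.sqrt(noise_share / w.sum())
        field = field + cell_sd * rng.standard_normal((n,) + p1.shape)

    months = config.time_index().month.to_numpy() - 1
    cyc = np.asarray(config.seasonal_cycle["sst"])[months]
    trend = config.trend_slope["sst"] * np.arange(n)
    field = field + (cyc + trend)[:, None, None]

    return xr.DataArray(
        field,
        coords={
            "time": config.time_index().to_timestamp(),
            "lat": lat,
            "lon": lon,
        },
        dims=("time", "lat", "lon"),
        name=f"sst_{basin.name}",
        attrs={"units": "K", "basin": basin.name},
    )


def gen_fire_series(
    forcings: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Fire series responding instantaneously to the standardized forcings.

    fire(t) = sum_j R_j o_j(t - lag) + noise + seasonal cycle + trend, with
    i.i.d. Gaussian noise whose memory is negligible relative to the
    estimator's lag. Returns (fire, realized noise).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    r = config.true_response
    if forcings.shape[1] != len(r):
        raise ValueError("true_response length mismatch with forcing count")
    o = forcings.to_numpy()
    if config.response_lag:
        o = np.roll(o, config.response_lag, axis=0)
        o[: config.response_lag] = 0.0
    signal = o @ r
    noise = config.fire_noise_sd * rng.standard_normal(len(forcings))
    months = forcings.index.month.to_numpy() - 1
    cyc = np.asarray(config.seasonal_cycle["fire"])[months]
    trend = config.trend_slope["fire"] * np.arange(len(forcings))
    fire = pd.Series(signal + noise + cyc + trend, index=forcings.index, name="fire")
    return fire, pd.Series(noise, index=forcings.index, name="fire_noise")


def gen_predictor_suite(
    config: SynthConfig,
    fire_anom: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly atmospheric predictors and annual socioeconomic step series.

    Atmospheric series have configurable contemporaneous correlation with the
    fire anomaly and short memory (AR(1) = 0.2). Socioeconomic series are
    annual random walks reported for the antecedent year, constant within
    each calendar year.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rho = config.atmos_fire_corr
    if not -1 <= rho <= 1:
        raise ValueError("atmos_fire_corr must be in [-1, 1]")
    n = config.n_months
    z = fire_anom.to_numpy()
    sd = z.std(ddof=0)
    zstd = z / sd if sd > 0 else z
    cols = {}
    for name in ATMOS_LABELS:
        eps = np.empty(n)
        e = rng.standard_normal(n) * np.sqrt(1 - 0.2**2)
        prev = rng.standard_normal()
        for t in range(n):
            prev = 0.2 * prev + e[t]
            eps[t] = prev
        cols[name] = rho * zstd + np.sqrt(max(1 - rho**2, 0.0)) * eps
    atmos = pd.DataFrame(cols, index=fire_anom.index)

    years = fire_anom.index.year.unique()
    socio_cols = {}
    for name in SOCIO_LABELS:
        walk = np.cumsum(rng.standard_normal(len(years))) * 0.1 + 1.0
        socio_cols[name] = walk
    socio = pd.DataFrame(socio_cols, index=pd.Index(years, name="year"))
    return atmos, socio


def make_bundle(config: SynthConfig) -> SynthBundle:
    """Generate the full synthetic study: SST basins, LAI, SM, fire, predictors."""
    rng = np.random.default_rng(config.seed)
    forcings = gen_forcings(config, rng)
    labels = list(config.labels())

    sst_fields: dict[str, xr.DataArray] = {}
    if config.n_forcings == 18:
        for i, basin in enumerate(DEFAULT_BASINS):
            pcs = forcings.iloc[:, 2 * i : 2 * i + 2]
            sst_fields[basin.name] = gen_sst_field(basin, pcs, config, rng)

    t = np.arange(config.n_months)
    months = config.time_index().month.to_numpy() - 1

    def raw(name: str, anom: np.ndarray, scale: float) -> pd.Series:
        cyc = np.asarray(config.seasonal_cycle[name])[months]
        return pd.Series(
            scale * anom + cyc + config.trend_slope[name] * t,
            index=config.time_index(),
            name=name,
        )

    lai = raw("lai", forcings[labels[-2]].to_numpy(), 0.3)
    sm = raw("sm", forcings[labels[-1]].to_numpy(), 0.02)

    fire, noise = gen_fire_series(forcings, config, np.random.default_rng(config.seed + 1))
    anomalies = fire - fire.groupby(fire.index.month).transform("mean")
    burned = np.clip(0.02 + 0.01 * anomalies.to_numpy(), 0.0, 1.0)
    burned_area = pd.Series(burned, index=config.time_index(), name="burned_area")

    atmos, socio = gen_predictor_suite(config, anomalies)
    return SynthBundle(
        sst_fields=sst_fields,
        lai=lai,
        sm=sm,
        fire=fire,
        burned_area=burned_area,
        atmos=atmos,
        socio=socio,
        forcings=forcings,
        fire_noise=noise,
        truth=config,
    )


# ---------------------------------------------------------------------------
# fixtures on disk


def _series_to_csv(s: pd.Series | pd.DataFrame, path: Path, time_col: str = "month") -> None:
    df = s.to_frame() if isinstance(s, pd.Series) else s.copy()
    df.insert(0, time_col, df.index.astype(str))
    df.to_csv(path, index=False, float_format="%.17g")


def _series_from_csv(path: Path, time_col: str = "month") -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if time_col not in df.columns:
        raise ValueError(f"{path.name}: missing required {time_col!r} column")
    if time_col == "month":
        df.index = pd.PeriodIndex(df.pop(time_col), freq="M")
    else:
        df.index = pd.Index(df.pop(time_col).astype(int), name="year")
    return df


def write_fixture(bundle: SynthBundle, path: str | Path) -> Path:
    """Write a bundle: NetCDF per basin, CSV per series, YAML truth echo."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for name, da in bundle.sst_fields.items():
        da.to_netcdf(root / f"sst_{name}.nc", engine="scipy")
    for name in ("lai", "sm", "fire", "burned_area", "fire_noise"):
        _series_to_csv(getattr(bundle, name), root / f"{name}.csv")
    _series_to_csv(bundle.forcings, root / "forcings.csv")
    _series_to_csv(bundle.atmos, root / "atmos.csv")
    _series_to_csv(bundle.socio, root / "socio.csv", time_col="year")
    cfg = bundle.truth
    echo = {
        "n_years": cfg.n_years,
        "start": cfg.start,
        "n_forcings": cfg.n_forcings,
        "ar1_coeffs": cfg.ar1_coeffs.tolist(),
        "forcing_corr": cfg.forcing_corr.tolist(),
        "true_response": cfg.true_response.tolist(),
        "response_lag": cfg.response_lag,
        "fire_noise_sd": cfg.fire_noise_sd,
        "seasonal_cycle": {k: np.asarray(v).tolist() for k, v in cfg.seasonal_cycle.items()},
        "trend_slope": dict(cfg.trend_slope),
        "grid_step": cfg.grid_step,
        "sst_mode_shares": list(cfg.sst_mode_shares),
        "atmos_fire_corr": cfg.atmos_fire_corr,
        "seed": cfg.seed,
    }
    (root / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return root


def read_fixture(path: str | Path) -> SynthBundle:
    """Read a bundle written by :func:`write_fixture` (round-trip identity)."""
    root = Path(path)
    raw = yaml.safe_load((root / "config.yaml").read_text())
    cfg = SynthConfig(
        n_years=raw["n_years"],
        start=raw["start"],
        n_forcings=raw["n_forcings"],
        ar1_coeffs=np.array(raw["ar1_coeffs"]),
        forcing_corr=np.array(raw["forcing_corr"]),
        true_response=np.array(raw["true_response"]),
        response_lag=raw["response_lag"],
        fire_noise_sd=raw["fire_noise_sd"],
        seasonal_cycle={k: np.array(v) for k, v in raw["seasonal_cycle"].items()},
        trend_slope=dict(raw["trend_slope"]),
        grid_step=raw["grid_step"],
        sst_mode_shares=tuple(raw["sst_mode_shares"]),
        atmos_fire_corr=raw["atmos_fire_corr"],
        seed=raw["seed"],
    )
    sst_fields = {}
    for f in sorted(root.glob("sst_*.nc")):
        da = xr.open_dataarray(f, engine="scipy").load()
        if "time" not in da.dims:
            raise ValueError(f"{f.name}: missing time coordinate")
        sst_fields[da.attrs.get("basin", f.stem.removeprefix("sst_"))] = da

    def one(name: str) -> pd.Series:
        df = _series_from_csv(root / f"{name}.csv")
        return df.iloc[:, 0].rename(name)

    return SynthBundle(
        sst_fields=sst_fields,
        lai=one("lai"),
        sm=one("sm"),
        fire=one("fire"),
        burned_area=one("burned_area"),
        atmos=_series_from_csv(root / "atmos.csv"),
        socio=_series_from_csv(root / "socio.csv", time_col="year"),
        forcings=_series_from_csv(root / "forcings.csv"),
        fire_noise=one("fire_noise"),
        truth=cfg,
    )
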