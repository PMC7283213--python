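"""Stepwise generalized equilibrium feedback assessment (SGEFA).

The estimator quantifies the instantaneous response R of a fast variable
F(t) (fire carbon emission, burned-area fraction) to a matrix O(t) of slowly
evolving forcings, under the decomposition

    F(t) = R O(t) + N(t),

where N is internal noise with persistence much shorter than the lag tau.
Multiplying by the transposed forcing matrix at an earlier time t - tau and
taking covariances gives C_FO(tau) = R C_OO(tau) + C_NO(tau); because slow
forcings cannot be driven by subsequent fast-variable noise, C_NO(tau) ~ 0
and

    R = C_FO(tau) C_OO(tau)^{-1}.

Sampling error with many (often intercorrelated) forcings is controlled by
backward-stepwise selection on the Akaike information criterion, and the
significance of each retained response is assessed with a Monte Carlo
permutation bootstrap of the fire series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .preprocess import PooledSamples, SeasonWindow, pool_season, season_window

logger = logging.getLogger(__name__)

__all__ = [
    "FeedbackEstimate",
    "lagged_covariance",
    "estimate_response",
    "aic_score",
    "backward_stepwise",
    "bootstrap_significance",
    "assess_feedback",
    "seasonal_feedback_cycle",
    "max_response_season",
    "robustness_count",
    "spatial_response_map",
]

COND_LIMIT = 1e8  # above this, fall back to pseudo-inverse with a warning


@dataclass
class FeedbackEstimate:
    """Response vector with selection flags and bootstrap p-values.

    ``response`` and ``p_value`` are indexed by the retained forcing labels
    only; non-retained forcings are absent (not zero).
    """

    labels: list[str]
    retained: pd.Series                 # bool per forcing label
    response: pd.Series                 # R per retained forcing
    p_value: pd.Series                  # per retained forcing
    tau: int
    season: SeasonWindow | None
    n_samples: int
    c_fo: np.ndarray = field(repr=False, default=None)
    c_oo: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.1) -> pd.Series:
        return self.p_value < alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.labels:
            kept = bool(self.retained[lab])
            rows.append(
                {
                    "season": self.season.index if self.season else 0,
                    "forcing": lab,
                    "retained": kept,
                    "response": self.response[lab] if kept else np.nan,
                    "p_value": self.p_value[lab] if kept else np.nan,
                    "n": self.n_samples,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariance core


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def lagged_covariance(pooled: PooledSamples) -> tuple[np.ndarray, np.ndarray]:
    """Sample lagged covariances (denominator n - 1).

    C_FO[j] = cov(F(t), O_j(t - tau)); C_OO[i, j] = cov(O_i(t), O_j(t - tau)).
    """
    n = len(pooled.f)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    fc = _center(pooled.f)
    ot = _center(pooled.o_t)
    ol = _center(pooled.o_lag)
    c_fo = fc @ ol / (n - 1)
    c_oo = ot.T @ ol / (n - 1)
    return c_fo, c_oo


def _solve_response(c_fo: np.ndarray, c_oo: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(c_oo)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        warnings.warn(
            f"C_OO(tau) condition number {cond:.2e} exceeds {COND_LIMIT:.0e}; "
            "using pseudo-inverse — consider stepwise reduction of the forcing matrix",
            RuntimeWarning,
            stacklevel=3,
        )
        return c_fo @ np.linalg.pinv(c_oo)
    return np.linalg.solve(c_oo.T, c_fo)


def estimate_response(pooled: PooledSamples) -> np.ndarray:
    """R = C_FO(tau) C_OO(tau)^{-1}: fire units per unit (standardized) forcing."""
    k = pooled.o_t.shape[1]
    if len(pooled.f) <= k + 2:
        raise ValueError(
            f"insufficient samples ({len(pooled.f)}) for {k} forcings"
        )
    c_fo, c_oo = lagged_covariance(pooled)
    return _solve_response(c_fo, c_oo)


def _subset(pooled: PooledSamples, idx: np.ndarray) -> PooledSamples:
    return PooledSamples(
        f=pooled.f,
        o_t=pooled.o_t[:, idx],
        o_lag=pooled.o_lag[:, idx],
        times=pooled.times,
        n_dropped=pooled.n_dropped,
        tau=pooled.tau,
        season=pooled.season,
    )


def aic_score(pooled: PooledSamples, subset: np.ndarray | None = None) -> float:
    """AIC = n ln(RSS/n) + 2(k + 1) with RSS from the lagged-covariance fit.

    ``subset=None`` or empty scores the null (noise-only) model, k = 0.
    The +1 counts the noise variance parameter.
    """
    n = len(pooled.f)
    if subset is None or len(subset) == 0:
        rss = float(np.sum(_center(pooled.f) ** 2))
        k = 0
    else:
        sub = _subset(pooled, np.asarray(subset))
        r = estimate_response(sub)
        resid = pooled.f - sub.o_t @ r
        rss = float(np.sum(resid**2))
        k = len(subset)
    if rss <= 0:
        warnings.warn("zero residual sum of squares; AIC -> -inf", RuntimeWarning)
        return -np.inf
    return n * np.log(rss / n) + 2 * (k + 1)


def _approx_se(pooled: PooledSamples, idx: np.ndarray) -> np.ndarray:
    """Bootstrap-free standard errors used only to break stepwise ties."""
    sub = _subset(pooled, idx)
    n = len(sub.f)
    r = estimate_response(sub)
    resid = sub.f - sub.o_t @ r
    sigma2 = float(resid @ resid) / max(n - len(idx) - 1, 1)
    _, c_oo = lagged_covariance(sub)
    s_ll = _center(sub.o_lag).T @ _center(sub.o_lag) / (n - 1)
    a_inv = np.linalg.pinv(c_oo.T)
    cov_r = sigma2 * (a_inv @ s_ll @ a_inv.T) / n
    return np.sqrt(np.maximum(np.diag(cov_r), 1e-300))


def backward_stepwise(
    pooled: PooledSamples, labels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Drop forcings one at a time while AIC improves.

    Starting from the full forcing matrix, remove at each step the single
    forcing whose removal most decreases the AIC; stop when no removal
    decreases it. Ties (equal AIC gain) are broken by removing the forcing
    with the smaller |R|/SE. Returns (retained indices, re-estimated R).
    """
    k = pooled.o_t.shape[1]
    current = list(range(k))
    aic_cur = aic_score(pooled, np.array(current))
    while len(current) > 0:
        cand_aic = np.array(
            [aic_score(pooled, np.array([i for i in current if i != j])) for j in current]
        )
        best = float(cand_aic.min())
        if best >= aic_cur - 1e-12:
            break
        ties = np.where(np.abs(cand_aic - best) <= 1e-10)[0]
        if len(ties) > 1:
            se = _approx_se(pooled, np.array(current))
            r = estimate_response(_subset(pooled, np.array(current)))
            tstats = np.abs(r[ties]) / se[ties]
            drop_pos = ties[int(np.argmin(tstats))]
        else:
            drop_pos = int(ties[0])
        current.pop(drop_pos)
        aic_cur = best
    idx = np.array(current, dtype=int)
    r = estimate_response(_subset(pooled, idx)) if len(idx) else np.array([])
    return idx, r


def _block_permutation(n: int, block: int, rng: np.random.Generator) -> np.ndarray:
    """Permute the order of consecutive blocks, preserving within-block order."""
    starts = np.arange(0, n, block)
    order = rng.permutation(len(starts))
    return np.concatenate([np.arange(s, min(s + block, n)) for s in starts[order]])


def bootstrap_significance(
    pooled: PooledSamples,
    idx: np.ndarray,
    r_hat: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    block: int | None = None,
) -> np.ndarray:
    """Two-sided permutation p-values for each retained response.

    The null distribution is built by re-estimating R on random permutations
    of the pooled fire sample vector with the forcing samples fixed;
    p_j = (1 + #{|R*_j| >= |R_j|}) / (n_iter + 1). ``block`` permutes
    blocks of that many consecutive samples instead of single samples — an
    option for fire series with residual autocorrelation.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} < 100 gives coarse p-values", RuntimeWarning)
    rng = np.random.default_rng() if rng is None else rng
    sub = _subset(pooled, np.asarray(idx))
    n = len(sub.f)
    fc = _center(sub.f)
    ol = _center(sub.o_lag)
    _, c_oo = lagged_covariance(sub)
    inv = np.linalg.pinv(c_oo.T)
    if block is not None and block > 1:
        perms = np.array([_block_permutation(n, block, rng) for _ in range(n_iter)])
    else:
        perms = np.array([rng.permutation(n) for _ in range(n_iter)])
    # permuting F leaves its mean unchanged, so centering commutes with it
    c_fo_star = fc[perms] @ ol / (n - 1)          # (n_iter, k)
    r_star = c_fo_star @ inv.T
    exceed = (np.abs(r_star) >= np.abs(r_hat)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_iter + 1.0)


def assess_feedback(
    pooled: PooledSamples,
    labels: list[str],
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
) -> FeedbackEstimate:
    """Stepwise selection then permutation bootstrap on the retained subset."""
    idx, r = backward_stepwise(pooled)
    if len(idx):
        p = bootstrap_significance(pooled, idx, r, n_iter=n_iter, rng=rng)
    else:
        p = np.array([])
    retained = pd.Series(False, index=labels)
    retained.iloc[idx] = True
    kept_labels = [labels[i] for i in idx]
    c_fo, c_oo = lagged_covariance(pooled)
    return FeedbackEstimate(
        labels=list(labels),
        retained=retained,
        response=pd.Series(r, index=kept_labels, dtype=float),
        p_value=pd.Series(p, index=kept_labels, dtype=float),
        tau=pooled.tau,
        season=pooled.season,
        n_samples=len(pooled.f),
        c_fo=c_fo,
        c_oo=c_oo,
    )


# ---------------------------------------------------------------------------
# summarization products


def seasonal_feedback_cycle(
    fire: pd.Series,
    o: pd.DataFrame,
    tau: int = 1,
    seasons: list[int] | None = None,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    min_samples: int | None = None,
) -> dict[int, FeedbackEstimate]:
    """Run selection + bootstrap independently per 3-month season."""
    rng = np.random.default_rng() if rng is None else rng
    seasons = list(range(1, 13)) if seasons is None else seasons
    labels = list(o.columns)
    min_n = (o.shape[1] + 3) if min_samples is None else min_samples
    out: dict[int, FeedbackEstimate] = {}
    for s in seasons:
        pooled = pool_season(fire, o, season_window(s), tau=tau)
        if len(pooled.f) < min_n:
            logger.warning(
                "season %d skipped: %d samples < minimum %d", s, len(pooled.f), min_n
            )
            continue
        out[s] = assess_feedback(pooled, labels, n_iter=n_iter, rng=rng)
    return out


def max_response_season(
    cycle: dict[int, FeedbackEstimate], forcing: str, alpha: float = 0.1
) -> tuple[int, float] | None:
    """Season of maximum |R| among significant seasons; None if never significant."""
    best: tuple[int, float] | None = None
    for s, est in cycle.items():
        if not est.retained.get(forcing, False):
            continue
        if est.p_value[forcing] >= alpha:
            continue
        r = float(est.response[forcing])
        if best is None or abs(r) > abs(best[1]):
            best = (s, r)
    return best


def robustness_count(
    cycles: list[dict[int, FeedbackEstimate]], alpha: float = 0.1
) -> pd.DataFrame:
    """Count of dataset combinations with a significant response, per season x forcing."""
    if not cycles:
        raise ValueError("need at least one dataset combination")
    labels = next(iter(cycles[0].values())).labels
    seasons = sorted({s for c in cycles for s in c})
    counts = pd.DataFrame(0, index=pd.Index(seasons, name="season"), columns=labels)
    for cyc in cycles:
        for s, est in cyc.items():
            sig = est.significant(alpha)
            for lab in sig.index[sig]:
                counts.loc[s, lab] += 1
    return counts


def spatial_response_map(
    fire_field: xr.DataArray,
    o: pd.DataFrame,
    tau: int = 1,
    season: int | None = None,
    n_iter: int = 500,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
) -> xr.Dataset:
    """Per-grid-cell response and significance; insignificant cells masked.

    The full-matrix estimator and permutation bootstrap run independently at
    each cell (no stepwise per cell). Cells where estimation fails are
    masked and counted.
    """
    rng = np.random.default_rng() if rng is None else rng
    da = fire_field.transpose("time", "lat", "lon")
    idx = pd.PeriodIndex(da["time"].values, freq="M")
    labels = list(o.columns)
    k = len(labels)
    shape = (k,) + da.shape[1:]
    resp = np.full(shape, np.nan)
    pval = np.full(shape, np.nan)
    n_failed = 0
    sw = season_window(season) if season else None
    for i in range(da.shape[1]):
        for j in range(da.shape[2]):
            cell = pd.Series(da.values[:, i, j], index=idx)
            if not np.isfinite(cell.values).all():
                n_failed += 1
                continue
            try:
                pooled = pool_season(cell, o, sw, tau=tau)
                r = estimate_response(pooled)
                all_idx = np.arange(k)
                p = bootstrap_significance(pooled, all_idx, r, n_iter=n_iter, rng=rng)
            except (ValueError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            resp[:, i, j] = r
            pval[:, i, j] = p
    if n_failed:
        logger.warning("spatial_response_map: %d cells failed/masked", n_failed)
    coords = {"forcing": labels, "lat": da["lat"], "lon": da["lon"]}
    r_da = xr.DataArray(resp, coords=coords, dims=("forcing", "lat", "lon"))
    p_da = xr.DataArray(pval, coords=coords, dims=("forcing", "lat", "lon"))
    masked = r_da.where(p_da < alpha)
    return xr.Dataset(
        {"response": masked, "response_unmasked": r_da, "p_value": p_da},
        attrs={"tau": tau, "alpha": alpha, "n_failed_cells": n_failed},
    )
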