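"""Left-censored concentration imputation by regression on order statistics.

A zero net catch means "below this tow's detection limit", not "no plastic".
Because the detection limit is 1/swept_area, every station can have a
*different* limit, so the imputation honors multiple censoring thresholds:

1. Hirsch–Stedinger plotting positions. With the unique limits
   ``b_1 < ... < b_k`` (and ``b_0 = 0``), the exceedance probability of each
   threshold is built recursively from the top down,

       pe_j = pe_{j+1} + A_j / (A_j + B_j) * (1 - pe_{j+1}),

   where ``A_j`` counts detected values in ``[b_j, b_{j+1})`` and ``B_j``
   counts all observations known to lie below ``b_j``. Detected values in
   interval ``j`` get Weibull-type positions spread over
   ``(1 - pe_j, 1 - pe_{j+1})``; values censored at ``b_j`` get positions
   spread over ``(0, 1 - pe_j)``.

2. Ordinary least squares of ``log(value)`` on the standard-normal quantile
   of the plotting position, using detected values only — the working
   assumption (supported by the data) is that corrected concentrations are
   lognormal.

3. Each censored element is predicted at its own plotting position and
   exponentiated. Detected values pass through untouched. A prediction above
   its detection limit is clipped to the limit and counted.

The procedure is deterministic; ``seed`` is reserved for a future
stochastic-imputation mode and currently unused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, PlastrendError

__all__ = [
    "CensoredSeries",
    "ROSResult",
    "hirsch_stedinger_positions",
    "ros_impute",
    "censoring_report",
    "impute_table",
]


@dataclass(frozen=True)
class CensoredSeries:
    """Concentration values with per-element censoring flags and limits.

    ``values`` holds the observed concentration where uncensored (NaN
    otherwise); ``detection_limits`` holds the limit where censored (NaN
    otherwise).
    """

    values: np.ndarray
    censored: np.ndarray
    detection_limits: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.censored, dtype=bool)
        d = np.asarray(self.detection_limits, dtype=float)
        if not (v.shape == c.shape == d.shape):
            raise PlastrendError("values, censored, detection_limits must align")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "censored", c)
        object.__setattr__(self, "detection_limits", d)
        if c.all() and c.size:
            raise InsufficientDataError("series is entirely censored")
        if np.any(v[~c] <= 0) or np.any(~np.isfinite(v[~c])):
            raise PlastrendError("uncensored values must be finite and > 0")
        if np.any(~np.isfinite(d[c])) or np.any(d[c] <= 0):
            raise PlastrendError("censored elements must carry a positive detection limit")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n if self.n else 0.0

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CensoredSeries":
        return cls(df["concentration"].to_numpy(dtype=float),
                   df["censored"].to_numpy(dtype=bool),
                   df["detection_limit"].to_numpy(dtype=float))


def hirsch_stedinger_positions(series: CensoredSeries) -> np.ndarray:
    """Plotting positions (non-exceedance probabilities) for every element.

    Honors multiple detection limits; positions are strictly inside (0, 1).
    """
    v, cen, lim = series.values, series.censored, series.detection_limits
    detects = v[~cen]
    limits = np.unique(lim[cen]) if cen.any() else np.empty(0)
    bounds = np.r_[0.0, limits]                      # b_0 .. b_k
    k = limits.size
    # A_j: detects in [b_j, b_{j+1}); B_j: all observations below b_j
    A = np.zeros(k + 1)
    B = np.zeros(k + 1)
    C = np.zeros(k + 1)                              # censored at b_j (j >= 1)
    upper = np.r_[bounds[1:], np.inf]
    for j in range(k + 1):
        A[j] = np.sum((detects >= bounds[j]) & (detects < upper[j]))
        B[j] = np.sum(detects < bounds[j]) + np.sum(lim[cen] <= bounds[j]) if j > 0 else 0.0
        if j > 0:
            C[j] = np.sum(lim[cen] == bounds[j])
    pe = np.zeros(k + 2)                             # pe[j] = P(exceed b_j); pe[k+1] = 0
    for j in range(k, 0, -1):
        denom = A[j] + B[j]
        frac = A[j] / denom if denom > 0 else 0.0
        pe[j] = pe[j + 1] + frac * (1.0 - pe[j + 1])
    pe[0] = 1.0

    p = np.empty(series.n)
    # detected values, interval by interval, ranked ascending within interval
    det_idx = np.nonzero(~cen)[0]
    for j in range(k + 1):
        in_j = det_idx[(v[det_idx] >= bounds[j]) & (v[det_idx] < upper[j])]
        if in_j.size == 0:
            continue
        order = in_j[np.argsort(v[in_j], kind="stable")]
        r = np.arange(1, order.size + 1)
        p[order] = (1.0 - pe[j]) + (pe[j] - pe[j + 1]) * r / (order.size + 1)
    # censored values, limit by limit, stable order
    cen_idx = np.nonzero(cen)[0]
    for j in range(1, k + 1):
        at_j = cen_idx[lim[cen_idx] == bounds[j]]
        r = np.arange(1, at_j.size + 1)
        p[at_j] = (1.0 - pe[j]) * r / (at_j.size + 1)
    return np.clip(p, 1e-12, 1 - 1e-12)


@dataclass
class ROSResult:
    """Imputed series plus the fitted lognormal model and bookkeeping."""

    values: np.ndarray            # fully numeric series, same order as input
    log_mean: float               # OLS intercept (log-space location)
    log_sd: float                 # OLS slope (log-space scale)
    positions: np.ndarray
    n_clipped: int                # imputations clipped to their limit
    diagnostics: dict = field(default_factory=dict)


def ros_impute(series: CensoredSeries, seed: int | None = None,
               max_censored_frac: float = 0.8) -> ROSResult:
    """Impute censored elements by lognormal regression on order statistics.

    Deterministic: ``seed`` is accepted for interface stability but unused.
    Requires >= 3 uncensored values and a censored fraction at most
    ``max_censored_frac``.
    """
    n_unc = series.n - series.n_censored
    if n_unc < 3:
        raise InsufficientDataError(
            f"ROS needs >= 3 uncensored values, have {n_unc}"
        )
    if series.censored_fraction > max_censored_frac:
        raise InsufficientDataError(
            f"censored fraction {series.censored_fraction:.2f} exceeds "
            f"{max_censored_frac:.2f}"
        )
    p = hirsch_stedinger_positions(series)
    q = stats.norm.ppf(p)
    cen = series.censored
    slope, intercept, r, *_ = stats.linregress(q[~cen], np.log(series.values[~cen]))
    out = series.values.copy()
    pred = np.exp(intercept + slope * q[cen])
    limit = series.detection_limits[cen]
    clipped = pred > limit
    out[cen] = np.where(clipped, limit, pred)
    return ROSResult(
        values=out,
        log_mean=float(intercept),
        log_sd=float(slope),
        positions=p,
        n_clipped=int(clipped.sum()),
        diagnostics={"r_fit": float(r), "n_censored": series.n_censored},
    )


def censoring_report(series: CensoredSeries, basins=None, n_clipped: int = 0) -> dict:
    """Summary of censoring in a series (optionally per basin)."""
    if series.n == 0:
        import warnings

        warnings.warn("censoring report on an empty series", stacklevel=2)
        return {"n": 0, "n_censored": 0, "n_uncensored": 0,
                "censored_fraction": 0.0, "n_clipped": 0}
    rep = {
        "n": series.n,
        "n_censored": series.n_censored,
        "n_uncensored": series.n - series.n_censored,
        "censored_fraction": series.censored_fraction,
        "n_clipped": n_clipped,
    }
    if basins is not None:
        basins = np.asarray(basins)
        rep["by_basin"] = {
            str(b): float(series.censored[basins == b].mean())
            for b in np.unique(basins)
        }
    return rep


def impute_table(stations: pd.DataFrame, group_by: str | None = None,
                 max_censored_frac: float = 0.8) -> tuple[pd.DataFrame, dict]:
    """Replace censored concentrations in a station table via ROS.

    By default the lognormal model is fitted globally (pooling all stations);
    ``group_by="basin"`` fits per basin as a sensitivity option. Returns the
    table (``censored`` reset to False, ``concentration`` complete) and a
    censoring report.
    """
    df = stations.copy()
    total_clipped = 0
    groups = [(None, df.index)] if group_by is None else list(
        df.groupby(group_by).groups.items()
    )
    for _, idx in groups:
        sub = df.loc[idx]
        series = CensoredSeries.from_frame(sub)
        if series.n_censored == 0:
            continue
        res = ros_impute(series, max_censored_frac=max_censored_frac)
        df.loc[idx, "concentration"] = res.values
        total_clipped += res.n_clipped
    report = censoring_report(
        CensoredSeries.from_frame(stations),
        basins=stations["basin"].to_numpy() if "basin" in stations else None,
        n_clipped=total_clipped,
    )
    df["censored"] = False
    return df, report
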