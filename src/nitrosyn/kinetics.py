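"""Nitrification growth kinetics from bottle-experiment time series.

Nitrifier growth is tracked through the chemistry it drives: the oxidation
product accumulates exponentially while the population grows exponentially,
so the specific growth rate is the slope of ln(product) against time over
the exponential phase. For ammonia oxidisers (AOB) the product is
NO2- + NO3- (nitrite plus whatever a partner has already oxidised further);
for nitrite oxidisers (NOB) it is NO3- alone. The exponential window is
chosen algorithmically: the longest contiguous stretch of positive
measurements whose log-linear regression has a positive slope and a
coefficient of determination at or above the acceptance floor (0.99 by
default). Lag is the time from inoculation to the first point of that
window. Substrate dependence of the rate follows the Monod model
mu = mu_max * S / (Ks + S).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

Guild = Literal["AOB", "NOB"]


@dataclass
class GrowthCurve:
    """Time-stamped N-species concentrations for one bottle/replicate.

    Times are hours (strictly increasing); concentrations are μM and any
    subset of nh4/no2/no3 may be present.
    """

    times: np.ndarray
    nh4: np.ndarray | None = None
    no2: np.ndarray | None = None
    no3: np.ndarray | None = None
    replicate_id: str = "r1"
    inoculation_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array with >= 2 points")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        for name in ("nh4", "no2", "no3"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
                if (v < 0).any():
                    raise ValueError(f"{name} concentrations must be >= 0")
                setattr(self, name, v)


@dataclass(frozen=True)
class Window:
    """An accepted exponential-phase regression window (inclusive indices)."""

    start: int
    stop: int
    t_start: float
    t_end: float
    n_points: int
    slope: float
    r2: float


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu: float  # h^-1, slope of ln(product) vs time
    window: tuple[float, float]
    r2: float
    lag_h: float
    n_points: int


@dataclass(frozen=True)
class MonodFit:
    mu_max: float  # h^-1
    ks: float  # μM
    rss: float
    converged: bool
    n_obs: int


def oxidation_product(curve: GrowthCurve, guild: Guild) -> np.ndarray:
    """Oxidation-product series tracking the guild's cumulative activity."""
    if guild == "AOB":
        if curve.no2 is None or curve.no3 is None:
            raise ValueError("AOB product needs both no2 and no3 series")
        product = curve.no2 + curve.no3
    elif guild == "NOB":
        if curve.no3 is None:
            raise ValueError("NOB product needs the no3 series")
        product = curve.no3.copy()
    else:
        raise ValueError(f"unknown guild {guild!r}")
    if not (product > 0).any():
        raise ValueError(f"all-zero oxidation product for guild {guild}: nothing to log")
    return product


_VAR_FLOOR = 1e-12  # ln-scale variance below this is numerical noise


def select_window(series: Sequence[float], times: Sequence[float], r2_min: float = 0.99,
                  min_points: int = 4) -> Window:
    """Pick the exponential-phase window of a product series.

    Considers every contiguous window of at least ``min_points`` samples that
    contains only positive values (zeros mark sub-detection measurements and
    are excluded), and keeps those whose ln(series)-vs-time regression has
    positive slope and R² >= ``r2_min``. Among them the longest wins; ties
    break towards the earliest start.

    Raises ``ValueError`` ("no exponential phase detected") when nothing
    qualifies.
    """
    if not 0 < r2_min <= 1:
        raise ValueError("r2_min must lie in (0, 1]")
    if min_points < 4:
        raise ValueError("min_points must be >= 4")
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series and times must have equal length")

    pos = y > 0
    best: Window | None = None
    # iterate over maximal runs of positive values
    idx = np.flatnonzero(pos)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for rs, re in zip(run_starts, run_ends):
            lo, hi = idx[rs], idx[re]
            n = hi - lo + 1
            if n < min_points:
                continue
            tt = t[lo:hi + 1]
            zz = np.log(y[lo:hi + 1])
            # prefix sums for O(1) regression statistics per (i, j) window
            c1 = np.concatenate(([0.0], np.cumsum(tt)))
            c2 = np.concatenate(([0.0], np.cumsum(tt * tt)))
            cz = np.concatenate(([0.0], np.cumsum(zz)))
            czz = np.concatenate(([0.0], np.cumsum(zz * zz)))
            ctz = np.concatenate(([0.0], np.cumsum(tt * zz)))
            for i in range(n - min_points + 1):
                j = np.arange(i + min_points - 1, n)  # inclusive window ends
                m = (j - i + 1).astype(float)
                st = c1[j + 1] - c1[i]
                stt = c2[j + 1] - c2[i]
                sz = cz[j + 1] - cz[i]
                szz = czz[j + 1] - czz[i]
                stz = ctz[j + 1] - ctz[i]
                sxx = stt - st * st / m
                syy = szz - sz * sz / m
                sxy = stz - st * sz / m
                with np.errstate(divide="ignore", invalid="ignore"):
                    slope = sxy / sxx
                    r2 = np.where(syy > _VAR_FLOOR, sxy * sxy / (sxx * syy), 0.0)
                # a window with numerically zero response variance is flat,
                # not exponential, whatever round-off does to its slope
                ok = (slope > 0) & (syy > _VAR_FLOOR) & (r2 >= r2_min)
                if not ok.any():
                    continue
                jj = j[ok]
                # longest qualifying window for this start
                jbest = int(jj[-1])
                cand_n = jbest - i + 1
                k = np.flatnonzero(ok)[-1]
                cand = Window(
                    start=lo + i, stop=lo + jbest,
                    t_start=float(tt[i]), t_end=float(tt[jbest]),
                    n_points=cand_n, slope=float(slope[k]), r2=float(min(r2[k], 1.0)),
                )
                if best is None or cand.n_points > best.n_points or (
                    cand.n_points == best.n_points and cand.t_start < best.t_start
                ):
                    best = cand
    if best is None:
        raise ValueError("no exponential phase detected")
    return best


def growth_rate(series: Sequence[float], times: Sequence[float], window: Window,
                inoculation_time: float = 0.0) -> GrowthRateEstimate:
    """OLS slope of ln(series) vs time over an accepted window.

    The slope is the specific growth rate μ (h⁻¹; natural log, so the slope
    needs no rescaling). Lag is the window start minus the inoculation time.
    """
    y = np.asarray(series, dtype=float)[window.start:window.stop + 1]
    t = np.asarray(times, dtype=float)[window.start:window.stop + 1]
    if (y <= 0).any():
        raise ValueError("non-positive values inside the regression window")
    res = stats.linregress(t, np.log(y))
    return GrowthRateEstimate(
        mu=float(res.slope),
        window=(float(t[0]), float(t[-1])),
        r2=float(res.rvalue**2),
        lag_h=float(t[0] - inoculation_time),
        n_points=int(t.size),
    )


def monod_mu(S, mu_max: float, ks: float):
    """Monod growth rate μ = μ_max · S / (Ks + S); vectorised over S."""
    if mu_max <= 0 or ks <= 0:
        raise ValueError("mu_max and ks must be positive")
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("substrate concentration must be >= 0")
    out = mu_max * S / (ks + S)
    return float(out) if out.ndim == 0 else out


def fit_monod(pairs: Sequence[tuple[float, float]]) -> MonodFit:
    """Bounded nonlinear least squares of the Monod model on (S, μ) pairs.

    Initialisation: μ_max⁰ = max observed μ; Ks⁰ = the S whose μ is nearest
    μ_max⁰/2. Parameters are constrained positive. On non-convergence the
    best iterate is returned with ``converged=False``.
    """
    S = np.array([p[0] for p in pairs], dtype=float)
    mu = np.array([p[1] for p in pairs], dtype=float)
    if S.size < 3 or np.unique(S).size < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if (mu < 0).any():
        raise ValueError("growth rates must be >= 0")
    if not (mu > 0).any():
        raise ValueError("all growth rates are zero: no kinetics to fit")

    mu_max0 = float(mu.max())
    ks0 = float(S[np.argmin(np.abs(mu - mu_max0 / 2))])
    if ks0 <= 0:
        ks0 = float(np.median(S[S > 0]))

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * S / (p[1] + S) - mu

    res = optimize.least_squares(
        resid, x0=[mu_max0, ks0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    return MonodFit(
        mu_max=float(res.x[0]), ks=float(res.x[1]),
        rss=float(2.0 * res.cost), converged=bool(res.status > 0), n_obs=int(S.size),
    )
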