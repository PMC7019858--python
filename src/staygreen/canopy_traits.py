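"""Thermal time, senescence-curve fitting, and derived canopy traits.

The senescence model is a two-parameter logistic power curve for the
fraction of green leaf area ``y`` as a function of thermal time ``TT``::

    y(TT) = 1 / (1 + (TT / GLA50) ** s)

``GLA50`` is the thermal time (degree-days) at which the green leaf area
has declined to 50% and ``s`` controls the steepness of the decline.
Derived traits: green canopy duration GCD = GLA50 - TT_heading, and leaf
area duration LAD = LAI_max * integral of the curve from heading to
harvest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

__all__ = [
    "ThermalTimeSeries",
    "GreenLeafSeries",
    "SenescenceFit",
    "CanopyTraits",
    "InsufficientSenescenceError",
    "senescence_curve",
    "thermal_time",
    "fit_senescence",
    "green_canopy_duration",
    "gcd_to_days",
    "leaf_area_duration",
    "grain_filling_duration",
    "derived_yield_components",
]


class InsufficientSenescenceError(ValueError):
    """Raised when a green-leaf series shows no decline below 50%."""


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Daily cumulative thermal time from sowing (base temperature 0 degC)."""

    dates: pd.DatetimeIndex
    tmean: np.ndarray
    tt: np.ndarray

    def at(self, date) -> float:
        """Cumulative thermal time (degC d) on the given date."""
        date = pd.Timestamp(date)
        idx = self.dates.get_indexer([date])
        if idx[0] < 0:
            raise KeyError(f"date {date.date()} outside thermal-time range")
        return float(self.tt[idx[0]])


@dataclass(frozen=True)
class GreenLeafSeries:
    """Observed green-leaf-area fractions (%) at increasing thermal times."""

    plot_id: str
    tt: np.ndarray
    green_pct: np.ndarray

    def __post_init__(self):
        tt = np.asarray(self.tt, dtype=float)
        y = np.asarray(self.green_pct, dtype=float)
        if tt.shape != y.shape:
            raise ValueError("tt and green_pct must have equal length")
        if np.any(np.diff(tt) <= 0):
            raise ValueError("thermal times must be strictly increasing")
        if np.any((y < 0) | (y > 100)):
            raise ValueError("green fractions must lie in [0, 100]%")
        object.__setattr__(self, "tt", tt)
        object.__setattr__(self, "green_pct", y)


@dataclass(frozen=True)
class SenescenceFit:
    """Fitted senescence-curve parameters for one plot time course."""

    gla50: float
    s: float
    rss: float
    n_points: int
    converged: bool
    plot_id: str = ""

    def predict(self, tt) -> np.ndarray:
        """Green leaf area (%) predicted at thermal time(s) ``tt``."""
        return 100.0 * senescence_curve(np.asarray(tt, dtype=float), self.gla50, self.s)


@dataclass(frozen=True)
class CanopyTraits:
    gcd: float
    lad: float
    tt_heading: float
    tt_harvest: float
    lai_max: float
    grain_filling_duration: float | None = None
    warnings: tuple = field(default_factory=tuple)


def senescence_curve(tt, gla50: float, s: float):
    """Green leaf fraction (0..1) of the logistic power senescence model.

    Evaluated in log space so large steepness values do not overflow.
    """
    tt = np.asarray(tt, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        log_ratio = np.where(tt > 0, np.log(tt / gla50), -np.inf)
        z = s * log_ratio
        out = np.where(z > 500, 0.0, 1.0 / (1.0 + np.exp(np.minimum(z, 500))))
    return out


def thermal_time(weather: pd.DataFrame, sowing_date, end_date=None) -> ThermalTimeSeries:
    """Cumulative daily mean temperature from sowing, base 0 degC.

    ``weather`` needs a ``date`` column plus either ``tmean`` or both
    ``tmin``/``tmax`` (mean taken as their midpoint). Daily means below
    0 degC contribute 0 degree-days. The series starts at the sowing day
    with TT = 0 (the sowing day itself accumulates nothing).

    Raises ``ValueError`` on missing days or a sowing date outside the
    weather record.
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values("date").reset_index(drop=True)
    if "tmean" in w.columns:
        tmean = w["tmean"].astype(float).to_numpy()
    elif {"tmin", "tmax"}.issubset(w.columns):
        tmean = ((w["tmin"].astype(float) + w["tmax"].astype(float)) / 2.0).to_numpy()
    else:
        raise ValueError("weather table needs a 'tmean' column or 'tmin'+'tmax'")
    if np.isnan(tmean).any():
        bad = w.loc[np.isnan(tmean), "date"].dt.date.tolist()
        raise ValueError(f"missing temperature on {bad[:5]}")

    sowing = pd.Timestamp(sowing_date)
    end = pd.Timestamp(end_date) if end_date is not None else w["date"].iloc[-1]
    if sowing < w["date"].iloc[0] or sowing > w["date"].iloc[-1]:
        raise ValueError("sowing date outside weather range")
    if end > w["date"].iloc[-1]:
        raise ValueError("end date outside weather range")

    mask = (w["date"] >= sowing) & (w["date"] <= end)
    dates = pd.DatetimeIndex(w.loc[mask, "date"])
    expected = pd.date_range(sowing, end, freq="D")
    if len(dates) != len(expected) or not (dates == expected).all():
        missing = expected.difference(dates)
        raise ValueError(f"weather record has gaps: {[d.date() for d in missing[:5]]}")

    t = w.loc[mask, "date"].map(dict(zip(w["date"], tmean))).to_numpy(dtype=float)
    daily = np.maximum(t, 0.0)
    daily[0] = 0.0  # sowing day anchors TT at zero
    tt = np.cumsum(daily)
    return ThermalTimeSeries(dates=dates, tmean=t, tt=tt)


def _initial_guess(tt: np.ndarray, y_frac: np.ndarray) -> tuple[float, float]:
    # GLA50 from linear interpolation of the 50% crossing; s from the slope
    # of log(1/y - 1) on log(TT) over interior points (log-linearised model).
    eps = 1e-4
    yc = np.clip(y_frac, eps, 1 - eps)
    below = np.nonzero(y_frac < 0.5)[0]
    i = below[0]
    if i == 0:
        gla50 = tt[0]
    else:
        y0, y1 = y_frac[i - 1], y_frac[i]
        frac = (y0 - 0.5) / (y0 - y1) if y0 != y1 else 0.5
        gla50 = tt[i - 1] + frac * (tt[i] - tt[i - 1])
    interior = (yc > eps) & (yc < 1 - eps) & (tt > 0)
    if interior.sum() >= 2:
        lx = np.log(tt[interior])
        lz = np.log(1.0 / yc[interior] - 1.0)
        slope = np.polyfit(lx, lz, 1)[0]
        s0 = float(np.clip(slope, 0.5, 200.0))
    else:
        s0 = 10.0
    return float(max(gla50, 1.0)), s0


def fit_senescence(series: GreenLeafSeries, max_restarts: int = 5) -> SenescenceFit:
    """Least-squares fit of the senescence curve to one green-leaf series.

    Observations are rescaled to the unit interval internally, so percent
    and fraction inputs give identical parameter estimates. Requires at
    least three points and at least one observation below 50% green (the
    decline must constrain the curve); an all-green series raises
    ``InsufficientSenescenceError``.
    """
    tt = series.tt
    # percent or fraction input: rescale to the unit interval either way
    scale = 100.0 if np.nanmax(series.green_pct) > 1.0 else 1.0
    y = series.green_pct / scale
    if len(tt) < 3:
        raise ValueError("need at least 3 observation points")
    if not np.any(y < 0.5):
        raise InsufficientSenescenceError(
            f"insufficient senescence signal for {series.plot_id!r}: "
            "no observation below 50% green"
        )
    if np.any(tt <= 0):
        raise ValueError("thermal times must be positive")

    gla0, s0 = _initial_guess(tt, y)
    hi_gla = 2.0 * tt[-1]
    bounds = ([1e-6, 1e-6], [hi_gla, 200.0])

    def resid(theta):
        return senescence_curve(tt, theta[0], theta[1]) - y

    best = None
    starts = [(gla0, s0)]
    rng = np.random.default_rng(0)  # fixed jitter for deterministic restarts
    for _ in range(max_restarts):
        starts.append(
            (
                float(np.clip(gla0 * rng.uniform(0.7, 1.3), 1.0, hi_gla)),
                float(np.clip(s0 * rng.uniform(0.5, 2.0), 0.5, 200.0)),
            )
        )
    for x0 in starts:
        try:
            res = optimize.least_squares(resid, x0=x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20:
            break
    if best is None:
        return SenescenceFit(np.nan, np.nan, np.nan, len(tt), False, series.plot_id)
    gla50, s = best.x
    rss = float(2.0 * best.cost)  # least_squares cost is 0.5 * sum(resid^2)
    return SenescenceFit(float(gla50), float(s), rss, len(tt), bool(best.success), series.plot_id)


def green_canopy_duration(fit: SenescenceFit, tt_heading: float) -> float:
    """GCD (degC d): fitted GLA50 minus thermal time at heading."""
    if not fit.converged:
        raise ValueError("senescence fit did not converge; GCD undefined")
    if tt_heading <= 0:
        raise ValueError("tt_heading must be positive")
    gcd = fit.gla50 - tt_heading
    if gcd < 0:
        warnings.warn(
            f"negative GCD ({gcd:.1f} degC d): canopy halved before heading", stacklevel=2
        )
    return float(gcd)


def gcd_to_days(delta_gcd: float, mean_temperature: float) -> float:
    """Convert a GCD difference (degC d) to calendar days at a mean temperature."""
    if mean_temperature <= 0:
        raise ValueError("mean temperature must be positive")
    return delta_gcd / mean_temperature


def leaf_area_duration(
    fit: SenescenceFit, tt_heading: float, tt_harvest: float, lai_max: float
) -> float:
    """LAD: integral of the senescence curve over [heading, harvest] x LAI_max."""
    if not fit.converged:
        raise ValueError("senescence fit did not converge; LAD undefined")
    if tt_harvest <= tt_heading:
        raise ValueError("tt_harvest must exceed tt_heading")
    if lai_max < 0:
        raise ValueError("lai_max must be non-negative")
    if lai_max == 0:
        return 0.0
    val, _ = integrate.quad(
        lambda t: senescence_curve(t, fit.gla50, fit.s),
        tt_heading,
        tt_harvest,
        epsabs=1e-8,
        epsrel=1e-10,
        limit=200,
        points=[fit.gla50] if tt_heading < fit.gla50 < tt_harvest else None,
    )
    return float(val * lai_max)


def grain_filling_duration(tt_bbch59: float, tt_bbch87: float) -> float:
    """Thermal-time span from end of heading (BBCH59) to hard dough (BBCH87)."""
    if tt_bbch59 <= 0 or tt_bbch87 <= 0:
        raise ValueError("thermal times must be positive")
    if tt_bbch87 < tt_bbch59:
        raise ValueError("hard-dough before heading")
    return tt_bbch87 - tt_bbch59


def derived_yield_components(
    yield_g_m2: float | None = None,
    biomass_g_m2: float | None = None,
    harvest_index: float | None = None,
    spikes_m2: float | None = None,
    grains_per_spike: float | None = None,
    tgw_g: float | None = None,
) -> dict:
    """Close the yield-component identities from whichever inputs are given.

    HI = yield / biomass, biomass = yield / HI, grains per m2 =
    spikes per m2 x grains per spike, and yield = grains per m2 x TGW/1000.
    """
    out: dict[str, float] = {}
    if yield_g_m2 is not None:
        out["yield_g_m2"] = float(yield_g_m2)
    if biomass_g_m2 is not None:
        out["biomass_g_m2"] = float(biomass_g_m2)
    if harvest_index is not None:
        out["harvest_index"] = float(harvest_index)

    if "yield_g_m2" in out and "biomass_g_m2" in out and "harvest_index" not in out:
        if out["biomass_g_m2"] == 0:
            raise ZeroDivisionError("biomass is zero; harvest index undefined")
        out["harvest_index"] = out["yield_g_m2"] / out["biomass_g_m2"]
    elif "yield_g_m2" in out and "harvest_index" in out and "biomass_g_m2" not in out:
        if out["harvest_index"] == 0:
            raise ZeroDivisionError("harvest index is zero; biomass undefined")
        out["biomass_g_m2"] = out["yield_g_m2"] / out["harvest_index"]

    if spikes_m2 is not None and grains_per_spike is not None:
        out["spikes_m2"] = float(spikes_m2)
        out["grains_per_spike"] = float(grains_per_spike)
        out["grains_m2"] = float(spikes_m2) * float(grains_per_spike)
        if tgw_g is not None:
            out["tgw_g"] = float(tgw_g)
            out.setdefault("yield_g_m2", out["grains_m2"] * float(tgw_g) / 1000.0)
    elif tgw_g is not None:
        out["tgw_g"] = float(tgw_g)
    return out


def fit_plot_table(
    scorings: pd.DataFrame,
    phenology: pd.DataFrame | None = None,
    lai: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the senescence curve per plot and derive canopy traits.

    ``scorings`` is long format with columns ``plot`` (or cultivar/season/rep
    triplet), ``tt`` and ``green_pct``. Optional ``phenology`` supplies
    per-plot ``tt_heading``/``tt_harvest`` and ``lai`` supplies ``lai_max``;
    where available GCD and LAD are added. Unconverged or degenerate fits
    yield NaN traits with ``converged = False``.
    """
    keys = [c for c in ("cultivar", "season", "rep") if c in scorings.columns]
    if not keys:
        keys = ["plot"]
    rows = []
    for key, grp in scorings.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        plot_id = "/".join(str(k) for k in key)
        grp = grp.sort_values("tt")
        rec = dict(zip(keys, key))
        try:
            series = GreenLeafSeries(plot_id, grp["tt"].to_numpy(), grp["green_pct"].to_numpy())
            fit = fit_senescence(series)
        except (ValueError, InsufficientSenescenceError):
            rec.update(gla50=np.nan, s=np.nan, rss=np.nan, converged=False,
                       gcd=np.nan, lad=np.nan)
            rows.append(rec)
            continue
        rec.update(gla50=fit.gla50, s=fit.s, rss=fit.rss, converged=fit.converged)
        meta: dict[str, float] = {}
        for aux in (phenology, lai):
            if aux is not None:
                sel = aux
                for k, v in zip(keys, key):
                    if k in sel.columns:
                        sel = sel[sel[k] == v]
                if len(sel):
                    meta.update(sel.iloc[0].to_dict())
        if fit.converged and "tt_heading" in meta and np.isfinite(meta["tt_heading"]):
            rec["gcd"] = green_canopy_duration(fit, float(meta["tt_heading"]))
            if "tt_harvest" in meta and "lai_max" in meta:
                rec["lad"] = leaf_area_duration(
                    fit, float(meta["tt_heading"]), float(meta["tt_harvest"]), float(meta["lai_max"])
                )
            else:
                rec["lad"] = np.nan
        else:
            rec["gcd"] = np.nan
            rec["lad"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
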