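"""Breeding-progress quantification from adjusted cultivar means.

Cultivars are ordered by year of release and summarised in overlapping
sliding windows of a fixed number of cultivars; the regression of window
trait mean on window mean year gives the absolute progress (trait units
per year), and the ratio of the regression predictions at two reference
years (default 2010 vs 1970) gives the relative progress in percent
superiority of the modern cultivar. A continuous two-phase segmented
regression locates trend breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowSeries",
    "ProgressEstimate",
    "SegmentedFit",
    "sliding_window",
    "absolute_progress",
    "relative_progress",
    "segmented_regression",
    "trait_correlations",
    "progress_report",
]


@dataclass(frozen=True)
class WindowSeries:
    """Sliding-window summary of a trait over the release-year ordering."""

    trait: str
    mean_year: np.ndarray
    trait_mean: np.ndarray
    trait_sd: np.ndarray
    members: list[tuple[str, ...]]
    window_size: int

    def __len__(self) -> int:
        return len(self.mean_year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_year": self.mean_year,
                "trait_mean": self.trait_mean,
                "trait_sd": self.trait_sd,
                "members": ["|".join(m) for m in self.members],
            }
        )


@dataclass(frozen=True)
class ProgressEstimate:
    trait: str
    slope: float  # absolute progress, trait units per year
    intercept: float
    r2: float
    n_windows: int
    relative_pct: float | None = None
    ref_years: tuple[int, int] = (1970, 2010)

    def predict(self, year: float) -> float:
        return self.intercept + self.slope * year


@dataclass(frozen=True)
class SegmentedFit:
    breakpoint_year: float
    slope_before: float
    slope_after: float
    intercept: float
    r2: float
    rss: float
    rss_single_line: float
    breakpoint_supported: bool

    @property
    def rss_improvement(self) -> float:
        """Fractional RSS reduction of the two-phase fit over a single line."""
        if self.rss_single_line == 0:
            return 0.0
        return 1.0 - self.rss / self.rss_single_line


def sliding_window(
    blues: pd.DataFrame,
    trait: str,
    window_size: int = 10,
    stride: int = 1,
    value_col: str = "blue",
) -> WindowSeries:
    """Overlapping windows of ``window_size`` cultivars ordered by release year.

    ``blues`` needs columns ``cultivar``, ``year_of_release``, ``trait`` and
    the value column. Cultivars without a release year are excluded; ties
    in release year are broken by cultivar name so the ordering is
    deterministic. Window count is ``n - window_size + 1`` at stride 1.
    """
    df = blues[blues["trait"] == trait] if "trait" in blues.columns else blues
    if "season" in df.columns:
        df = df[df["season"].isna()] if df["season"].isna().any() else df
    df = df.dropna(subset=["year_of_release", value_col])
    df = df.drop_duplicates("cultivar")
    df = df.sort_values(["year_of_release", "cultivar"]).reset_index(drop=True)
    n = len(df)
    if n < window_size:
        raise ValueError(f"only {n} cultivars with release year; window needs {window_size}")
    years = df["year_of_release"].to_numpy(dtype=float)
    vals = df[value_col].to_numpy(dtype=float)
    names = df["cultivar"].to_numpy()

    starts = range(0, n - window_size + 1, stride)
    mean_year, tmean, tsd, members = [], [], [], []
    for i in starts:
        sl = slice(i, i + window_size)
        mean_year.append(years[sl].mean())
        tmean.append(vals[sl].mean())
        tsd.append(vals[sl].std(ddof=1))
        members.append(tuple(names[sl]))
    return WindowSeries(
        trait=trait,
        mean_year=np.asarray(mean_year),
        trait_mean=np.asarray(tmean),
        trait_sd=np.asarray(tsd),
        members=members,
        window_size=window_size,
    )


def absolute_progress(ws: WindowSeries) -> ProgressEstimate:
    """OLS of window trait mean on window mean year: slope is the gain/year."""
    if len(ws) < 2:
        raise ValueError("need at least 2 windows for a regression")
    if np.ptp(ws.mean_year) == 0:
        raise ValueError("zero variance in window mean year")
    res = stats.linregress(ws.mean_year, ws.trait_mean)
    return ProgressEstimate(
        trait=ws.trait,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_windows=len(ws),
    )


def relative_progress(
    pe: ProgressEstimate, year_start: int = 1970, year_end: int = 2010
) -> float:
    """Percent superiority of the ``year_end`` prediction over ``year_start``.

    100 * (yhat(end) / yhat(start) - 1); undefined when the start
    prediction is not positive on the trait scale.
    """
    y0 = pe.predict(year_start)
    y1 = pe.predict(year_end)
    if y0 <= 0:
        raise ValueError(
            f"prediction at {year_start} is {y0:.3g} <= 0; relative progress undefined"
        )
    return float(100.0 * (y1 / y0 - 1.0))


def _two_phase_fit(x: np.ndarray, y: np.ndarray, bp: float):
    # continuous hinge basis: y = a + b*x + d*max(x - bp, 0)
    H = np.column_stack([np.ones_like(x), x, np.maximum(x - bp, 0.0)])
    beta, *_ = np.linalg.lstsq(H, y, rcond=None)
    resid = y - H @ beta
    return beta, float(resid @ resid)


def segmented_regression(ws: WindowSeries, min_points_per_phase: int = 2) -> SegmentedFit:
    """Continuous two-phase fit with exhaustive breakpoint search.

    Candidate breakpoints are the window mean years (excluding the phase
    edges); the candidate minimising the residual sum of squares wins, with
    ties going to the earliest year. A two-phase RSS improvement below 1%
    over the single straight line is reported as unsupported.
    """
    if len(ws) < 6:
        raise ValueError("need at least 6 windows for segmented regression")
    x, y = ws.mean_year, ws.trait_mean
    res = stats.linregress(x, y)
    resid1 = y - (res.intercept + res.slope * x)
    rss1 = float(resid1 @ resid1)

    candidates = np.unique(x)[min_points_per_phase:-min_points_per_phase]
    if len(candidates) == 0:
        raise ValueError("no interior breakpoint candidates")
    best_bp, best_beta, best_rss = None, None, np.inf
    for bp in candidates:  # ascending: ties keep the earliest year
        beta, rss = _two_phase_fit(x, y, bp)
        if rss < best_rss - 1e-12:
            best_bp, best_beta, best_rss = bp, beta, rss
    if best_bp is None:
        warnings.warn("all breakpoint candidates tie; returning earliest", stacklevel=2)
        best_bp = candidates[0]
        best_beta, best_rss = _two_phase_fit(x, y, best_bp)

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_rss / tss if tss > 0 else 1.0
    improvement = 1.0 - best_rss / rss1 if rss1 > 0 else 0.0
    return SegmentedFit(
        breakpoint_year=float(best_bp),
        slope_before=float(best_beta[1]),
        slope_after=float(best_beta[1] + best_beta[2]),
        intercept=float(best_beta[0]),
        r2=float(r2),
        rss=best_rss,
        rss_single_line=rss1,
        breakpoint_supported=bool(improvement >= 0.01),
    )


def trait_correlations(
    blues: pd.DataFrame, trait_pairs, value_col: str = "blue"
) -> pd.DataFrame:
    """Pearson correlations between trait BLUEs, pairwise-complete.

    Returns one row per pair with r, r2, two-sided p-value and n.
    """
    if "season" in blues.columns and blues["season"].isna().any():
        blues = blues[blues["season"].isna()]
    wide = blues.pivot_table(index="cultivar", columns="trait", values=value_col,
                             aggfunc="first")
    rows = []
    for a, b in trait_pairs:
        for t in (a, b):
            if t not in wide.columns:
                raise KeyError(f"trait {t!r} not in BLUE table")
        sub = pd.DataFrame({"a": wide[a], "b": wide[b]}).dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
        if sub["a"].std() == 0 or sub["b"].std() == 0:
            raise ValueError(f"zero variance in ({a}, {b})")
        r, p = stats.pearsonr(sub["a"], sub["b"])
        rows.append({"trait_a": a, "trait_b": b, "r": float(r), "r2": float(r**2),
                     "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def progress_report(
    blues: pd.DataFrame,
    traits,
    window_size: int = 10,
    ref_years: tuple[int, int] = (1970, 2010),
    segmented: bool = False,
) -> pd.DataFrame:
    """Per-trait absolute/relative progress table (one row per trait)."""
    rows = []
    for trait in traits:
        ws = sliding_window(blues, trait, window_size=window_size)
        pe = absolute_progress(ws)
        rec = {
            "trait": trait,
            "absolute": pe.slope,
            "r2": pe.r2,
            "relative_pct": relative_progress(pe, *ref_years),
            "n_windows": len(ws),
        }
        if segmented and len(ws) >= 6:
            sf = segmented_regression(ws)
            rec.update(
                breakpoint_year=sf.breakpoint_year,
                slope_before=sf.slope_before,
                slope_after=sf.slope_after,
                breakpoint_supported=sf.breakpoint_supported,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
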