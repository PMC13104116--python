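"""Longitudinal series: baseline normalization, daily interpolation,
sliding-window lag correlation, and timepoint statistics.

Post-operative metrics are measured on a sparse day grid (day 1 is the
baseline — the first day after surgery, since no pre-surgery measurement
exists).  Series are normalized to the cross-animal day-1 mean, linearly
interpolated to daily resolution over days 1–56, and compared across
modalities with a lagged sliding-window Pearson correlation: the first
window is fixed at day 1, the second slides by a lag L, and the best lag
is the grid argmax of R over window widths {7, 14, 21, 28, 35} days.

Timepoint comparisons follow a normality-gated route: Shapiro–Wilk per
day, then repeated-measures one-way ANOVA with Tukey's post hoc test when
every day passes, otherwise the Friedman test with Dunn's post hoc test
(Bonferroni-corrected).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import LongitudinalSeries

__all__ = [
    "LongitudinalSeries",
    "DailySeries",
    "LagCorrelationResult",
    "StatsReport",
    "normalize_to_baseline",
    "interpolate_daily",
    "lag_correlation",
    "best_lag",
    "compare_timepoints",
]

DEFAULT_WIDTHS = (7, 14, 21, 28, 35)


@dataclass(frozen=True)
class DailySeries:
    """Values on consecutive integer days; measured days keep their exact
    values, the rest are linear interpolants (no extrapolation)."""

    days: np.ndarray
    values: np.ndarray
    measured: np.ndarray  # bool flag per day

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "measured", np.asarray(self.measured, dtype=bool))
        if not (len(days) == len(self.values) == len(self.measured)):
            raise ValueError("days, values and measured must align")
        if len(days) and np.any(np.diff(days) != 1):
            raise ValueError("days must be consecutive integers")

    def value_on(self, day: int) -> float:
        idx = day - self.days[0]
        if idx < 0 or idx >= len(self.days):
            raise KeyError(f"day {day} outside the interpolated range")
        return float(self.values[idx])

    def covers(self, day: int) -> bool:
        return self.days[0] <= day <= self.days[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.days, "value": self.values, "measured": self.measured})


def normalize_to_baseline(
    series: list[LongitudinalSeries], baseline_day: int = 1
) -> list[LongitudinalSeries]:
    """Divide every value by the cross-animal mean of baseline-day values.

    Normalization is per modality: the baseline average is the mean of the
    baseline-day values across all animals of that modality, so the mean
    of normalized baseline-day values is exactly 1 while inter-animal
    baseline variability is retained.
    """
    by_modality: dict[str, list[LongitudinalSeries]] = {}
    for s in series:
        by_modality.setdefault(s.modality, []).append(s)
    out: list[LongitudinalSeries] = []
    for modality, group in by_modality.items():
        baselines = []
        for s in group:
            hit = np.flatnonzero(s.days == baseline_day)
            if len(hit) == 0:
                raise ValueError(
                    f"animal {s.animal!r} ({modality}) has no value on "
                    f"baseline day {baseline_day}")
            baselines.append(s.values[hit[0]])
        avg = float(np.mean(baselines))
        if avg == 0:
            raise ValueError(f"zero baseline average for modality {modality!r}")
        for s in group:
            out.append(LongitudinalSeries(
                animal=s.animal, modality=s.modality,
                days=s.days, values=s.values / avg))
    return out


def interpolate_daily(
    series: LongitudinalSeries, day_range: tuple[int, int] = (1, 56)
) -> DailySeries:
    """Piecewise-linear interpolation onto integer days.

    Measured days keep their exact values; the output covers the
    intersection of ``day_range`` with [first, last] measured day — there
    is no extrapolation.
    """
    if len(np.unique(series.days)) != len(series.days):
        raise ValueError("duplicate measured days")
    lo = max(day_range[0], int(series.days[0]))
    hi = min(day_range[1], int(series.days[-1]))
    if hi < lo:
        raise ValueError("day range does not overlap the measured span")
    days = np.arange(lo, hi + 1)
    values = np.interp(days, series.days, series.values)
    measured = np.isin(days, series.days)
    return DailySeries(days=days, values=values, measured=measured)


@dataclass(frozen=True)
class LagCorrelationResult:
    """Grid of (window width, lag) → Pearson R with the best lag.

    The fixed window always starts at day 1; the sliding window starts at
    day 1 + lag.  ``grid`` has columns width, lag, r, p, n, available.
    The headline lag maximizes the mean R across available widths (ties →
    smallest lag): short windows over a monotone segment of a smooth
    recovery curve correlate near 1 at many lags, so a single-cell argmax
    is unstable while the width-averaged profile peaks at the true offset.
    ``lag_scores`` holds that per-lag mean-R profile.

    The p-values use the t transform of R with n equal to the window
    width; because interpolated days are not independent measurements the
    effective n is smaller — flagged in ``caveat``.
    """

    grid: pd.DataFrame
    lag_scores: pd.Series  # lag → mean R across available widths
    best: tuple[int, int, float, float]  # (lag, width, r, p)
    caveat: str = ("p-values assume n = window width; linear interpolation "
                   "inflates the effective sample size")


def lag_correlation(
    fixed: DailySeries,
    sliding: DailySeries,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    max_lag: int = 20,
    start_day: int = 1,
) -> LagCorrelationResult:
    """Sliding-window lagged Pearson correlation between two daily series.

    For each width w and lag L ≥ 0, correlate fixed[start … start+w−1]
    against sliding[start+L … start+L+w−1].  Cells whose windows exceed
    either series' coverage are marked unavailable.  The headline lag is
    the argmax of the mean R across available widths, ties resolved to the
    smallest lag; the reported (R, p, width) are those of the best cell at
    that lag (ties → smallest width).
    """
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    rows = []
    for w, L in itertools.product(widths, range(max_lag + 1)):
        f_days = np.arange(start_day, start_day + w)
        s_days = f_days + L
        ok = (fixed.covers(f_days[0]) and fixed.covers(f_days[-1])
              and sliding.covers(s_days[0]) and sliding.covers(s_days[-1]))
        if not ok:
            rows.append({"width": w, "lag": L, "r": np.nan, "p": np.nan,
                         "n": w, "available": False})
            continue
        x = np.array([fixed.value_on(d) for d in f_days])
        y = np.array([sliding.value_on(d) for d in s_days])
        if x.std() == 0 or y.std() == 0:
            rows.append({"width": w, "lag": L, "r": np.nan, "p": np.nan,
                         "n": w, "available": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"width": w, "lag": L, "r": float(r), "p": float(p),
                     "n": w, "available": True})
    grid = pd.DataFrame(rows)
    avail = grid[grid["available"]]
    if avail.empty:
        raise ValueError("entire lag-correlation grid is unavailable")
    lag_scores = avail.groupby("lag")["r"].mean()
    best_lag_ = int(lag_scores.index[np.argmax(lag_scores.to_numpy())])
    at_lag = avail[avail["lag"] == best_lag_].sort_values(
        ["r", "width"], ascending=[False, True]).iloc[0]
    best = (best_lag_, int(at_lag["width"]), float(at_lag["r"]),
            float(at_lag["p"]))
    return LagCorrelationResult(grid=grid, lag_scores=lag_scores, best=best)


def best_lag(result: LagCorrelationResult) -> tuple[int, float, float, int]:
    """(lag days, R, p, width) of the grid argmax (ties → smallest lag,
    then smallest width)."""
    lag, width, r, p = result.best
    return lag, r, p, width


def _stars(p: float) -> str:
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


@dataclass(frozen=True)
class StatsReport:
    """Outcome of a timepoint comparison with the route recorded."""

    test_name: str
    statistic: float
    p_value: float
    df: tuple
    normality: pd.DataFrame  # per day: W, p, normal
    posthoc: pd.DataFrame  # pairwise comparisons with adjusted p
    alpha: float

    @property
    def stars(self) -> str:
        return _stars(self.p_value)


def _rm_anova(table: np.ndarray) -> tuple[float, float, tuple, float, int]:
    """Repeated-measures one-way ANOVA by direct SS decomposition.

    Returns (F, p, (df_days, df_err), MS_error, df_err).
    """
    n, k = table.shape
    grand = table.mean()
    ss_days = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_days - ss_subj
    df_days = k - 1
    df_err = (n - 1) * (k - 1)
    ms_days = ss_days / df_days
    ms_err = ss_err / df_err
    F = ms_days / ms_err
    p = float(stats.f.sf(F, df_days, df_err))
    return float(F), p, (df_days, df_err), float(ms_err), df_err


def _tukey_rm(table: np.ndarray, days, ms_err: float, df_err: int) -> pd.DataFrame:
    """Tukey HSD on repeated measures using the RM-ANOVA error MS."""
    n, k = table.shape
    means = table.mean(axis=0)
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        q = abs(means[a] - means[b]) / np.sqrt(ms_err / n)
        p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append({"day_a": days[a], "day_b": days[b],
                     "statistic": float(q), "p_adj": min(p, 1.0),
                     "stars": _stars(p)})
    return pd.DataFrame(rows)


def _dunn_friedman(table: np.ndarray, days) -> pd.DataFrame:
    """Dunn's post hoc test on within-subject ranks, Bonferroni-corrected."""
    n, k = table.shape
    ranks = stats.rankdata(table, axis=1)
    mean_ranks = ranks.mean(axis=0)
    m = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = min(2.0 * stats.norm.sf(z) * m, 1.0)
        rows.append({"day_a": days[a], "day_b": days[b],
                     "statistic": float(z), "p_adj": float(p),
                     "stars": _stars(p)})
    return pd.DataFrame(rows)


def compare_timepoints(
    table: pd.DataFrame,
    paired: bool = True,
    alpha: float = 0.05,
) -> StatsReport:
    """Compare a metric across post-operative days (animals × days table).

    Shapiro–Wilk runs per day at ``alpha``; if every day is consistent
    with normality the route is repeated-measures one-way ANOVA with
    Tukey's post hoc test, otherwise the Friedman test with Dunn's post
    hoc test under Bonferroni correction.  The table must be complete
    (paired design); rows are animals, columns are days.
    """
    if not paired:
        raise NotImplementedError(
            "only the paired (repeated-measures) design is implemented")
    if isinstance(table, pd.DataFrame):
        days = list(table.columns)
        data = table.to_numpy(dtype=float)
    else:
        data = np.asarray(table, dtype=float)
        days = list(range(data.shape[1]))
    if data.shape[1] < 2:
        raise ValueError("need at least 2 days")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 animals")
    missing = np.argwhere(~np.isfinite(data))
    if len(missing):
        cells = [(int(a), days[d]) for a, d in missing]
        raise ValueError(f"incomplete paired table; missing cells: {cells}")

    norm_rows = []
    all_normal = True
    for j, day in enumerate(days):
        W, p = stats.shapiro(data[:, j])
        is_norm = p > alpha
        all_normal &= is_norm
        norm_rows.append({"day": day, "W": float(W), "p": float(p),
                          "normal": bool(is_norm)})
    normality = pd.DataFrame(norm_rows)

    if all_normal:
        F, p, dfs, ms_err, df_err = _rm_anova(data)
        posthoc = _tukey_rm(data, days, ms_err, df_err)
        return StatsReport(test_name="rm_anova_tukey", statistic=F,
                           p_value=p, df=dfs, normality=normality,
                           posthoc=posthoc, alpha=alpha)
    chi2, p = stats.friedmanchisquare(*[data[:, j] for j in range(len(days))])
    posthoc = _dunn_friedman(data, days)
    return StatsReport(test_name="friedman_dunn", statistic=float(chi2),
                       p_value=float(p), df=(len(days) - 1,),
                       normality=normality, posthoc=posthoc, alpha=alpha)
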