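"""Variety-level statistics: rankings, blooming calendars, yield regression.

Rankings compare varieties on a crown metric with one-way ANOVA followed by
all-pairs Tukey HSD (Tukey-Kramer for unequal group sizes) at a family-wise
alpha, summarized as a compact letter display: varieties sharing a letter
are not significantly different.

The blooming calendar maps per-variety flower-density time series onto the
standard phenological anchors: bloom is considered started once mean density
first reaches 5% of its seasonal peak, full between the first and last dates
at 50% of peak, and over after the last date at 5% — the same 5%/50% flower
fractions that define the field-scored stages, here applied to densities as
an estimator. The threshold fractions are parameters.

Yield regressions are per-variety ordinary least squares of grouped yield
weight on mean crown volume, reporting R^2 and the two-sided slope p-value
with significance flags at 0.05 and 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

METRIC_COLUMNS = {"height": "max_height_m", "volume": "crown_volume_m3"}


# ---------------------------------------------------------------------------
# Tukey HSD ranking with compact letter display
# ---------------------------------------------------------------------------

@dataclass
class VarietyRanking:
    metric: str
    alpha: float
    table: pd.DataFrame        # variety, n, mean, sd, letters (desc. mean)
    pairwise: pd.DataFrame     # group1, group2, meandiff, p_adj, reject
    anova_f: float
    anova_p: float


def compact_letter_display(groups: Sequence[str],
                           significant_pairs: set[tuple[str, str]],
                           order: Optional[Sequence[str]] = None,
                           ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column holding every group; every significantly
    different pair splits the columns containing both; redundant columns are
    absorbed. Letters are assigned in the supplied display order, so the
    result is deterministic and invariant to input relabeling.
    """
    display_order = list(order) if order is not None else list(groups)
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant_pairs):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb: drop columns contained in another
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
        # deduplicate while keeping deterministic order
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # order columns by the first display-order member they contain
    def col_key(col: set[str]) -> int:
        return min(display_order.index(g) for g in col)
    columns.sort(key=col_key)
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i) if i < 26 else f"({i + 1})"
        for g in display_order:
            if g in col:
                letters[g] += letter
    return letters


def rank_varieties(records: pd.DataFrame, metric: str = "height",
                   alpha: float = 0.05, value_column: Optional[str] = None,
                   group_column: str = "variety") -> VarietyRanking:
    """Rank varieties on a crown metric with Tukey HSD at ``alpha``.

    ``records`` is a per-tree metrics table; varieties with fewer than two
    trees are excluded with a warning.
    """
    column = value_column or METRIC_COLUMNS.get(metric, metric)
    data = records[[group_column, column]].dropna()
    sizes = data.groupby(group_column).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding varieties with fewer than 2 trees: {small}",
                      stacklevel=2)
        data = data[~data[group_column].isin(small)]
    if data[group_column].nunique() < 2:
        raise ValueError("need at least two varieties with >= 2 trees each")
    values = data[column].to_numpy(float)
    groups = data[group_column].to_numpy()
    samples = [values[groups == g] for g in np.unique(groups)]
    anova_f, anova_p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairwise = pd.DataFrame(tukey.summary().data[1:],
                            columns=[c.replace("-", "_") for c in
                                     tukey.summary().data[0]])
    pairwise = pairwise.rename(columns={"p_adj": "p_adj"})
    sig = {
        tuple(sorted((row.group1, row.group2)))
        for row in pairwise.itertuples(index=False) if bool(row.reject)
    }
    summary = (data.groupby(group_column)[column]
               .agg(n="size", mean="mean", sd="std")
               .reset_index().rename(columns={group_column: "variety"}))
    summary = summary.sort_values("mean", ascending=False,
                                  kind="stable").reset_index(drop=True)
    letters = compact_letter_display(summary["variety"].tolist(), sig,
                                     order=summary["variety"].tolist())
    summary["letters"] = summary["variety"].map(letters)
    return VarietyRanking(metric=metric, alpha=alpha, table=summary,
                          pairwise=pairwise, anova_f=float(anova_f),
                          anova_p=float(anova_p))


# ---------------------------------------------------------------------------
# Blooming calendar
# ---------------------------------------------------------------------------

@dataclass
class BloomCalendar:
    densities: pd.DataFrame    # varieties x dates, mean flower density
    stages: pd.DataFrame       # variety, peak_date, peak_density, start,
    #                            full_start, full_end, end, no_bloom flag
    start_fraction: float
    full_fraction: float


def build_calendar(flower_tables: pd.DataFrame,
                   start_fraction: float = 0.05,
                   full_fraction: float = 0.50,
                   variety_map: Optional[pd.DataFrame] = None,
                   ) -> BloomCalendar:
    """Build a per-variety blooming calendar from flower-density tables.

    ``flower_tables`` stacks per-date flower estimates (columns date,
    tree_id, flower_density_per_m3 and, unless ``variety_map`` supplies it,
    variety). Per variety and date the tree densities are averaged; bloom
    stages are read off the density curve at ``start_fraction`` and
    ``full_fraction`` of the seasonal peak.
    """
    data = flower_tables.copy()
    data = data[data["tree_id"] != -1]
    if "variety" not in data.columns or data["variety"].isna().all():
        if variety_map is None:
            raise ValueError("no variety information available")
        data = data.drop(columns=["variety"], errors="ignore").merge(
            variety_map[["tree_id", "variety"]], on="tree_id", how="left")
    dates = sorted(data["date"].unique())
    if len(dates) < 2:
        raise ValueError("calendar construction needs at least two dates")
    densities = (data.pivot_table(index="variety", columns="date",
                                  values="flower_density_per_m3",
                                  aggfunc="mean")
                 .reindex(columns=dates))
    rows = []
    for variety, series in densities.iterrows():
        vals = series.to_numpy(float)
        peak_idx = int(np.nanargmax(vals))
        peak = float(vals[peak_idx])
        if not peak > 0:
            rows.append({"variety": variety, "peak_date": None,
                         "peak_density": 0.0, "start": None,
                         "full_start": None, "full_end": None, "end": None,
                         "no_bloom": True})
            continue
        above_start = np.flatnonzero(vals >= start_fraction * peak)
        above_full = np.flatnonzero(vals >= full_fraction * peak)
        rows.append({
            "variety": variety,
            "peak_date": dates[peak_idx],
            "peak_density": peak,
            "start": dates[above_start[0]],
            "full_start": dates[above_full[0]],
            "full_end": dates[above_full[-1]],
            "end": dates[above_start[-1]],
            "no_bloom": False,
        })
    stages = pd.DataFrame(rows)
    return BloomCalendar(densities=densities, stages=stages,
                         start_fraction=start_fraction,
                         full_fraction=full_fraction)


# ---------------------------------------------------------------------------
# Yield-volume regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    variety: str
    date: object
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    significant_05: bool
    significant_10: bool
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "variety": self.variety, "date": self.date, "n": self.n,
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "significant_05": self.significant_05,
            "significant_10": self.significant_10,
            "undefined": self.undefined,
        }


def _ols_result(variety: str, date, volume: np.ndarray, yield_kg: np.ndarray,
                ) -> RegressionResult:
    n = volume.size
    if np.ptp(volume) == 0:
        return RegressionResult(variety=variety, date=date, n=n,
                                slope=float("nan"), intercept=float("nan"),
                                r_squared=float("nan"), p_value=float("nan"),
                                significant_05=False, significant_10=False,
                                undefined=True)
    if np.ptp(yield_kg) == 0:
        # flat response: zero slope explains nothing, by convention R^2 = 0
        return RegressionResult(variety=variety, date=date, n=n, slope=0.0,
                                intercept=float(yield_kg.mean()),
                                r_squared=0.0, p_value=1.0,
                                significant_05=False, significant_10=False)
    model = sm.OLS(yield_kg, sm.add_constant(volume)).fit()
    slope = float(model.params[1])
    p = float(model.pvalues[1])
    return RegressionResult(variety=variety, date=date, n=n, slope=slope,
                            intercept=float(model.params[0]),
                            r_squared=float(model.rsquared), p_value=p,
                            significant_05=p < 0.05, significant_10=p < 0.10)


def fit_yield_volume(volumes: pd.DataFrame, yields: pd.DataFrame,
                     pooled: bool = False) -> pd.DataFrame:
    """Per-variety (and per-date) OLS of grouped yield on mean crown volume.

    ``volumes`` holds one row per (variety, block[, date]) with the mean
    crown volume of the group of adjacent trees whose harvest was pooled;
    ``yields`` holds the matching grouped yield weights (kg). Varieties
    require at least three groups. With ``pooled=True`` a single
    across-variety regression is returned instead (reported separately
    because pooling heterogeneous varieties is generally uninformative).
    """
    keys = ["variety", "block"] + (["date"] if "date" in volumes else [])
    merged = volumes.merge(yields, on=[k for k in keys if k in yields.columns])
    date_vals = merged["date"].unique() if "date" in merged else [None]
    results = []
    for date in date_vals:
        part = merged if date is None else merged[merged["date"] == date]
        if pooled:
            if len(part) >= 3:
                results.append(_ols_result(
                    "(pooled)", date,
                    part["crown_volume_m3"].to_numpy(float),
                    part["yield_kg"].to_numpy(float)).as_dict())
            continue
        for variety, sub in part.groupby("variety"):
            if len(sub) < 3:
                warnings.warn(
                    f"variety {variety!r}: fewer than 3 yield groups, skipped",
                    stacklevel=2)
                continue
            results.append(_ols_result(
                str(variety), date,
                sub["crown_volume_m3"].to_numpy(float),
                sub["yield_kg"].to_numpy(float)).as_dict())
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# Cross-date tree matching
# ---------------------------------------------------------------------------

def match_trees_across_dates(centroids_per_date: Sequence[pd.DataFrame],
                             max_displacement: float = 2.0,
                             ) -> list[dict[int, int]]:
    """Greedy nearest-centroid matching of crowns across dates.

    Each element of ``centroids_per_date`` is a frame with tree_id, x, y for
    one date. The first date fixes the global ids; on later dates crowns are
    matched to the nearest unmatched global centroid within
    ``max_displacement`` metres (closest pairs first); leftovers get fresh
    ids. Returns one {local id -> global id} mapping per date.
    """
    if len(centroids_per_date) < 2:
        raise ValueError("matching needs at least two dates")
    ref = centroids_per_date[0]
    mappings = [{int(t): int(t) for t in ref["tree_id"]}]
    global_pos = {int(r.tree_id): (float(r.x), float(r.y))
                  for r in ref.itertuples(index=False)}
    next_id = max(global_pos, default=0) + 1
    for frame in centroids_per_date[1:]:
        locals_ = [(int(r.tree_id), float(r.x), float(r.y))
                   for r in frame.itertuples(index=False)]
        pairs = []
        for lid, lx, ly in locals_:
            for gid, (gx, gy) in global_pos.items():
                d = float(np.hypot(lx - gx, ly - gy))
                if d <= max_displacement:
                    pairs.append((d, lid, gid))
        pairs.sort()
        mapping: dict[int, int] = {}
        used_globals: set[int] = set()
        for d, lid, gid in pairs:
            if lid in mapping or gid in used_globals:
                continue
            mapping[lid] = gid
            used_globals.add(gid)
        for lid, lx, ly in locals_:
            if lid not in mapping:
                mapping[lid] = next_id
                global_pos[next_id] = (lx, ly)
                next_id += 1
        mappings.append(mapping)
    return mappings
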