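"""Aggregation of simulation results into published-style output tables.

Cell estimates are means across simulations; the headline standard error
is the across-simulation standard deviation (the standard error of the
Monte Carlo mean, SD/sqrt(n_sims), is also emitted under its own label).
Per-visit cost is computed within each simulation as total/count and then
averaged, not as a ratio of averaged totals; the ratio-of-means variant is
emitted alongside for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AggregationError, ConfigurationError, UndefinedShareError
from .national_simulation import SimulationResult

log = logging.getLogger(__name__)

_KEY = ["stratifier", "level", "visit_type"]


@dataclass
class AggregateEstimate:
    """Across-simulation estimates per (stratifier, level, visit type).

    ``table`` is indexed by the cell key and carries: total_mean, total_se
    (across-simulation SD), total_se_mean (SD/sqrt(n_sims)), count_mean,
    pervisit_mean, pervisit_se, pervisit_ratio_of_means, n_sims_nonzero.
    All costs are base-year dollars.
    """

    table: pd.DataFrame
    n_sims: int

    def cell(self, stratifier: str, level: str, visit_type: str) -> pd.Series:
        try:
            return self.table.loc[(stratifier, str(level), visit_type)]
        except KeyError:
            raise AggregationError(
                f"no cell ({stratifier!r}, {level!r}, {visit_type!r})"
            ) from None

    def total(self, stratifier: str, level: str, visit_type: str) -> float:
        return float(self.cell(stratifier, level, visit_type)["total_mean"])

    def per_visit_from_totals(self, stratifier: str, level: str, visit_type: str) -> float:
        """Mean cost per visit implied by the cell's totals (total/count)."""
        row = self.cell(stratifier, level, visit_type)
        if row["count_mean"] == 0:
            raise UndefinedShareError("zero visit count")
        return float(row["total_mean"] / row["count_mean"])

    @classmethod
    def from_totals(cls, frame: pd.DataFrame) -> "AggregateEstimate":
        """Build an estimate from a plain totals table (columns: stratifier,
        level, visit_type, total_cost, n_visits), e.g. published values
        typed in for arithmetic-identity checks."""
        t = frame.copy()
        t["level"] = t["level"].astype(str)
        t = t.rename(columns={"total_cost": "total_mean", "n_visits": "count_mean"})
        t["total_se"] = 0.0
        t["total_se_mean"] = 0.0
        t["pervisit_mean"] = np.where(
            t["count_mean"] > 0, t["total_mean"] / t["count_mean"], np.nan
        )
        t["pervisit_se"] = 0.0
        t["pervisit_ratio_of_means"] = t["pervisit_mean"]
        t["n_sims_nonzero"] = 1
        return cls(t.set_index(_KEY).sort_index(), n_sims=1)


def aggregate(results: list[SimulationResult]) -> AggregateEstimate:
    """Mean/SE of every cell across simulations.

    All results must share one cell universe; a single simulation yields
    SE 0 by convention (flagged via a log warning).
    """
    if not results:
        raise AggregationError("no simulation results to aggregate")
    frames = []
    universe = None
    for res in results:
        cells = res.cells.sort_values(_KEY, ignore_index=True)
        key = list(map(tuple, cells[_KEY].to_numpy()))
        if universe is None:
            universe = key
            template = cells
        elif key != universe:
            raise AggregationError(
                f"simulation {res.index} has a different cell universe"
            )
        frames.append(cells[["total_cost", "n_visits"]].to_numpy(dtype=float))
    stack = np.stack(frames)  # (n_sims, n_cells, 2)
    n_sims = stack.shape[0]
    if n_sims == 1:
        log.warning("aggregating a single simulation; standard errors are 0 by convention")
    totals = stack[:, :, 0]
    counts = stack[:, :, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        pervisit = np.where(counts > 0, totals / np.where(counts > 0, counts, 1), np.nan)
    n_nonzero = (counts > 0).sum(axis=0)

    def _sd(arr):
        if n_sims < 2:
            return np.zeros(arr.shape[1])
        sd = np.nanstd(arr, axis=0, ddof=1)
        # identical draws must give an SE of exactly zero, not rounding dust
        degenerate = np.nanmax(arr, axis=0) == np.nanmin(arr, axis=0)
        sd[degenerate] = 0.0
        return sd

    out = template[_KEY].copy()
    out["total_mean"] = totals.mean(axis=0)
    out["total_se"] = _sd(totals)
    out["total_se_mean"] = out["total_se"] / np.sqrt(n_sims)
    out["count_mean"] = counts.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["pervisit_mean"] = np.where(
            n_nonzero > 0, np.nanmean(pervisit, axis=0), np.nan
        )
        pervisit_sd = np.where(n_nonzero > 1, np.nan_to_num(_sd(pervisit)), 0.0)
    out["pervisit_se"] = pervisit_sd
    out["pervisit_ratio_of_means"] = np.where(
        out["count_mean"] > 0, out["total_mean"] / out["count_mean"].replace(0, np.nan), np.nan
    )
    out["n_sims_nonzero"] = n_nonzero
    return AggregateEstimate(out.set_index(_KEY).sort_index(), n_sims=n_sims)


def share_of_total(
    estimate: AggregateEstimate,
    numerator: tuple[str, str, str],
    denominator: tuple[str, str, str],
    ndigits: int | None = 0,
) -> float:
    """100 x mean(numerator cell) / mean(denominator cell), rounded."""
    den = estimate.total(*denominator)
    if den == 0:
        raise UndefinedShareError(f"zero denominator cell {denominator}")
    share = 100.0 * estimate.total(*numerator) / den
    return round(share, ndigits) if ndigits is not None else share


@dataclass
class TrendSeries:
    """Per-year cost series for one grouping variable.

    ``totals``/``means`` are year x level frames of mean total cost and
    mean per-visit cost across simulations.
    """

    by: str
    totals: pd.DataFrame
    means: pd.DataFrame

    def percent_change(self, level: str, year_from: int, year_to: int) -> float:
        for y in (year_from, year_to):
            if y not in self.totals.index:
                raise ConfigurationError(f"year {y} outside the data range")
        v1 = self.totals.loc[year_from, level]
        v2 = self.totals.loc[year_to, level]
        if v1 == 0:
            raise UndefinedShareError("zero base-year value")
        return 100.0 * (v2 - v1) / v1


_TREND_STRATIFIER = {
    "visit_type": "year",
    "age_group": "year|age_group",
    "race_ethnicity": "year|race_ethnicity",
}


def trend_table(results: list[SimulationResult], by: str = "visit_type") -> TrendSeries:
    """Annual series of mean total and per-visit cost by the grouping.

    ``visit_type`` reads the per-year cells directly; the other groupings
    read year x group crossed cells.
    """
    if by not in _TREND_STRATIFIER:
        raise ConfigurationError(f"unsupported trend grouping {by!r}")
    est = aggregate(results)
    frame = est.table.reset_index()
    strat = _TREND_STRATIFIER[by]
    sub = frame[frame["stratifier"] == strat].copy()
    if sub.empty:
        raise ConfigurationError(f"no cells for stratifier {strat!r}; was it tallied?")
    if by == "visit_type":
        sub = sub[sub["level"] != "missing"]
        sub["year"] = sub["level"].astype(int)
        sub["group"] = sub["visit_type"]
    else:
        parts = sub["level"].str.split("|", expand=True)
        sub = sub[sub["visit_type"] == "overall"]
        parts = parts.loc[sub.index]
        keep = (parts[0] != "missing") & (parts[1] != "missing")
        sub = sub[keep]
        sub["year"] = parts.loc[keep, 0].astype(int)
        sub["group"] = parts.loc[keep, 1]
    totals = sub.pivot_table(index="year", columns="group", values="total_mean", aggfunc="sum")
    means = sub.pivot_table(index="year", columns="group", values="pervisit_mean", aggfunc="mean")
    totals.columns.name = by
    means.columns.name = by
    return TrendSeries(by=by, totals=totals, means=means)


def median_table(reference_sample: pd.DataFrame, stratifiers) -> pd.DataFrame:
    """Median per-visit cost per cell, over the pooled per-visit cost
    distribution of a reference simulated national sample (original plus
    resampled visits)."""
    from .national_simulation import HOSPITAL_QUARTILE_SOURCE

    rows = []
    sample = reference_sample

    def _groups(strat):
        if strat == "overall":
            return pd.Series("all", index=sample.index)
        if isinstance(strat, tuple):
            return sample[list(strat)].astype(str).agg("|".join, axis=1)
        if strat in HOSPITAL_QUARTILE_SOURCE:
            from .clinical_derivation import assign_quartiles, compute_quartile_thresholds

            src = HOSPITAL_QUARTILE_SOURCE[strat]
            th = compute_quartile_thresholds(sample[src].to_numpy(), name=strat)
            return pd.Series(assign_quartiles(sample[src].to_numpy(), th), index=sample.index)
        if strat not in sample.columns:
            raise ConfigurationError(f"unknown stratifier {strat!r}")
        return sample[strat]

    for strat in stratifiers:
        name = "|".join(strat) if isinstance(strat, tuple) else str(strat)
        groups = _groups(strat).astype(str).where(lambda s: s != "nan", "missing")
        for (level, vt), g in sample.groupby([groups, sample["visit_type"]], observed=True):
            if len(g) == 0:
                continue
            rows.append(
                {
                    "stratifier": name,
                    "level": level,
                    "visit_type": str(vt),
                    "median_cost": float(g["cost_base"].median()),
                    "n_visits": int(len(g)),
                }
            )
        med_all = sample.groupby(groups, observed=True)["cost_base"].median()
        cnt_all = sample.groupby(groups, observed=True).size()
        for level in med_all.index:
            rows.append(
                {
                    "stratifier": name,
                    "level": level,
                    "visit_type": "overall",
                    "median_cost": float(med_all[level]),
                    "n_visits": int(cnt_all[level]),
                }
            )
    return pd.DataFrame(rows, columns=["stratifier", "level", "visit_type", "median_cost", "n_visits"])


def write_tables(
    estimate: AggregateEstimate,
    trend: TrendSeries | None,
    out_dir,
    medians: pd.DataFrame | None = None,
    run_info: dict | None = None,
) -> dict[str, Path]:
    """Emit the output tables as CSV plus a JSON run summary.

    ``table1_total_cost.csv`` holds totals in millions at one decimal;
    ``table2_mean_cost.csv`` holds per-visit means in whole dollars;
    ``full_precision.csv`` retains the unrounded values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frame = estimate.table.reset_index()
    if frame.empty:
        log.warning("empty estimate; writing header-only tables")

    if frame.empty:
        t1 = pd.DataFrame(columns=_KEY + ["total_cost_musd", "se_musd"])
    else:
        t1 = frame.copy()
        t1["total_cost_musd"] = (t1["total_mean"] / 1e6).round(1)
        t1["se_musd"] = (t1["total_se"] / 1e6).round(1)
        t1 = t1[_KEY + ["total_cost_musd", "se_musd"]]
    paths["table1"] = out / "table1_total_cost.csv"
    t1.to_csv(paths["table1"], index=False)

    t2 = frame[frame["visit_type"].isin(["ed_only", "inpatient"])].copy() if not frame.empty else frame.copy()
    if not t2.empty:
        t2["mean_cost_usd"] = t2["pervisit_mean"].round(0)
        t2["se_usd"] = t2["pervisit_se"].round(1)
        t2 = t2[_KEY + ["mean_cost_usd", "se_usd"]]
    else:
        t2 = pd.DataFrame(columns=_KEY + ["mean_cost_usd", "se_usd"])
    paths["table2"] = out / "table2_mean_cost.csv"
    t2.to_csv(paths["table2"], index=False)

    paths["full"] = out / "full_precision.csv"
    frame.to_csv(paths["full"], index=False)

    if trend is not None:
        paths["trends"] = out / "trends.csv"
        tt = trend.totals.copy()
        tt.columns = [f"total_{c}" for c in tt.columns]
        tm = trend.means.copy()
        tm.columns = [f"mean_{c}" for c in tm.columns]
        pd.concat([tt, tm], axis=1).to_csv(paths["trends"])

    if medians is not None:
        paths["medians"] = out / "medians.csv"
        medians.to_csv(paths["medians"], index=False)

    paths["summary"] = out / "run_summary.json"
    info = {"n_sims": estimate.n_sims, "n_cells": int(len(frame))}
    info.update(run_info or {})
    paths["summary"].write_text(json.dumps(info, indent=2, sort_keys=True))
    return paths


def plot_trends(trend: TrendSeries, path) -> None:
    """Optional line plot of the annual total-cost series."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    (trend.totals / 1e9).plot(ax=ax, marker="o")
    ax.set_xlabel("year")
    ax.set_ylabel("total cost (billions, base-year dollars)")
    ax.set_title(f"Annual national cost by {trend.by}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
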