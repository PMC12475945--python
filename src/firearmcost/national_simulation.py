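"""Monte Carlo extrapolation from sample states to a national sample.

Each simulation, for each year: draw inpatient visits with replacement
from the pooled sample-state inpatient visits, matching the external
state-year inpatient admission targets for the unobserved states; draw
ED-only visits analogously, with the ED draw count per state equal to the
inpatient target times the year's pooled ED:inpatient ratio in the sample
states (half-up rounding); combine resampled and original visits into a
national annual sample; tally cost totals and visit counts per stratum.
Hospital volume quartile thresholds are recomputed inside every simulated
national sample, weighting hospitals by their visit multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical_derivation import assign_quartiles, compute_quartile_thresholds
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyPoolError,
    ValidationError,
)

#: Stratifiers tallied by default; tuples are crossed (used for trends).
DEFAULT_STRATIFIERS = (
    "overall",
    "year",
    "age_group",
    "sex",
    "race_ethnicity",
    "payer",
    "zip_income_quartile",
    "disposition",
    "intent",
    "body_region",
    "iss_category",
    "comorbidity_category",
    "reinjury_flag",
    "beds_category",
    "medicaid_quartile",
    "cbsa",
    "trauma_level",
    "rural_hospital",
    "admissions_quartile",
    "ed_volume_quartile",
    "med_school",
    ("year", "age_group"),
    ("year", "race_ethnicity"),
)

#: Hospital variables whose quartiles are recomputed per simulation, as
#: (stratifier name -> visit-level source column).
HOSPITAL_QUARTILE_SOURCE = {
    "medicaid_quartile": "hosp_medicaid_share",
    "admissions_quartile": "hosp_admissions",
    "ed_volume_quartile": "hosp_ed_visits",
}

MINIMAL_STRATIFIERS = ("overall", "year")


@dataclass
class SimulationSpec:
    """Monte Carlo run parameters."""

    n_simulations: int = 2400
    master_seed: int = 0
    ed_ratio_scope: str = "per_year"
    rounding_rule: str = "half_up"

    def validate(self) -> None:
        if self.n_simulations < 1:
            raise ConfigurationError("n_simulations must be >= 1")
        if self.ed_ratio_scope != "per_year":
            raise ConfigurationError(f"unknown ed_ratio_scope {self.ed_ratio_scope!r}")
        if self.rounding_rule != "half_up":
            raise ConfigurationError(f"unknown rounding_rule {self.rounding_rule!r}")


def load_targets(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"state": str})
    frame["year"] = frame["year"].astype(int)
    frame["ip_target"] = frame["ip_target"].astype(int)
    if (frame["ip_target"] < 0).any():
        raise ValidationError("negative inpatient target")
    return frame


def compute_ed_target(ip_target: int, sample_ed: int, sample_ip: int) -> int:
    """ED draw count: inpatient target x sample ED:inpatient ratio, half-up.

    Exact integer arithmetic, so a true .5 always rounds up.
    """
    if ip_target < 0:
        raise ValidationError("negative inpatient target")
    if ip_target == 0:
        return 0
    if sample_ip == 0:
        raise DegenerateInputError("sample inpatient count is zero; ratio undefined")
    num = ip_target * sample_ed
    return (2 * num + sample_ip) // (2 * sample_ip)


def resample_visits(
    pool: pd.DataFrame, n: int, rng, id_prefix: str = "r", year=None, visit_type=None
) -> pd.DataFrame:
    """n independent uniform with-replacement draws from the pool.

    Drawn copies keep every attribute but receive fresh visit ids and a
    ``resampled`` marker. ``year``/``visit_type`` only label the error
    raised when the pool is empty but n > 0.
    """
    if n == 0:
        out = pool.iloc[0:0].copy()
        out["resampled"] = pd.Series([], dtype=bool)
        return out
    if len(pool) == 0:
        raise EmptyPoolError(year, visit_type, n)
    idx = rng.integers(0, len(pool), size=n)
    out = pool.take(idx)
    out = out.reset_index(drop=True)
    out["visit_id"] = [f"{id_prefix}{i}" for i in range(n)]
    out["resampled"] = True
    return out


@dataclass
class SimulationResult:
    """Stratified tallies of one simulated national sample."""

    index: int
    cells: pd.DataFrame  # stratifier, level, visit_type, total_cost, n_visits
    counts: dict[str, int]
    resampled_by_year: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, index: int) -> "SimulationResult":
        cells = pd.read_csv(path, dtype={"stratifier": str, "level": str, "visit_type": str})
        counts = {}
        for vt in ("ed_only", "inpatient"):
            sub = cells[(cells["stratifier"] == "overall") & (cells["visit_type"] == vt)]
            counts[vt] = int(sub["n_visits"].sum())
        return cls(index, cells, counts)


def _level_codes(sample: pd.DataFrame, strat):
    """(codes, levels) for one stratifier; missing values get code -1."""
    if strat == "overall":
        return np.zeros(len(sample), dtype=np.int64), ["all"]
    if isinstance(strat, tuple):
        codes = None
        levels: list[str] = [""]
        for part in strat:
            c, lv = _level_codes(sample, part)
            nlv = len(lv) + 1  # reserve slot for missing within each part
            c = np.where(c < 0, len(lv), c)
            lv = list(lv) + ["missing"]
            if codes is None:
                codes = c
                levels = lv
            else:
                codes = codes * nlv + c
                levels = [f"{a}|{b}" for a in levels for b in lv]
        return codes, levels
    if strat not in sample.columns:
        raise ConfigurationError(f"unknown stratifier {strat!r}")
    col = sample[strat]
    if isinstance(col.dtype, pd.CategoricalDtype):
        return col.cat.codes.to_numpy(dtype=np.int64), [str(c) for c in col.cat.categories]
    codes, uniques = pd.factorize(col, use_na_sentinel=True)
    order = np.argsort(np.asarray(uniques, dtype=object).astype(str))
    remap = np.empty(len(uniques), dtype=np.int64)
    remap[order] = np.arange(len(uniques))
    codes = np.where(codes < 0, -1, remap[np.where(codes < 0, 0, codes)])
    levels = [str(uniques[i]) for i in order]
    return codes.astype(np.int64), levels


def summarize_sample(
    sample: pd.DataFrame, stratifiers=DEFAULT_STRATIFIERS, index: int = 0
) -> SimulationResult:
    """Cost totals and visit counts per (stratifier, level, visit type).

    Missing stratifier values accumulate into a reserved ``missing`` level,
    so category totals need not sum to the overall total. For hospital
    volume variables the quartile thresholds are recomputed from this
    sample (hospitals weighted by visit multiplicity) before tallying.
    """
    vt = (sample["visit_type"] == "inpatient").to_numpy(dtype=np.int64)
    cost = sample["cost_base"].to_numpy(dtype=float)
    rows = []
    for strat in stratifiers:
        name = "|".join(strat) if isinstance(strat, tuple) else str(strat)
        if not isinstance(strat, tuple) and strat in HOSPITAL_QUARTILE_SOURCE:
            src = HOSPITAL_QUARTILE_SOURCE[strat]
            if src not in sample.columns:
                raise ConfigurationError(f"stratifier {strat!r} needs column {src!r}")
            levels = ["Q1", "Q2", "Q3", "Q4"]
            if len(sample) == 0:
                codes = np.zeros(0, dtype=np.int64)
            else:
                th = compute_quartile_thresholds(sample[src].to_numpy(), name=strat)
                labels = assign_quartiles(sample[src].to_numpy(), th)
                codes = np.searchsorted(np.array(levels), labels).astype(np.int64)
        else:
            codes, levels = _level_codes(sample, strat)
        nlev = len(levels)
        codes = np.where(codes < 0, nlev, codes)  # missing -> last slot
        key = codes * 2 + vt
        minlength = (nlev + 1) * 2
        tot = np.bincount(key, weights=cost, minlength=minlength)
        cnt = np.bincount(key, minlength=minlength)
        all_levels = levels + ["missing"]
        for li, level in enumerate(all_levels):
            ed_t, ip_t = tot[li * 2], tot[li * 2 + 1]
            ed_n, ip_n = int(cnt[li * 2]), int(cnt[li * 2 + 1])
            rows.append((name, level, "ed_only", ed_t, ed_n))
            rows.append((name, level, "inpatient", ip_t, ip_n))
            rows.append((name, level, "overall", ed_t + ip_t, ed_n + ip_n))
    cells = pd.DataFrame(
        rows, columns=["stratifier", "level", "visit_type", "total_cost", "n_visits"]
    )
    counts = {"ed_only": int((vt == 0).sum()), "inpatient": int((vt == 1).sum())}
    return SimulationResult(index=index, cells=cells, counts=counts)


def attach_hospital_attributes(visits: pd.DataFrame, hospitals: pd.DataFrame) -> pd.DataFrame:
    """Join stratification-relevant hospital attributes onto visits."""
    h = hospitals.copy()
    h["beds_category"] = pd.cut(
        h["beds"], bins=[0, 99, 499, np.inf], labels=["1-99", "100-499", ">=500"]
    ).astype(str)
    h = h.rename(
        columns={
            "medicaid_share": "hosp_medicaid_share",
            "admissions": "hosp_admissions",
            "ed_visits": "hosp_ed_visits",
            "beds": "hosp_beds",
        }
    ).drop(columns=["state"])
    out = visits.merge(h, on="hospital_id", how="left", validate="m:1")
    if out["hosp_medicaid_share"].isna().any():
        missing = out.loc[out["hosp_medicaid_share"].isna(), "hospital_id"].iloc[0]
        raise ValidationError(f"no hospital attributes for hospital {missing!r}")
    return out


# Columns cast to fixed categoricals so every simulation shares one level
# universe (a level absent from one resample still yields a zero cell).
_CATEGORICAL_COLUMNS = (
    "visit_type", "age_group", "sex", "race_ethnicity", "payer", "disposition",
    "intent", "body_region", "iss_category", "comorbidity_category",
    "beds_category", "cbsa", "trauma_level", "rural_hospital", "med_school",
)


def prepare_mc_inputs(visits: pd.DataFrame) -> pd.DataFrame:
    """Freeze stratifier level universes before simulation."""
    out = visits.copy()
    for col in _CATEGORICAL_COLUMNS:
        if col in out.columns and not isinstance(out[col].dtype, pd.CategoricalDtype):
            cats = sorted(out[col].dropna().astype(str).unique())
            out[col] = pd.Categorical(out[col].astype(str), categories=cats)
    for col in ("zip_income_quartile", "reinjury_flag", "year"):
        if col in out.columns and not isinstance(out[col].dtype, pd.CategoricalDtype):
            cats = sorted(out[col].dropna().unique())
            out[col] = pd.Categorical(out[col], categories=cats)
    if "resampled" not in out.columns:
        out["resampled"] = False
    if "source_state" not in out.columns:
        out["source_state"] = out["state"]
    return out


def _year_pools(visits: pd.DataFrame):
    pools = {}
    for year, g in visits.groupby("year", observed=True):
        ip = g[g["visit_type"] == "inpatient"]
        ed = g[g["visit_type"] == "ed_only"]
        pools[int(year)] = (ip, ed)
    return pools


def _ed_targets_by_state(targets: pd.DataFrame, pools) -> pd.DataFrame:
    rows = []
    for (state, year), g in targets.groupby(["state", "year"]):
        t_ip = int(g["ip_target"].sum())
        year = int(year)
        if year not in pools:
            raise ConfigurationError(f"targets refer to year {year} absent from sample visits")
        ip_pool, ed_pool = pools[year]
        t_ed = compute_ed_target(t_ip, len(ed_pool), len(ip_pool)) if t_ip else 0
        rows.append({"state": state, "year": year, "ip_target": t_ip, "ed_target": t_ed})
    return pd.DataFrame(rows)


def build_national_sample(
    year: int,
    sample_visits: pd.DataFrame,
    targets: pd.DataFrame,
    spec: SimulationSpec,
    rng,
) -> pd.DataFrame:
    """One year's national sample: original visits + resampled visits.

    Resampled inpatient count equals the summed inpatient targets for the
    year; resampled ED-only count is the per-state sum of the rounded
    ED targets. Draws are uniform with replacement from the year's pooled
    sample-state visits of the matching type.
    """
    spec.validate()
    base = prepare_mc_inputs(sample_visits)
    year_visits = base[base["year"] == year]
    pools = _year_pools(year_visits)
    if year not in pools:
        pools[year] = (year_visits.iloc[0:0], year_visits.iloc[0:0])
    tgt = _ed_targets_by_state(targets[targets["year"] == year], pools)
    parts = [year_visits]
    parts.extend(_draw_year_parts(pools[year], tgt, rng, sim_index=0, year=year))
    return pd.concat(parts, ignore_index=True)


def _draw_year_parts(pool_pair, tgt: pd.DataFrame, rng, sim_index: int, year: int):
    """Resampled inpatient and ED parts for one year (one pooled uniform
    draw per visit type; per-state provenance assigned by repetition)."""
    ip_pool, ed_pool = pool_pair
    parts = []
    for vt, pool, col in (("inpatient", ip_pool, "ip_target"), ("ed_only", ed_pool, "ed_target")):
        sizes = tgt[col].to_numpy(dtype=np.int64) if len(tgt) else np.zeros(0, dtype=np.int64)
        total = int(sizes.sum())
        if total == 0:
            continue
        if len(pool) == 0:
            raise EmptyPoolError(year, vt, total)
        idx = rng.integers(0, len(pool), size=total)
        out = pool.take(idx).reset_index(drop=True)
        out["visit_id"] = [f"mc{sim_index}-{year}-{vt}-{i}" for i in range(total)]
        out["resampled"] = True
        out["source_state"] = np.repeat(tgt["state"].to_numpy(), sizes)
        parts.append(out)
    return parts


@dataclass
class MonteCarloRun:
    """All per-simulation results (plus, optionally, the first simulated
    national sample kept for median reporting)."""

    spec: SimulationSpec
    results: list[SimulationResult]
    ed_targets: pd.DataFrame
    reference_sample: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for res in self.results:
            res.to_csv(out / f"sim_{res.index:05d}.csv")
        self.ed_targets.to_csv(out / "ed_targets.csv", index=False)

    @staticmethod
    def read_results(in_dir) -> list[SimulationResult]:
        paths = sorted(Path(in_dir).glob("sim_*.csv"))
        return [SimulationResult.from_csv(p, i) for i, p in enumerate(paths)]


def run_monte_carlo(
    visits: pd.DataFrame,
    targets: pd.DataFrame,
    spec: SimulationSpec,
    stratifiers=DEFAULT_STRATIFIERS,
    keep_reference: bool = False,
) -> MonteCarloRun:
    """Repeat the resample-and-combine procedure ``spec.n_simulations``
    times and tally each simulated national sample.

    Simulation k draws from a child generator derived deterministically
    from (master_seed, k), so results are reproducible and order
    independent. ``resampled_by_year`` on each result records the cost
    total and count of the resampled portion per year and visit type,
    supporting analytic expectation/variance checks.
    """
    spec.validate()
    base = prepare_mc_inputs(visits)
    pools = _year_pools(base)
    years = sorted(pools)
    tgt_all = _ed_targets_by_state(targets, pools)
    tgt_by_year = {y: tgt_all[tgt_all["year"] == y] for y in years}

    results = []
    reference = None
    for k in range(spec.n_simulations):
        rng = np.random.default_rng(np.random.SeedSequence(spec.master_seed, spawn_key=(k,)))
        parts = [base]
        res_rows = []
        for year in years:
            year_parts = _draw_year_parts(
                pools[year], tgt_by_year.get(year, tgt_all.iloc[0:0]), rng, k, year
            )
            for part in year_parts:
                vt_val = str(part["visit_type"].iloc[0])
                res_rows.append(
                    {
                        "year": year,
                        "visit_type": vt_val,
                        "total_cost": float(part["cost_base"].sum()),
                        "n_visits": int(len(part)),
                    }
                )
            parts.extend(year_parts)
        national = pd.concat(parts, ignore_index=True) if len(parts) > 1 else base
        result = summarize_sample(national, stratifiers, index=k)
        result.resampled_by_year = pd.DataFrame(
            res_rows, columns=["year", "visit_type", "total_cost", "n_visits"]
        )
        results.append(result)
        if keep_reference and k == 0:
            reference = national.copy()
    return MonteCarloRun(spec=spec, results=results, ed_targets=tgt_all, reference_sample=reference)
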