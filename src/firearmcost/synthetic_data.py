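"""Synthetic administrative-claims generator.

Emulates the statistical structure of linked state inpatient / emergency
department claims joined to hospital survey attributes: heavy-tailed
(log-normal) billed charges by visit type, a missing-charge fraction,
person-level visit linkage within calendar years and states, hospital
attributes used for stratification, hospital-year cost-to-charge ratios,
an annual price index, and state-year inpatient admission targets for the
states the pipeline never observes directly. Ground truth (true counts and
base-year cost totals per state-year and nationally) is recorded at
generation time so downstream estimators can be validated exactly.

Everything is driven by a single integer seed; a fixed seed regenerates
every table bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cost_engine import CCRTable, CPITable, apply_costs, exclude_missing_charge
from .errors import ConfigurationError

# Region codes emitted on synthetic diagnoses; labels follow the standard
# six-region severity-scoring convention.
REGION_CODES = ["HN", "FA", "CH", "AB", "EX", "OT"]

# External-cause code families by intent (new-encounter codes end in "A").
INTENT_PREFIXES = {
    "unintentional": ["W32", "W33", "W34"],
    "self-inflicted": ["X72", "X73", "X74"],
    "assault": ["X93", "X94", "X95"],
    "undetermined": ["Y22", "Y23", "Y24"],
    "legal intervention": ["Y35.0"],
}

# The six states whose claims the estimation pipeline observes directly.
SAMPLE_STATE_CODES = ["AR", "FL", "MD", "MA", "NY", "WI"]


def default_category_probabilities() -> dict[str, dict[str, float]]:
    """Marginal distributions for patient stratifiers.

    Chosen to resemble the demographic mix of hospital-treated firearm
    injury in the US (predominantly young adult, male, publicly insured or
    self-pay, lower-income-area residents); stratifiers are independent.
    """
    return {
        "age_group": {"0-17": 0.10, "18-24": 0.25, "25-44": 0.42, "45-64": 0.17, ">=65": 0.06},
        "sex": {"female": 0.13, "male": 0.87},
        "race_ethnicity": {
            "Asian or Pacific Islander": 0.010,
            "Black": 0.500,
            "Hispanic": 0.120,
            "Native American": 0.005,
            "White": 0.280,
            "other": 0.085,
        },
        "payer": {
            "Medicaid": 0.45,
            "Medicare": 0.06,
            "private": 0.18,
            "self-pay": 0.20,
            "no-charge": 0.03,
            "other": 0.08,
        },
        "zip_income_quartile": {"1": 0.44, "2": 0.25, "3": 0.17, "4": 0.12, "missing": 0.02},
        "disposition": {
            "routine home": 0.70,
            "transfer acute": 0.04,
            "transfer other facility": 0.08,
            "home health": 0.07,
            "AMA": 0.04,
            "died": 0.07,
        },
        "intent": {
            "assault": 0.40,
            "self-inflicted": 0.05,
            "unintentional": 0.45,
            "undetermined": 0.08,
            "legal intervention": 0.02,
        },
        "region": {"HN": 0.10, "FA": 0.05, "CH": 0.12, "AB": 0.15, "EX": 0.50, "OT": 0.08},
        "comorbidity_count": {"0": 0.45, "1": 0.25, "2": 0.15, "3": 0.10, "4": 0.05},
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic claims generator.

    Defaults describe the study conditions emulated throughout: 6 observed
    ("sample") states plus 44 unobserved states over 2016-2021, a realised
    ED-only : inpatient visit ratio near 1.607, a 16.9% missing-charge
    fraction, and log-normal nominal charges whose costed means land near
    $1.7k (ED) and $39k (inpatient) in base-2024 dollars after a typical
    cost-to-charge ratio of ~0.35.
    """

    seed: int = 0
    n_sample_states: int = 6
    n_nonsample_states: int = 44
    years: tuple[int, int] = (2016, 2021)
    hospitals_per_state: int = 25
    visits_per_state_year: float = 2500.0
    ed_to_inpatient_ratio: float = 1.607
    charge_location: dict = field(
        default_factory=lambda: {"ed_only": 8.0, "inpatient": 11.0}
    )
    charge_scale: dict = field(
        default_factory=lambda: {"ed_only": 1.0, "inpatient": 1.1}
    )
    missing_charge_rate: float = 0.169
    reinjury_rate: float = 0.06
    subsequent_visit_rate: float = 0.0
    multi_region_probs: dict = field(
        default_factory=lambda: {1: 0.60, 2: 0.30, 3: 0.10}
    )
    ais_severity_probs: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.30, 3: 0.30, 4: 0.15, 5: 0.08, 6: 0.02}
    )
    category_probabilities: dict = field(default_factory=default_category_probabilities)
    base_year: int = 2024
    ccr_beta: tuple[float, float] = (7.0, 13.0)
    cpi_start: float = 240.0
    cpi_annual_growth: float = 0.03

    def validate(self) -> None:
        if self.hospitals_per_state <= 0:
            raise ConfigurationError("hospitals_per_state must be positive")
        if self.n_sample_states <= 0 or self.n_nonsample_states < 0:
            raise ConfigurationError("state counts must be positive/non-negative")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years range is inverted")
        if self.ed_to_inpatient_ratio <= 0:
            raise ConfigurationError("ed_to_inpatient_ratio must be > 0")
        for rate in (self.missing_charge_rate, self.reinjury_rate, self.subsequent_visit_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        for vt in ("ed_only", "inpatient"):
            if self.charge_scale[vt] <= 0:
                raise ConfigurationError("charge scale parameters must be > 0")
        for name, dist in list(self.category_probabilities.items()) + [
            ("multi_region", self.multi_region_probs),
            ("ais_severity", self.ais_severity_probs),
        ]:
            probs = np.array(list(dist.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigurationError(f"{name} probabilities outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities sum to {probs.sum()}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def sample_states(self) -> list[str]:
        if self.n_sample_states == len(SAMPLE_STATE_CODES):
            return list(SAMPLE_STATE_CODES)
        return [f"S{i:02d}" for i in range(1, self.n_sample_states + 1)]

    def nonsample_states(self) -> list[str]:
        return [f"N{i:02d}" for i in range(1, self.n_nonsample_states + 1)]

    def all_states(self) -> list[str]:
        return self.sample_states() + self.nonsample_states()

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        if "ccr_beta" in raw:
            raw["ccr_beta"] = tuple(raw["ccr_beta"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """True counts and base-year cost totals known only to the generator.

    ``per_state_year`` has one row per (state, year, visit_type) with the
    generated visit count, the count with non-missing charges, and the
    base-year cost total over the non-missing-charge visits only (missing
    charges are excluded from the analytic sample, so they are excluded
    from the recoverable truth as well). ``national_by_level`` holds
    national cost totals by generation-time stratifier level.
    """

    per_state_year: pd.DataFrame
    national_by_level: pd.DataFrame

    def national_total(self, visit_type: str | None = None) -> float:
        frame = self.per_state_year
        if visit_type is not None:
            frame = frame[frame["visit_type"] == visit_type]
        # accumulate per state so the national total is the exact float
        # sum of state totals (invariant)
        return float(frame.groupby("state")["total_cost_base"].sum().sum())

    def national_count(self, visit_type: str | None = None, costed: bool = False) -> int:
        frame = self.per_state_year
        if visit_type is not None:
            frame = frame[frame["visit_type"] == visit_type]
        col = "n_costed" if costed else "n_visits"
        return int(frame[col].sum())

    def inpatient_counts(self, states: list[str]) -> pd.DataFrame:
        frame = self.per_state_year
        mask = (frame["visit_type"] == "inpatient") & frame["state"].isin(states)
        return frame.loc[mask, ["state", "year", "n_visits"]].reset_index(drop=True)


def generate_hospitals(cfg: GeneratorConfig) -> tuple[pd.DataFrame, CCRTable]:
    """Generate hospital attribute records and their hospital-year CCRs.

    Every hospital gets >=1 beds, a Medicaid discharge share in [0, 1], a
    CBSA class, a trauma level, binary rural / medical-school flags and
    positive admission and ED volumes; the CCR table has one ratio in
    (0, 1] per (hospital, year).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    rows = []
    for state in cfg.all_states():
        for i in range(cfg.hospitals_per_state):
            beds = max(1, int(rng.lognormal(5.0, 1.0)))
            cbsa = rng.choice(["metro", "micro", "rural"], p=[0.70, 0.18, 0.12])
            trauma = rng.choice(["I", "II", "III", "IV"], p=[0.20, 0.25, 0.30, 0.25])
            rural = "yes" if (cbsa == "rural" or rng.random() < 0.05) else "no"
            rows.append(
                {
                    "hospital_id": f"{state}-H{i:03d}",
                    "state": state,
                    "beds": beds,
                    "medicaid_share": float(rng.beta(2.0, 5.0)),
                    "cbsa": cbsa,
                    "trauma_level": trauma,
                    "rural_hospital": rural,
                    "med_school": "yes" if rng.random() < 0.35 else "no",
                    "admissions": int(max(1, rng.lognormal(8.0, 1.0))),
                    "ed_visits": int(max(1, rng.lognormal(9.5, 1.0))),
                }
            )
    hospitals = pd.DataFrame(rows)
    a, b = cfg.ccr_beta
    ccr_rows = []
    for hid in hospitals["hospital_id"]:
        for year in cfg.year_list:
            ccr_rows.append(
                {"hospital_id": hid, "year": year, "ccr": float(rng.beta(a, b))}
            )
    ccr = CCRTable(pd.DataFrame(ccr_rows))
    return hospitals, ccr


def generate_cpi_table(cfg: GeneratorConfig) -> CPITable:
    """Annual price index covering the data years through the base year."""
    index = {
        y: cfg.cpi_start * (1.0 + cfg.cpi_annual_growth) ** (y - cfg.years[0])
        for y in range(cfg.years[0], cfg.base_year + 1)
    }
    return CPITable(index, base_year=cfg.base_year)


def _draw_categorical(rng, dist: dict, n: int) -> np.ndarray:
    labels = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def _make_cause_codes(rng, intents: np.ndarray, subsequent_rate: float) -> np.ndarray:
    n = len(intents)
    suffix = np.where(rng.random(n) < subsequent_rate, "D", "A")
    codes = np.empty(n, dtype=object)
    for intent, prefixes in INTENT_PREFIXES.items():
        mask = intents == intent
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        pick = rng.integers(0, len(prefixes), cnt)
        digits = rng.integers(0, 10, cnt)
        where = np.flatnonzero(mask)
        for j, row in enumerate(where):
            prefix = prefixes[pick[j]]
            if "." in prefix:  # e.g. Y35.0 -> Y35.013A
                codes[row] = f"{prefix}13{suffix[row]}"
            else:
                codes[row] = f"{prefix}.{digits[j]}XX{suffix[row]}"
    return codes


def _draw_regions_and_ais(rng, nv, region_labels, region_p, nreg_k, nreg_p, sev_k, sev_p):
    """Per-visit distinct injured regions (Gumbel top-k weighted sampling
    without replacement) and an AIS severity for each region."""
    n_regions = rng.choice(nreg_k, size=nv, p=nreg_p).astype(int)
    gumbel = np.log(region_p)[None, :] + rng.gumbel(size=(nv, len(region_p)))
    order = np.argsort(-gumbel, axis=1)
    sev_idx = rng.choice(len(sev_k), size=(nv, int(n_regions.max(initial=1))), p=sev_p)
    region_strs = np.empty(nv, dtype=object)
    ais_strs = np.empty(nv, dtype=object)
    for j in range(nv):
        k = n_regions[j]
        regs = region_labels[order[j, :k]]
        sevs = sev_k[sev_idx[j, :k]]
        region_strs[j] = ";".join(regs)
        ais_strs[j] = ";".join(f"{r}:{s}" for r, s in zip(regs, sevs))
    return region_strs, ais_strs


def generate_visits(
    cfg: GeneratorConfig,
    hospitals: pd.DataFrame,
    ccr: CCRTable,
    cpi: CPITable,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate visit records for every state-year plus their ground truth.

    Per state-year, visit counts are Poisson around
    ``visits_per_state_year``; a ``reinjury_rate`` fraction of persons
    receive two new-injury visits within the calendar year (person links
    never cross states or years). Each visit carries a new-injury cause
    code (or, at ``subsequent_visit_rate``, a subsequent-encounter code
    destined to be filtered out), a log-normal nominal charge missing with
    probability ``missing_charge_rate``, and independent draws of all
    patient stratifiers.
    """
    cfg.validate()
    if hospitals is None or len(hospitals) == 0:
        raise ConfigurationError("empty hospital collection")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    probs = cfg.category_probabilities
    p_ed = cfg.ed_to_inpatient_ratio / (1.0 + cfg.ed_to_inpatient_ratio)
    region_dist = probs["region"]
    region_labels = np.array(list(region_dist.keys()), dtype=object)
    region_p = np.array(list(region_dist.values()), dtype=float)
    region_p = region_p / region_p.sum()
    nreg_k = np.array(list(cfg.multi_region_probs.keys()))
    nreg_p = np.array(list(cfg.multi_region_probs.values()), dtype=float)
    sev_k = np.array(list(cfg.ais_severity_probs.keys()))
    sev_p = np.array(list(cfg.ais_severity_probs.values()), dtype=float)

    hosp_by_state = {s: g["hospital_id"].to_numpy() for s, g in hospitals.groupby("state")}
    frames = []
    visit_counter = 0
    for state in cfg.all_states():
        if state not in hosp_by_state:
            raise ConfigurationError(f"no hospitals for state {state}")
        person_counter = 0
        for year in cfg.year_list:
            n = int(rng.poisson(cfg.visits_per_state_year))
            if n == 0:
                continue
            # person structure: m2 persons with 2 visits, rest with 1
            p2 = cfg.reinjury_rate
            m2 = int(round(n * p2 / (1.0 + p2)))
            m2 = min(m2, n // 2)
            m1 = n - 2 * m2
            m = m1 + m2
            person_ids = np.array(
                [f"{state}-{year}-P{person_counter + j:06d}" for j in range(m)],
                dtype=object,
            )
            person_counter += m
            visit_counts = np.concatenate(
                [np.ones(m1, dtype=int), np.full(m2, 2, dtype=int)]
            )
            # person-level draws, repeated onto visits
            person_attrs = {
                name: _draw_categorical(rng, probs[name], m)
                for name in ("age_group", "sex", "race_ethnicity", "zip_income_quartile")
            }
            comorb = _draw_categorical(rng, probs["comorbidity_count"], m).astype(int)
            rep = np.repeat(np.arange(m), visit_counts)
            df = pd.DataFrame(
                {
                    "person_link": person_ids[rep],
                    "state": state,
                    "year": year,
                    "comorbidity_count": comorb[rep],
                }
            )
            for name, vals in person_attrs.items():
                df[name] = vals[rep]
            nv = len(df)
            df["visit_id"] = [f"V{visit_counter + j:09d}" for j in range(nv)]
            visit_counter += nv
            df["hospital_id"] = rng.choice(hosp_by_state[state], size=nv)
            df["visit_type"] = np.where(rng.random(nv) < p_ed, "ed_only", "inpatient")
            df["payer"] = _draw_categorical(rng, probs["payer"], nv)
            df["disposition"] = _draw_categorical(rng, probs["disposition"], nv)
            intents = _draw_categorical(rng, probs["intent"], nv)
            df["cause_code"] = _make_cause_codes(rng, intents, cfg.subsequent_visit_rate)
            df["true_intent"] = intents
            # injured regions + AIS severities
            region_strs, ais_strs = _draw_regions_and_ais(
                rng, nv, region_labels, region_p, nreg_k, nreg_p, sev_k, sev_p
            )
            df["diagnosis_region_codes"] = region_strs
            df["ais_codes"] = ais_strs
            # nominal charges, heavy-tailed, by visit type, with missingness
            charge = np.empty(nv)
            for vt in ("ed_only", "inpatient"):
                mask = (df["visit_type"] == vt).to_numpy()
                charge[mask] = rng.lognormal(
                    cfg.charge_location[vt], cfg.charge_scale[vt], mask.sum()
                )
            missing = rng.random(nv) < cfg.missing_charge_rate
            charge[missing] = np.nan
            df["total_charge"] = charge
            frames.append(df)

    visits = pd.concat(frames, ignore_index=True)
    col_order = [
        "visit_id", "person_link", "state", "year", "hospital_id", "visit_type",
        "total_charge", "cause_code", "diagnosis_region_codes", "ais_codes",
        "age_group", "sex", "race_ethnicity", "payer", "zip_income_quartile",
        "disposition", "comorbidity_count", "true_intent",
    ]
    visits = visits[col_order]
    visits["zip_income_quartile"] = pd.array(
        pd.to_numeric(visits["zip_income_quartile"].replace("missing", np.nan)),
        dtype="Int64",
    )

    truth = _compute_ground_truth(cfg, visits, ccr, cpi)
    return visits, truth


def _compute_ground_truth(cfg, visits, ccr, cpi) -> GroundTruth:
    costed, _ = exclude_missing_charge(visits)
    costed = apply_costs(costed, ccr, cpi)
    counts = (
        visits.groupby(["state", "year", "visit_type"], observed=True)
        .size()
        .rename("n_visits")
    )
    costed_g = costed.groupby(["state", "year", "visit_type"], observed=True)
    per_sy = pd.concat(
        [counts, costed_g.size().rename("n_costed"), costed_g["cost_base"].sum().rename("total_cost_base")],
        axis=1,
    ).reset_index()
    per_sy[["n_costed", "total_cost_base"]] = per_sy[["n_costed", "total_cost_base"]].fillna(0)
    per_sy["n_costed"] = per_sy["n_costed"].astype(int)

    nat_rows = []
    strat_cols = {
        "age_group": "age_group", "sex": "sex", "race_ethnicity": "race_ethnicity",
        "payer": "payer", "intent": "true_intent", "visit_type": "visit_type",
    }
    for strat, col in strat_cols.items():
        g = costed.groupby(col, observed=True)["cost_base"].agg(["sum", "size"])
        for level, row in g.iterrows():
            nat_rows.append(
                {"stratifier": strat, "level": str(level),
                 "total_cost_base": float(row["sum"]), "n_costed": int(row["size"])}
            )
    return GroundTruth(per_sy, pd.DataFrame(nat_rows))


def generate_nonsample_targets(
    cfg: GeneratorConfig, truth: GroundTruth, mode: str = "consistent"
) -> pd.DataFrame:
    """State-year inpatient admission targets for the unobserved states.

    ``consistent`` mode copies the generator's true inpatient counts (so a
    correct national estimator must recover the truth); ``external`` mode
    draws counts independently, emulating targets from an outside source.
    """
    if mode == "consistent":
        targets = truth.inpatient_counts(cfg.nonsample_states())
        targets = targets.rename(columns={"n_visits": "ip_target"})
    elif mode == "external":
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
        mean_ip = cfg.visits_per_state_year / (1.0 + cfg.ed_to_inpatient_ratio)
        rows = [
            {"state": s, "year": y, "ip_target": int(rng.poisson(mean_ip))}
            for s in cfg.nonsample_states()
            for y in cfg.year_list
        ]
        targets = pd.DataFrame(rows)
    else:
        raise ConfigurationError(f"unknown targets mode {mode!r}")
    targets["ip_target"] = targets["ip_target"].astype(int)
    return targets.reset_index(drop=True)


@dataclass
class SyntheticDataset:
    """Bundle of every generated table plus the ground truth."""

    cfg: GeneratorConfig
    hospitals: pd.DataFrame
    ccr: CCRTable
    cpi: CPITable
    visits: pd.DataFrame
    truth: GroundTruth
    targets: pd.DataFrame

    def sample_visits(self) -> pd.DataFrame:
        """Visits from the observed (sample) states only."""
        return self.visits[self.visits["state"].isin(self.cfg.sample_states())]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.visits.drop(columns=["true_intent"]).to_csv(out / "visits.csv", index=False)
        self.hospitals.to_csv(out / "hospitals.csv", index=False)
        self.ccr.to_csv(out / "ccr.csv")
        self.cpi.to_csv(out / "cpi.csv")
        self.targets.to_csv(out / "targets.csv", index=False)
        self.truth.per_state_year.to_csv(out / "truth_state_year.csv", index=False)
        self.truth.national_by_level.to_csv(out / "truth_national.csv", index=False)


def generate_dataset(cfg: GeneratorConfig, targets_mode: str = "consistent") -> SyntheticDataset:
    """Run the full generation sequence from a single config."""
    hospitals, ccr = generate_hospitals(cfg)
    cpi = generate_cpi_table(cfg)
    visits, truth = generate_visits(cfg, hospitals, ccr, cpi)
    targets = generate_nonsample_targets(cfg, truth, mode=targets_mode)
    return SyntheticDataset(cfg, hospitals, ccr, cpi, visits, truth, targets)


def read_visits_csv(path) -> pd.DataFrame:
    """Read a visits table with the dtypes the pipeline expects."""
    df = pd.read_csv(
        path,
        dtype={
            "visit_id": str, "person_link": str, "state": str, "hospital_id": str,
            "cause_code": str, "diagnosis_region_codes": str, "ais_codes": str,
            "zip_income_quartile": "Int64",
        },
    )
    df["year"] = df["year"].astype(int)
    return df
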