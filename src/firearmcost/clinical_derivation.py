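"""Derived injury and visit-level variables.

Intent from external-cause code prefixes (longest match wins, configurable
table), injured body region with a multiple-regions rule, the Injury
Severity Score (sum of squared highest AIS severities in the three most
severely injured distinct body regions, any unsurvivable grade forcing the
maximum of 75), comorbidity-count categories, same-calendar-year reinjury
flags, and per-sample quartile thresholds for hospital volume variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

INTENT_LABELS = {
    "assault", "self-inflicted", "unintentional", "undetermined", "legal intervention",
}

REGION_LABELS = {"head/neck", "face", "chest", "abdomen", "extremities", "other"}


@dataclass
class IntentMap:
    """Ordered (code prefix -> intent label) lookup, longest prefix first."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for prefix, label in self.entries:
            if label not in INTENT_LABELS:
                raise ValidationError(f"unknown intent label {label!r}")
        # longest-prefix-first so a more specific prefix always wins
        self.entries = sorted(self.entries, key=lambda e: -len(e[0]))

    def classify(self, cause_code: str) -> str:
        for prefix, label in self.entries:
            if cause_code.startswith(prefix):
                return label
        log.warning("cause code %r matched no intent prefix; using undetermined", cause_code)
        return "undetermined"

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["prefix", "label"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IntentMap":
        frame = pd.read_csv(path, dtype=str)
        return cls(list(frame[["prefix", "label"]].itertuples(index=False, name=None)))


def default_intent_map() -> IntentMap:
    entries = []
    for code in ("W32", "W33", "W34"):
        entries.append((code, "unintentional"))
    for code in ("X72", "X73", "X74"):
        entries.append((code, "self-inflicted"))
    for code in ("X93", "X94", "X95"):
        entries.append((code, "assault"))
    for code in ("Y22", "Y23", "Y24"):
        entries.append((code, "undetermined"))
    entries.append(("Y35.0", "legal intervention"))
    return IntentMap(entries)


@dataclass
class RegionMap:
    """Diagnosis region code -> body region label lookup."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for label in self.mapping.values():
            if label not in REGION_LABELS:
                raise ValidationError(f"unknown region label {label!r}")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["code", "label"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionMap":
        frame = pd.read_csv(path, dtype=str)
        return cls(dict(zip(frame["code"], frame["label"])))


def default_region_map() -> RegionMap:
    return RegionMap(
        {
            "HN": "head/neck",
            "FA": "face",
            "CH": "chest",
            "AB": "abdomen",
            "EX": "extremities",
            "OT": "other",
        }
    )


def classify_intent(cause_code: str, intent_map: IntentMap | None = None) -> str:
    """Intent label for an external-cause code via longest-prefix match."""
    return (intent_map or default_intent_map()).classify(cause_code)


def assign_body_region(region_codes, region_map: RegionMap | None = None) -> str:
    """Single region label, ``multiple regions`` for >=2 distinct mapped
    regions, ``other`` when nothing maps."""
    rmap = (region_map or default_region_map()).mapping
    labels = {rmap[c] for c in region_codes if c in rmap}
    if not labels:
        return "other"
    if len(labels) == 1:
        return labels.pop()
    return "multiple regions"


def parse_ais(text) -> list[tuple[str, int]]:
    """Parse an ``REGION:severity;REGION:severity`` string."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    out = []
    for part in str(text).split(";"):
        region, sev = part.split(":")
        out.append((region, int(sev)))
    return out


def compute_iss(ais_codes, mode: str = "strict") -> int:
    """Injury Severity Score from (region, AIS severity) pairs.

    ``strict`` (default): sum of squares of the highest severity in each of
    the three most severely injured distinct regions. ``sum_all``: sum of
    squares of every severity, capped at 75. Either way, any severity of 6
    (unsurvivable) forces the maximum score of 75.
    """
    sevs = []
    for region, sev in ais_codes:
        if not 1 <= int(sev) <= 6:
            raise ValidationError(f"AIS severity {sev} outside 1-6")
        sevs.append((region, int(sev)))
    if not sevs:
        return 0
    if any(s == 6 for _, s in sevs):
        return 75
    if mode == "strict":
        per_region: dict[str, int] = {}
        for region, s in sevs:
            per_region[region] = max(per_region.get(region, 0), s)
        top = sorted(per_region.values(), reverse=True)[:3]
        score = sum(s * s for s in top)
    elif mode == "sum_all":
        score = sum(s * s for _, s in sevs)
    else:
        raise ConfigurationError(f"unknown ISS mode {mode!r}")
    return min(score, 75)


def categorize_iss(score: int) -> str:
    """Severity bands: 0-8 mild, 9-25 serious, 26-75 severe."""
    if not 0 <= score <= 75:
        raise ValidationError(f"ISS {score} outside [0, 75]")
    if score <= 8:
        return "mild"
    if score <= 25:
        return "serious"
    return "severe"


def categorize_comorbidity(count: int) -> str:
    """Comorbidity-count bands: 0, 1, 2, >=3."""
    if count < 0:
        raise ValidationError(f"negative comorbidity count {count}")
    return str(count) if count < 3 else ">=3"


def flag_reinjury(visits: pd.DataFrame) -> pd.Series:
    """1 for every visit of a (person, calendar year) group with >=2 visits.

    Person linkage never crosses calendar years, so a person seen once in
    each of two years is never flagged. Output is independent of row order.
    """
    if visits.empty:
        return pd.Series([], dtype=int, index=visits.index)
    sizes = visits.groupby(["person_link", "year"])["person_link"].transform("size")
    return (sizes >= 2).astype(int)


@dataclass
class QuartileThresholds:
    """Ascending 25th/50th/75th percentile cuts for a named variable."""

    name: str
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValidationError(f"quartile thresholds for {self.name} not ascending")


def compute_quartile_thresholds(values, name: str = "") -> QuartileThresholds:
    """Inclusive linear-interpolation quartile cuts over finite values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 4:
        raise DegenerateInputError(
            f"need >=4 finite values for quartiles of {name or 'variable'}, got {len(arr)}"
        )
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return QuartileThresholds(name, float(q1), float(q2), float(q3))


def assign_quartiles(values, thresholds: QuartileThresholds) -> np.ndarray:
    """Quartile labels with ties at a cut going to the lower quartile."""
    arr = np.asarray(values, dtype=float)
    return np.select(
        [arr <= thresholds.q1, arr <= thresholds.q2, arr <= thresholds.q3],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )


def recode_no_charge(visits: pd.DataFrame, states) -> pd.DataFrame:
    """Recode payer ``no-charge`` to ``self-pay`` for the given states.

    Some state data systems fold uncompensated-care visits into self-pay;
    the recode keeps the payer variable comparable across states.
    """
    out = visits.copy()
    mask = out["state"].isin(list(states)) & (out["payer"] == "no-charge")
    out.loc[mask, "payer"] = "self-pay"
    return out


def derive_all(
    visits: pd.DataFrame,
    intent_map: IntentMap | None = None,
    region_map: RegionMap | None = None,
    iss_mode: str = "strict",
    self_pay_dialect_states=(),
) -> pd.DataFrame:
    """Append every derived column to a costed visits table.

    Adds ``intent``, ``body_region``, ``iss``, ``iss_category``,
    ``comorbidity_category`` and ``reinjury_flag``; applies the per-state
    no-charge payer recode first so it is reflected in stratified output.
    """
    imap = intent_map or default_intent_map()
    rmap = region_map or default_region_map()
    out = recode_no_charge(visits, self_pay_dialect_states)

    cause = out["cause_code"].astype(str)
    intent_lut = {c: imap.classify(c) for c in cause.unique()}
    out["intent"] = cause.map(intent_lut)

    regions = out["diagnosis_region_codes"].fillna("").astype(str)
    region_lut = {
        s: assign_body_region(s.split(";") if s else [], rmap) for s in regions.unique()
    }
    out["body_region"] = regions.map(region_lut)

    ais = out["ais_codes"].fillna("").astype(str)
    iss_lut = {s: compute_iss(parse_ais(s), mode=iss_mode) for s in ais.unique()}
    out["iss"] = ais.map(iss_lut).astype(int)
    out["iss_category"] = out["iss"].map(categorize_iss)

    out["comorbidity_category"] = out["comorbidity_count"].map(categorize_comorbidity)
    out["reinjury_flag"] = flag_reinjury(out)
    return out


def write_default_maps(out_dir) -> None:
    """Ship the editable intent/region lookup tables as CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    default_intent_map().to_csv(out / "intent_map.csv")
    default_region_map().to_csv(out / "region_map.csv")
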