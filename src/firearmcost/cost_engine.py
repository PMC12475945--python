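"""Visit-level cost construction.

Converts nominal billed charges into estimated hospital resource costs
(charge x hospital-year cost-to-charge ratio) expressed in base-year
dollars (annual price-index rescaling), after applying the two row
filters of the analytic sample: new-injury cause codes only, and
non-missing charges only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CCRLookupError, MissingIndexError, ValidationError

#: Upper bound accepted for a cost-to-charge ratio. Ratios above 1 occur in
#: real hospital accounting data; values beyond 1.5 are treated as corrupt.
CCR_MAX = 1.5


@dataclass
class CCRTable:
    """Hospital-year cost-to-charge ratios.

    Wraps a frame with columns ``hospital_id``, ``year``, ``ccr``; every
    ratio must lie in ``(0, CCR_MAX]``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hospital_id", "year", "ccr"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"CCR table needs columns {sorted(required)}")
        ratios = self.frame["ccr"].to_numpy(dtype=float)
        if len(ratios) and ((ratios <= 0) | (ratios > CCR_MAX)).any():
            bad = self.frame.loc[(ratios <= 0) | (ratios > CCR_MAX)].iloc[0]
            raise ValidationError(
                f"cost-to-charge ratio {bad['ccr']} for hospital "
                f"{bad['hospital_id']!r} year {bad['year']} outside (0, {CCR_MAX}]"
            )
        if self.frame.duplicated(["hospital_id", "year"]).any():
            raise ValidationError("duplicate (hospital, year) in CCR table")

    def lookup(self, hospital_id, year) -> float:
        mask = (self.frame["hospital_id"] == hospital_id) & (
            self.frame["year"] == year
        )
        sub = self.frame.loc[mask, "ccr"]
        if sub.empty:
            raise CCRLookupError(hospital_id, year)
        return float(sub.iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CCRTable":
        return cls(pd.read_csv(path, dtype={"hospital_id": str}))


@dataclass
class CPITable:
    """Annual price index with a base year (defaults to 2024).

    ``factor(year)`` is the multiplier taking a ``year``-dollar amount to
    base-year dollars: index(base) / index(year).
    """

    index: dict[int, float]
    base_year: int = 2024
    _idx: dict[int, float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._idx = {int(y): float(v) for y, v in self.index.items()}
        if any(v <= 0 for v in self._idx.values()):
            raise ValidationError("price index values must be positive")
        if self.base_year not in self._idx:
            raise MissingIndexError(self.base_year)

    def value(self, year: int) -> float:
        try:
            return self._idx[int(year)]
        except KeyError:
            raise MissingIndexError(year) from None

    def factor(self, year: int) -> float:
        return self._idx[self.base_year] / self.value(year)

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            {"year": sorted(self._idx), "index": [self._idx[y] for y in sorted(self._idx)]}
        )
        frame["base_year"] = self.base_year
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CPITable":
        frame = pd.read_csv(path)
        base = int(frame["base_year"].iloc[0]) if "base_year" in frame else 2024
        return cls(dict(zip(frame["year"].astype(int), frame["index"])), base)


def filter_new_injury(visits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep visits whose cause code ends in the new-encounter character ``A``.

    Malformed (missing/empty) codes are dropped and counted together with
    subsequent-encounter codes. Row order is preserved.
    """
    if visits.empty:
        return visits.copy(), 0
    codes = visits["cause_code"]
    wellformed = codes.notna() & (codes.astype(str).str.len() > 0)
    kept_mask = wellformed & codes.astype(str).str.endswith("A")
    kept = visits.loc[kept_mask]
    return kept, int(len(visits) - len(kept))


def exclude_missing_charge(visits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop visits without a charge value; returns (kept, excluded_count)."""
    if visits.empty:
        return visits.copy(), 0
    kept = visits.loc[visits["total_charge"].notna()]
    return kept, int(len(visits) - len(kept))


def compute_cost(charge: float, ratio: float) -> float:
    """Estimated resource cost: billed charge x cost-to-charge ratio."""
    if charge is None or (isinstance(charge, float) and math.isnan(charge)):
        raise ValidationError("charge is missing; exclude the visit first")
    if charge < 0:
        raise ValidationError(f"negative charge {charge}")
    if not 0 < ratio <= CCR_MAX:
        raise ValidationError(f"ratio {ratio} outside (0, {CCR_MAX}]")
    return charge * ratio


def adjust_to_base_year(cost: float, year: int, cpi: CPITable) -> float:
    """Rescale a nominal-year cost to base-year dollars via the price index."""
    return cost * cpi.factor(year)


def apply_costs(visits: pd.DataFrame, ccr: CCRTable, cpi: CPITable) -> pd.DataFrame:
    """Vectorised costing: adds ``cost`` and ``cost_base`` columns.

    Raises :class:`CCRLookupError` if any (hospital, year) pair lacks a
    ratio and :class:`MissingIndexError` if any visit year lacks an index.
    """
    out = visits.merge(
        ccr.frame, on=["hospital_id", "year"], how="left", validate="m:1"
    )
    out.index = visits.index
    if out["ccr"].isna().any():
        row = out.loc[out["ccr"].isna()].iloc[0]
        raise CCRLookupError(row["hospital_id"], int(row["year"]))
    factors = {y: cpi.factor(y) for y in out["year"].unique()}
    out["cost"] = out["total_charge"].to_numpy(dtype=float) * out["ccr"].to_numpy()
    out["cost_base"] = out["cost"] * out["year"].map(factors).to_numpy()
    return out


def cost_pipeline(
    visits: pd.DataFrame, ccr: CCRTable, cpi: CPITable
) -> tuple[pd.DataFrame, dict]:
    """Full costing pass: new-injury filter, missing-charge exclusion, costing.

    Returns the costed analytic sample and a summary dict with the drop
    counts (both filters are row predicates, so their order is immaterial).
    """
    kept, dropped_not_new = filter_new_injury(visits)
    kept, excluded_missing = exclude_missing_charge(kept)
    costed = apply_costs(kept, ccr, cpi)
    summary = {
        "n_input": int(len(visits)),
        "dropped_not_new_injury": dropped_not_new,
        "excluded_missing_charge": excluded_missing,
        "n_costed": int(len(costed)),
    }
    return costed, summary
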