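"""Exception hierarchy for the firearmcost pipeline."""


class FirearmCostError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FirearmCostError):
    """Invalid generator/simulation configuration or unknown option value."""


class ValidationError(FirearmCostError):
    """An input value violates a documented domain constraint."""


class CCRLookupError(FirearmCostError):
    """No cost-to-charge ratio for a (hospital, year) pair appearing in visits."""

    def __init__(self, hospital_id, year):
        self.hospital_id = hospital_id
        self.year = year
        super().__init__(
            f"no cost-to-charge ratio for hospital {hospital_id!r}, year {year}"
        )


class MissingIndexError(FirearmCostError):
    """A calendar year is absent from the price-index table."""

    def __init__(self, year):
        self.year = year
        super().__init__(f"no price index for year {year}")


class DegenerateInputError(FirearmCostError):
    """Too few values to compute the requested statistic."""


class EmptyPoolError(FirearmCostError):
    """A resampling pool is empty but a positive draw count was requested."""

    def __init__(self, year, visit_type, n):
        self.year = year
        self.visit_type = visit_type
        super().__init__(
            f"empty {visit_type} pool for year {year} with {n} draws requested"
        )


class AggregationError(FirearmCostError):
    """Simulation results cannot be aggregated (e.g. mismatched cell sets)."""


class UndefinedShareError(FirearmCostError):
    """Share of total requested against a zero denominator."""
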