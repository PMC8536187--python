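"""Domain vocabulary shared across the audit pipeline.

The unit of observation is a serum electrolyte measurement (a *lab event*)
and an electrolyte-replacement order (a *repletion event*) inside an ICU
stay.  Three electrolytes are audited: potassium (mEq/L), magnesium and
phosphate (both mg/dL).  Values are carried in their native units and never
converted; timestamps are timezone-naive at minute resolution, and all time
arithmetic is done in minutes (de-identified ICU data preserve time of day
and time differences, not calendar truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: The closed set of audited electrolytes.
ELECTROLYTES: tuple[str, ...] = ("potassium", "magnesium", "phosphate")

#: Native unit label carried with each electrolyte's serum values.
VALUE_UNITS: dict[str, str] = {
    "potassium": "mEq/L",
    "magnesium": "mg/dL",
    "phosphate": "mg/dL",
}

#: Scenario labels: lab with no repletion within 24 h; a single lab followed
#: by one repletion; multiple labs preceding one repletion (closest used).
SCENARIO_NR = "NR"
SCENARIO_1L1R = "1L_1R"
SCENARIO_ML1R = "ML_1R"
SCENARIOS: tuple[str, ...] = (SCENARIO_NR, SCENARIO_1L1R, SCENARIO_ML1R)

#: ICU unit labels used by the synthetic generator and the ANOVA grouping.
ICU_UNITS: tuple[str, ...] = ("MICU", "SICU", "CICU", "HVICU", "other")

#: Classification labels relative to a nominal range, in increasing order.
LABEL_BELOW = "below"
LABEL_WITHIN = "within"
LABEL_ABOVE = "above"
RANGE_LABELS: tuple[str, ...] = (LABEL_BELOW, LABEL_WITHIN, LABEL_ABOVE)


@dataclass(frozen=True)
class ReferenceRange:
    """Nominal laboratory interval; values outside it are flagged abnormal.

    ``low_inclusive``/``high_inclusive`` state whether a value exactly on a
    bound counts as *within* (the clinical default) or as out of range.
    """

    electrolyte: str
    low: float
    high: float
    low_inclusive: bool = True
    high_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.electrolyte not in ELECTROLYTES:
            raise ConfigError(f"unknown electrolyte {self.electrolyte!r}")
        if not self.low < self.high:
            raise ConfigError(
                f"reference range for {self.electrolyte} must have low < high, "
                f"got [{self.low}, {self.high}]"
            )


def default_reference_ranges() -> dict[str, ReferenceRange]:
    """Nominal ranges as flagged in the source database.

    3.7-5.7 mEq/L for potassium and 2.5-4.5 mg/dL for magnesium and
    phosphate, inclusive at both bounds.  These are defaults, not dogma:
    every classification entry point takes the ranges explicitly so a user
    can supply the intervals their own institution flags.
    """
    return {
        "potassium": ReferenceRange("potassium", 3.7, 5.7),
        "magnesium": ReferenceRange("magnesium", 2.5, 4.5),
        "phosphate": ReferenceRange("phosphate", 2.5, 4.5),
    }


def default_error_bounds() -> dict[str, tuple[float, float]]:
    """Physiologic plausibility bounds used to discard entry errors.

    Pre-repletion serum values strictly below/above these limits are treated
    as charting errors: potassium outside [2, 7] mEq/L, magnesium outside
    [1, 5] mg/dL, phosphate outside [0.5, 5] mg/dL.  Boundary values are
    retained (removal is strict on both sides).
    """
    return {
        "potassium": (2.0, 7.0),
        "magnesium": (1.0, 5.0),
        "phosphate": (0.5, 5.0),
    }


@dataclass
class ValidationReport:
    """Row-level accounting for one table read: nothing is silently dropped."""

    n_rows_read: int = 0
    n_rows_rejected: int = 0
    rejection_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_rows_accepted(self) -> int:
        return self.n_rows_read - self.n_rows_rejected

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rows_rejected += n
        self.rejection_reasons[reason] = self.rejection_reasons.get(reason, 0) + n

    def check(self) -> None:
        if sum(self.rejection_reasons.values()) != self.n_rows_rejected:
            raise AssertionError("rejection reasons do not sum to rejected count")
        if self.n_rows_accepted < 0:
            raise AssertionError("more rows rejected than read")
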