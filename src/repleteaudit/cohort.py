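"""Cohort construction: the exclusion cascade with a full attrition log.

The analyzable cohort is built by, in order: dropping stays with neither a
lab value nor a repletion, the pediatric exclusion (age strictly under the
minimum), first-diagnosis ICD-9 exclusions (one named code set per
condition, applied in configured order, matched against the ``seq_num == 1``
diagnosis only), and physiologic error bounds on serum values (event-level,
strict inequalities: boundary values are retained).

Every rule appends one entry to an :class:`AttritionLog`, which conserves
counts (``final == initial - sum(removed)``) by construction and is emitted
as CSV and human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .model import default_error_bounds

#: Conditions excluded by default, in application order.  The code sets are
#: deliberately editable configuration: institutional ICD-9 groupings vary,
#: so each set ships with a small, sensible default grouping (3-digit
#: prefixes match any more specific code).
DEFAULT_EXCLUDED_CONDITIONS: dict[str, tuple[str, ...]] = {
    "prbc_transfusion": ("9904",),
    "rhabdomyolysis": ("72888",),
    "parathyroid_disease": ("252",),
    "sarcoidosis": ("135",),
    "chronic_kidney_disease": ("585",),
    "acute_kidney_injury": ("584",),
    "end_stage_renal_disease": ("5856",),
    "coronary_artery_disease": ("414", "4140", "41401"),
    "congestive_heart_failure": ("428",),
    "atrial_fibrillation": ("42731",),
    "nutritional_deficiency": ("269",),
    "paralysis": ("344",),
    "dialysis_procedure": ("3995", "5498"),
}


@dataclass(frozen=True)
class ExclusionRule:
    """One named cohort filter.

    ``kind`` is one of ``diagnosis_code_set`` / ``procedure_code_set``
    (payload: ICD-9 code prefixes), ``age_minimum`` (payload: years) or
    ``value_bounds`` (payload: ``{electrolyte: (low, high)}``).
    """

    name: str
    kind: str
    payload: object

    def __post_init__(self) -> None:
        if self.kind in ("diagnosis_code_set", "procedure_code_set"):
            if not self.payload:
                raise ConfigError(f"rule {self.name!r}: empty code set")
        elif self.kind == "age_minimum":
            float(self.payload)  # type: ignore[arg-type]
        elif self.kind == "value_bounds":
            for elec, (low, high) in dict(self.payload).items():  # type: ignore[call-overload]
                if not low < high:
                    raise ConfigError(
                        f"rule {self.name!r}: bounds for {elec} must satisfy low < high"
                    )
        else:
            raise ConfigError(f"rule {self.name!r}: unknown kind {self.kind!r}")


def default_exclusion_rules(minimum_age: float = 18.0) -> list[ExclusionRule]:
    rules = [ExclusionRule("age_under_minimum", "age_minimum", minimum_age)]
    rules += [
        ExclusionRule(name, "diagnosis_code_set", codes)
        for name, codes in DEFAULT_EXCLUDED_CONDITIONS.items()
        if name != "dialysis_procedure"
    ]
    rules.append(
        ExclusionRule(
            "dialysis_procedure",
            "procedure_code_set",
            DEFAULT_EXCLUDED_CONDITIONS["dialysis_procedure"],
        )
    )
    rules.append(ExclusionRule("value_error_bounds", "value_bounds", default_error_bounds()))
    return rules


@dataclass
class AttritionLog:
    """Ordered record of (rule, removed, remaining) for one cohort build.

    ``level`` distinguishes stay-level rules from event-level ones (value
    bounds remove individual lab events, not encounters), so both kinds of
    count are reported.
    """

    entries: list[dict] = field(default_factory=list)

    def add(self, rule_name: str, level: str, n_removed: int, n_remaining: int) -> None:
        if self.entries:
            prev = [e for e in self.entries if e["level"] == level]
            if prev and n_remaining > prev[-1]["n_remaining"]:
                raise AssertionError("attrition log remaining count increased")
        self.entries.append(
            {
                "rule": rule_name,
                "level": level,
                "n_removed": int(n_removed),
                "n_remaining": int(n_remaining),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["rule", "level", "n_removed", "n_remaining"]
        )

    def removed(self, rule_name: str) -> int:
        return sum(e["n_removed"] for e in self.entries if e["rule"] == rule_name)

    def check(self, level: str = "stay") -> None:
        ent = [e for e in self.entries if e["level"] == level]
        if not ent:
            return
        initial = ent[0]["n_remaining"] + ent[0]["n_removed"]
        if ent[-1]["n_remaining"] != initial - sum(e["n_removed"] for e in ent):
            raise AssertionError("attrition conservation violated")

    def __str__(self) -> str:
        lines = ["Attrition log", "-------------"]
        for e in self.entries:
            lines.append(
                f"{e['rule']:<28s} [{e['level']}]  removed {e['n_removed']:>7d}"
                f"  remaining {e['n_remaining']:>8d}"
            )
        return "\n".join(lines)


def apply_age_filter(
    stays: pd.DataFrame, minimum_age: float = 18.0, log: AttritionLog | None = None
) -> tuple[pd.DataFrame, AttritionLog]:
    """Drop stays of patients strictly under ``minimum_age`` years.

    "Under 18" is strict: a patient aged exactly 18.0 is retained.  Stays
    with missing age are removed under the separate reason ``age_missing``.
    """
    if "age_years" not in stays.columns:
        raise ConfigError("stay table lacks age_years; cannot apply age filter")
    log = log if log is not None else AttritionLog()
    missing = stays["age_years"].isna()
    under = ~missing & (stays["age_years"] < minimum_age)
    kept = stays.loc[~missing & ~under]
    log.add("age_missing", "stay", int(missing.sum()), len(stays) - int(missing.sum()))
    log.add("age_under_minimum", "stay", int(under.sum()), len(kept))
    return kept, log


def first_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """The ``seq_num == 1`` (most relevant) diagnosis of each stay."""
    return diagnoses.loc[diagnoses["seq_num"] == 1]


def _codes_match(codes: pd.Series, code_set) -> pd.Series:
    """Prefix match: a configured code matches itself and any refinement."""
    prefixes = tuple(str(c) for c in code_set)
    return codes.astype(str).map(lambda c: c.startswith(prefixes))


def apply_diagnosis_exclusions(
    stays: pd.DataFrame,
    diagnoses: pd.DataFrame,
    rules: list[ExclusionRule],
    log: AttritionLog | None = None,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Remove stays whose *first* diagnosis is in any rule's code set.

    Only the ``seq_num == 1`` code is consulted: an excluded code appearing
    at ``seq_num >= 2`` never removes a stay.  Stays without any diagnosis
    are removed under ``diagnosis_missing``.  One log entry per rule, in
    configured order.
    """
    log = log if log is not None else AttritionLog()
    first = first_diagnoses(diagnoses).set_index("stay_id")["icd9_code"]
    first = first[~first.index.duplicated(keep="first")]
    stay_first = stays["stay_id"].map(first)

    missing = stay_first.isna()
    kept = stays.loc[~missing].copy()
    stay_first = stay_first.loc[~missing]
    log.add("diagnosis_missing", "stay", int(missing.sum()), len(kept))

    for rule in rules:
        if rule.kind not in ("diagnosis_code_set", "procedure_code_set"):
            continue
        hit = _codes_match(stay_first, rule.payload)
        kept = kept.loc[~hit.to_numpy()]
        stay_first = stay_first.loc[~hit]
        log.add(rule.name, "stay", int(hit.sum()), len(kept))
    return kept, log


def apply_value_error_filter(
    labs: pd.DataFrame,
    bounds: dict[str, tuple[float, float]] | None = None,
    log: AttritionLog | None = None,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Remove physiologically implausible serum values (entry errors).

    Removal is strict on both sides — e.g. potassium is removed only when
    *below* 2 or *above* 7 mEq/L, so 2.0 and 7.0 are retained.  Counts are
    logged per electrolyte at event level.
    """
    bounds = bounds if bounds is not None else default_error_bounds()
    log = log if log is not None else AttritionLog()
    for elec in labs["electrolyte"].unique():
        if elec not in bounds:
            raise ConfigError(f"no error bounds configured for electrolyte {elec!r}")
    keep = pd.Series(True, index=labs.index)
    for elec, (low, high) in bounds.items():
        sel = labs["electrolyte"] == elec
        bad = sel & ((labs["value"] < low) | (labs["value"] > high))
        keep &= ~bad
        log.add(f"value_error_{elec}", "event", int(bad.sum()), int(keep.sum()))
    return labs.loc[keep], log


def build_cohort(
    tables: dict[str, pd.DataFrame],
    rules: list[ExclusionRule] | None = None,
) -> tuple[dict[str, pd.DataFrame], AttritionLog]:
    """Apply the full exclusion cascade and return the analyzable bundle.

    ``tables`` holds canonical ``stays``, ``labs``, ``repletions`` and
    ``diagnoses`` frames.  Stays lacking both a lab value and a repletion
    are removed first; the configured rules then run in order (age filters,
    diagnosis/procedure code sets at stay level, value bounds at event
    level).  Event tables are restricted to the surviving stays.
    """
    rules = rules if rules is not None else default_exclusion_rules()
    for rule in rules:
        if rule.kind not in ("age_minimum", "diagnosis_code_set", "procedure_code_set", "value_bounds"):
            raise ConfigError(f"unknown rule kind {rule.kind!r}")
    stays = tables["stays"]
    labs = tables["labs"]
    repletions = tables["repletions"]
    diagnoses = tables["diagnoses"]
    log = AttritionLog()

    with_events = set(labs["stay_id"]) | set(repletions["stay_id"])
    has_events = stays["stay_id"].isin(with_events)
    stays = stays.loc[has_events]
    log.add("no_lab_or_repletion", "stay", int((~has_events).sum()), len(stays))

    dx_rules = [r for r in rules if r.kind in ("diagnosis_code_set", "procedure_code_set")]
    for rule in rules:
        if rule.kind == "age_minimum":
            stays, log = apply_age_filter(stays, float(rule.payload), log)  # type: ignore[arg-type]
    if dx_rules:
        stays, log = apply_diagnosis_exclusions(stays, diagnoses, dx_rules, log)

    keep_ids = set(stays["stay_id"])
    n_before = len(labs) + len(repletions)
    labs = labs.loc[labs["stay_id"].isin(keep_ids)]
    repletions = repletions.loc[repletions["stay_id"].isin(keep_ids)]
    log.add("events_of_excluded_stays", "event", n_before - len(labs) - len(repletions), len(labs))

    for rule in rules:
        if rule.kind == "value_bounds":
            labs, log = apply_value_error_filter(
                labs, {k: tuple(v) for k, v in dict(rule.payload).items()}, log  # type: ignore[call-overload]
            )

    log.check("stay")
    out = {
        "stays": stays.reset_index(drop=True),
        "labs": labs.reset_index(drop=True),
        "repletions": repletions.reset_index(drop=True),
        "diagnoses": diagnoses.loc[diagnoses["stay_id"].isin(keep_ids)].reset_index(drop=True),
    }
    return out, log
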