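"""Nominal-range interpretation of pre-order values.

Labels every episode's index (pre-order) value *below*, *within* or *above*
its electrolyte's nominal range and aggregates the audit's headline tables:
the interpretation table (counts, percentages, mean +/- SD per cell, split
by repletion vs non-repletion episodes), the per-electrolyte fraction of
lab orders followed by repletion, and the near-miss frequency (repletions
given when the preceding value was already above range).

Ranges are explicit arguments everywhere: nominal intervals are an
institutional convention, and the audit's conclusions hinge on them.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError
from .model import (
    LABEL_ABOVE,
    LABEL_BELOW,
    LABEL_WITHIN,
    RANGE_LABELS,
    SCENARIO_NR,
    ReferenceRange,
)

GROUP_REPLETION = "repletion"
GROUP_NON_REPLETION = "non_repletion"


def classify_value(value: float, range_: ReferenceRange) -> str:
    """Label one value relative to its nominal range."""
    return classify_values(np.asarray([value], dtype=float), range_)[0]


def classify_values(values: np.ndarray, range_: ReferenceRange) -> np.ndarray:
    """Vectorized below/within/above labelling.

    Inclusive bounds (the default) send a value exactly on a bound to
    *within*; exclusive bounds send it out of range.  Monotone in the
    value: increasing a value never moves its label toward *below*.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise DataError("cannot classify non-finite serum values")
    below = values < range_.low if range_.low_inclusive else values <= range_.low
    above = values > range_.high if range_.high_inclusive else values >= range_.high
    out = np.full(values.shape, LABEL_WITHIN, dtype=object)
    out[below] = LABEL_BELOW
    out[above] = LABEL_ABOVE
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for printed percentages."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def interpretation_table(
    episodes: pd.DataFrame, ranges: dict[str, ReferenceRange]
) -> pd.DataFrame:
    """The audit's central contingency table.

    One row per (electrolyte, scenario group, label) cell with count,
    percentage within the group, and mean +/- SD of the index values in the
    cell.  Cells partition the episodes; per-group percentages sum to 100
    up to rounding.  Empty cells are emitted with ``n == 0`` and NaN
    moments.  ``percent`` carries full precision; use
    :func:`round_half_up` for presentation.
    """
    rows = []
    ep = episodes.assign(
        _group=np.where(episodes["scenario"] == SCENARIO_NR, GROUP_NON_REPLETION, GROUP_REPLETION)
    )
    for elec in sorted(ep["electrolyte"].unique()):
        if elec not in ranges:
            raise DataError(f"no reference range configured for {elec!r}")
        sub = ep.loc[ep["electrolyte"] == elec]
        labels = classify_values(sub["index_value"].to_numpy(dtype=float), ranges[elec])
        for group in (GROUP_NON_REPLETION, GROUP_REPLETION):
            in_group = (sub["_group"] == group).to_numpy()
            n_group = int(in_group.sum())
            for label in (LABEL_ABOVE, LABEL_WITHIN, LABEL_BELOW):
                vals = sub["index_value"].to_numpy(dtype=float)[in_group & (labels == label)]
                rows.append(
                    {
                        "electrolyte": elec,
                        "scenario_group": group,
                        "label": label,
                        "n": len(vals),
                        "percent": 100.0 * len(vals) / n_group if n_group else np.nan,
                        "mean_value": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd_value": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["electrolyte", "scenario_group", "label", "n", "percent", "mean_value", "sd_value"],
    )


def repletion_fraction(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-electrolyte share of lab-order episodes followed by repletion.

    The denominator counts episodes (repletion episodes plus ``NR``
    episodes); draws consumed as *ignored* inside multi-lab windows are not
    separate orders.  NaN (undefined, not zero) when an electrolyte has no
    episodes.
    """
    rows = []
    for elec, grp in episodes.groupby("electrolyte", sort=True):
        n_rep = int((grp["scenario"] != SCENARIO_NR).sum())
        n_tot = len(grp)
        rows.append(
            {
                "electrolyte": elec,
                "n_repletion": n_rep,
                "n_episodes": n_tot,
                "fraction": n_rep / n_tot if n_tot else np.nan,
                "percent": 100.0 * n_rep / n_tot if n_tot else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["electrolyte", "n_repletion", "n_episodes", "fraction", "percent"])


def near_miss_frequencies(
    episodes: pd.DataFrame, ranges: dict[str, ReferenceRange]
) -> pd.DataFrame:
    """Share of repletion episodes whose pre-order value was already above range.

    These are the audit's "misses and near-misses": supplements given on
    top of an already supra-nominal serum level.  Equals the *above* cell
    percentage restricted to the repletion group of the interpretation
    table.
    """
    table = interpretation_table(episodes, ranges)
    rep = table.loc[table["scenario_group"] == GROUP_REPLETION]
    rows = []
    for elec, grp in rep.groupby("electrolyte", sort=True):
        n_group = int(grp["n"].sum())
        n_above = int(grp.loc[grp["label"] == LABEL_ABOVE, "n"].sum())
        rows.append(
            {
                "electrolyte": elec,
                "n_above": n_above,
                "n_repletion": n_group,
                "percent": 100.0 * n_above / n_group if n_group else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["electrolyte", "n_above", "n_repletion", "percent"])


def check_partition(table: pd.DataFrame, episodes: pd.DataFrame) -> None:
    """Assert that interpretation cells partition the episodes."""
    if int(table["n"].sum()) != len(episodes):
        raise AssertionError("interpretation cells do not partition the episodes")
    for (_, _), grp in table.groupby(["electrolyte", "scenario_group"]):
        if grp["n"].sum() and not np.isclose(grp["percent"].sum(), 100.0, atol=0.02):
            raise AssertionError("cell percentages do not normalize to 100")


__all__ = [
    "GROUP_NON_REPLETION",
    "GROUP_REPLETION",
    "RANGE_LABELS",
    "classify_value",
    "classify_values",
    "interpretation_table",
    "near_miss_frequencies",
    "repletion_fraction",
    "round_half_up",
]
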