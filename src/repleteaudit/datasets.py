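"""Published audit summary counts, usable as worked-example inputs.

A published ICU repletion audit reports, for each electrolyte, how many
pre-order values fell below/within/above the nominal range, split by
whether a repletion followed.  Those printed counts are sufficient input to
re-derive every percentage in the summary table (repletion fractions,
interpretation percentages, near-miss frequencies), which makes them a
compact worked example and an exact arithmetic check of the aggregation
code.

:func:`episodes_from_counts` expands a count table into a *synthetic*
episode frame — one episode per counted case with a representative value
planted inside the right label region — so the counts can be fed through
the same aggregation functions as real linked episodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import GROUP_NON_REPLETION, GROUP_REPLETION
from .model import (
    LABEL_ABOVE,
    LABEL_BELOW,
    LABEL_WITHIN,
    SCENARIO_1L1R,
    SCENARIO_NR,
    ReferenceRange,
)

_PUBLISHED = [
    # electrolyte, group, label, n, mean, sd
    ("potassium", GROUP_NON_REPLETION, LABEL_ABOVE, 5790, 6.05, 0.83),
    ("potassium", GROUP_NON_REPLETION, LABEL_WITHIN, 185666, 3.95, 0.42),
    ("potassium", GROUP_NON_REPLETION, LABEL_BELOW, 22410, 3.00, 0.26),
    ("potassium", GROUP_REPLETION, LABEL_ABOVE, 27, 5.69, 0.42),
    ("potassium", GROUP_REPLETION, LABEL_WITHIN, 6400, 3.84, 0.31),
    ("potassium", GROUP_REPLETION, LABEL_BELOW, 739, 3.02, 0.19),
    ("magnesium", GROUP_NON_REPLETION, LABEL_ABOVE, 812, 2.96, 0.70),
    ("magnesium", GROUP_NON_REPLETION, LABEL_WITHIN, 26823, 2.03, 0.22),
    ("magnesium", GROUP_NON_REPLETION, LABEL_BELOW, 4729, 1.38, 0.16),
    ("magnesium", GROUP_REPLETION, LABEL_ABOVE, 55, 3.06, 0.39),
    ("magnesium", GROUP_REPLETION, LABEL_WITHIN, 3041, 1.90, 0.16),
    ("magnesium", GROUP_REPLETION, LABEL_BELOW, 647, 1.41, 0.12),
    ("phosphate", GROUP_NON_REPLETION, LABEL_ABOVE, 22, 4.85, 0.49),
    ("phosphate", GROUP_NON_REPLETION, LABEL_WITHIN, 696, 3.28, 0.34),
    ("phosphate", GROUP_NON_REPLETION, LABEL_BELOW, 762, 2.05, 0.46),
    ("phosphate", GROUP_REPLETION, LABEL_ABOVE, 0, np.nan, np.nan),
    ("phosphate", GROUP_REPLETION, LABEL_WITHIN, 7, 3.04, 0.28),
    ("phosphate", GROUP_REPLETION, LABEL_BELOW, 288, 1.89, 0.43),
]


def published_interpretation_counts() -> pd.DataFrame:
    """The published per-cell counts (and printed mean +/- SD) as a frame."""
    return pd.DataFrame(
        _PUBLISHED,
        columns=["electrolyte", "scenario_group", "label", "n", "mean_value", "sd_value"],
    )


def published_reference_ranges() -> dict[str, ReferenceRange]:
    """Ranges consistent with the published cell means.

    The potassium and phosphate nominal ranges are the flagged 3.7-5.7 and
    2.5-4.5.  The magnesium split in the published table is internally
    inconsistent with its printed 2.5-4.5 nominal range (the "within" cell
    mean is 2.03); a 1.5-2.5 mg/dL interval brackets the printed cell
    means and is used only to *reconstruct* the published split, with no
    claim about the interval actually applied upstream.
    """
    return {
        "potassium": ReferenceRange("potassium", 3.7, 5.7),
        "magnesium": ReferenceRange("magnesium", 1.5, 2.5, high_inclusive=False),
        "phosphate": ReferenceRange("phosphate", 2.5, 4.5),
    }


def episodes_from_counts(
    counts: pd.DataFrame, ranges: dict[str, ReferenceRange]
) -> pd.DataFrame:
    """Expand a cell-count table into a synthetic episode frame.

    Each counted case becomes one episode whose index value is a
    representative point strictly inside its cell's label region, so
    classification recovers the counts exactly.  Repletion-group episodes
    get scenario ``1L_1R`` and a dummy order time; non-repletion episodes
    are ``NR``.
    """
    frames = []
    order_time = pd.Timestamp("2140-01-01 09:00")
    for _, row in counts.iterrows():
        n = int(row["n"])
        if n == 0:
            continue
        rng_ = ranges[row["electrolyte"]]
        span = rng_.high - rng_.low
        rep = {
            LABEL_BELOW: rng_.low - 0.25 * span,
            LABEL_WITHIN: rng_.low + 0.5 * span,
            LABEL_ABOVE: rng_.high + 0.25 * span,
        }[row["label"]]
        value = row["mean_value"] if not np.isnan(row["mean_value"]) else rep
        # printed cell means can sit outside their own region (rounding,
        # inconsistent source intervals); fall back to the representative
        from .classify import classify_value

        if classify_value(float(value), rng_) != row["label"]:
            value = rep
        is_rep = row["scenario_group"] == GROUP_REPLETION
        frames.append(
            pd.DataFrame(
                {
                    "electrolyte": row["electrolyte"],
                    "scenario": SCENARIO_1L1R if is_rep else SCENARIO_NR,
                    "index_value": np.full(n, float(value)),
                    "n_ignored": 0,
                    "order_time": pd.Series(
                        [order_time if is_rep else pd.NaT] * n, dtype="datetime64[ns]"
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
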