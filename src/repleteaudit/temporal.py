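"""Workflow timing: circadian histograms, latencies, threshold stability.

ICU lab draws and repletion orders cluster at specific clock hours (the
morning draw around 06:00, orders around 09:00) because they follow
hospital shift routine.  De-identified ICU timestamps preserve time of day,
so the clock hour as stored is the analysis unit.  Latencies are the
draw-to-order and order-to-follow-up intervals in minutes; their
distributions are right-skewed, so the median is reported alongside the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SCENARIO_NR


@dataclass
class HourHistogram:
    """Event counts by local clock hour 0-23."""

    counts: np.ndarray  # shape (24,)
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (24,) or self.counts.sum() != self.total:
            raise AssertionError("hour histogram does not conserve its total")

    @property
    def peak_hour(self) -> int:
        """Modal hour (smallest hour on ties)."""
        return int(np.argmax(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": np.arange(24), "count": self.counts})


def hour_histogram(events: pd.DataFrame, time_field: str) -> HourHistogram:
    """Bin events by the floor of their clock hour."""
    times = pd.to_datetime(events[time_field]).dropna()
    hours = times.dt.hour.to_numpy()
    counts = np.bincount(hours, minlength=24)
    return HourHistogram(counts=counts, total=len(hours))


def latency_summary(episodes: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/median latencies per electrolyte and kind.

    ``lab_to_order`` is measured from the index draw to the order;
    ``order_to_followup`` from the order to the follow-up draw.  Episodes
    missing either endpoint are excluded; an (electrolyte, kind) pair with
    no complete episodes is emitted with ``n == 0`` and NaN moments rather
    than silently omitted.
    """
    rows = []
    for elec in sorted(episodes["electrolyte"].unique()):
        sub = episodes.loc[episodes["electrolyte"] == elec]
        for kind, col in (
            ("lab_to_order", "lab_to_order_minutes"),
            ("order_to_followup", "order_to_followup_minutes"),
        ):
            x = sub[col].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "electrolyte": elec,
                    "kind": kind,
                    "n": len(x),
                    "mean_minutes": float(np.mean(x)) if len(x) else np.nan,
                    "sd_minutes": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                    "median_minutes": float(np.median(x)) if len(x) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def threshold_by_hour(episodes: pd.DataFrame) -> pd.DataFrame:
    """Mean pre-order value by clock hour, repletion vs non-repletion.

    24 rows per (electrolyte, group); hours with no episodes are emitted
    with ``n == 0`` and NaN mean so the 24-hour profile stays rectangular.
    A steady repletion threshold shows as a flat repletion-group profile.
    """
    ep = episodes.assign(
        _hour=pd.to_datetime(episodes["index_time"]).dt.hour,
        _group=np.where(episodes["scenario"] == SCENARIO_NR, "non_repletion", "repletion"),
    )
    rows = []
    for elec in sorted(ep["electrolyte"].unique()):
        for group in ("non_repletion", "repletion"):
            sub = ep.loc[(ep["electrolyte"] == elec) & (ep["_group"] == group)]
            for hour in range(24):
                vals = sub.loc[sub["_hour"] == hour, "index_value"].to_numpy(dtype=float)
                rows.append(
                    {
                        "electrolyte": elec,
                        "group": group,
                        "hour": hour,
                        "n": len(vals),
                        "mean_value": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd_value": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
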