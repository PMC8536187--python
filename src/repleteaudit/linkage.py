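"""Linking serum draws to repletion orders inside a 24-hour window.

This is the analytical heart of the audit.  Each repletion order is
anchored to an *index lab*: the latest same-electrolyte draw in the same
stay charted at or before the order and no more than ``window_minutes``
(default 24 h) earlier.  Other qualifying draws in that window are
*ignored* (the closest value is used).  Every draw then falls into exactly
one of three scenarios:

* ``NR``    — a draw with no repletion order in the following window;
* ``1L_1R`` — a single draw followed by one repletion;
* ``ML_1R`` — multiple draws preceding one repletion (closest used).

After anchoring, the *follow-up* lab of each repletion episode is the
earliest same-electrolyte draw strictly after the order and within the
window (a draw may serve both as follow-up of one episode and as index of a
later one).

Orders are assigned greedily in time order and one order consumes its
window's draws, so overlapping windows never double-assign a draw.
Conservation holds by construction: every input draw appears exactly once
as an index lab, an ignored lab, an ``NR`` episode, or in the (provably
empty under greedy assignment, but still reported) orphan side list.
Repletion orders with no qualifying preceding draw are emitted to an
*unanchored* side list, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import SCENARIO_1L1R, SCENARIO_ML1R, SCENARIO_NR

EPISODE_COLUMNS = [
    "episode_id",
    "stay_id",
    "subject_id",
    "electrolyte",
    "scenario",
    "index_time",
    "index_value",
    "n_ignored",
    "order_time",
    "dose",
    "lab_to_order_minutes",
    "followup_time",
    "followup_value",
    "order_to_followup_minutes",
]


@dataclass(frozen=True)
class LinkageConfig:
    """Tunable linkage behaviour.

    ``window_minutes`` is the look-back (and follow-up look-ahead) horizon.
    ``pre_boundary_inclusive`` keeps a draw charted at exactly the order
    time as a qualifying *preceding* draw (charting granularity makes exact
    ties common); the follow-up search is always strictly-after so the same
    draw is never double-counted.  ``same_electrolyte_only`` restricts
    anchoring to draws of the ordered electrolyte (combination products are
    handled upstream by expanding them to one order per electrolyte).
    """

    window_minutes: float = 1440.0
    pre_boundary_inclusive: bool = True
    same_electrolyte_only: bool = True

    def __post_init__(self) -> None:
        if not self.window_minutes > 0:
            raise ConfigError("window_minutes must be positive")


@dataclass
class LinkageResult:
    episodes: pd.DataFrame
    ignored_labs: pd.DataFrame = field(default_factory=pd.DataFrame)
    unanchored_repletions: pd.DataFrame = field(default_factory=pd.DataFrame)
    orphan_labs: pd.DataFrame = field(default_factory=pd.DataFrame)


def _minutes(times: pd.Series) -> np.ndarray:
    return times.to_numpy().astype("datetime64[m]").astype(np.int64)


def classify_scenario(episode) -> str:
    """Scenario label of one episode record (total function).

    ``NR`` when no repletion is attached; ``1L_1R`` when a repletion is
    attached with zero ignored draws; ``ML_1R`` otherwise.
    """
    has_repletion = pd.notna(episode["order_time"])
    if not has_repletion:
        return SCENARIO_NR
    return SCENARIO_ML1R if episode["n_ignored"] > 0 else SCENARIO_1L1R


def link_episodes(
    labs: pd.DataFrame,
    repletions: pd.DataFrame,
    config: LinkageConfig | None = None,
) -> LinkageResult:
    """Run the full matcher: anchoring, scenario labels and follow-ups.

    Input frames use the canonical schema.  Output row order is
    deterministic and independent of input row order (internal sort by
    stay, electrolyte, charttime; simultaneous draws tie-break to the later
    input sequence number).
    """
    config = config or LinkageConfig()
    w = float(config.window_minutes)

    lab_t = _minutes(labs["charttime"])
    rep_t = _minutes(repletions["ordertime"])

    group_cols = ["stay_id", "electrolyte"] if config.same_electrolyte_only else ["stay_id"]

    # sort labs/repletions by (group, time, input sequence)
    lab_sort = labs.assign(_t=lab_t, _seq=np.arange(len(labs))).sort_values(
        group_cols + ["_t", "_seq"], kind="mergesort"
    )
    rep_sort = repletions.assign(_t=rep_t, _seq=np.arange(len(repletions))).sort_values(
        group_cols + ["_t", "_seq"], kind="mergesort"
    )

    episodes: list[tuple] = []
    ignored_rows: list[tuple] = []
    unanchored_idx: list[int] = []
    orphan_idx: list[int] = []

    rep_groups = {key: grp for key, grp in rep_sort.groupby(group_cols, sort=False)}

    for key, lgrp in lab_sort.groupby(group_cols, sort=False):
        lt = lgrp["_t"].to_numpy()
        lv = lgrp["value"].to_numpy(dtype=float)
        lidx = lgrp.index.to_numpy()
        stay_id = lgrp["stay_id"].iloc[0]
        subject_id = lgrp["subject_id"].iloc[0] if "subject_id" in lgrp.columns else None
        rgrp = rep_groups.pop(key, None)

        role = np.zeros(len(lt), dtype=np.int8)  # 0 unassigned, 1 index, 2 ignored
        ep_of_lab = np.full(len(lt), -1, dtype=np.int64)

        rep_records: list[dict] = []
        if rgrp is not None:
            rt = rgrp["_t"].to_numpy()
            lo = 0
            for j in range(len(rt)):
                ot = rt[j]
                start = int(np.searchsorted(lt, ot - w, side="left"))
                side = "right" if config.pre_boundary_inclusive else "left"
                hi = int(np.searchsorted(lt, ot, side=side))
                start = max(start, lo)
                if hi <= start:
                    unanchored_idx.append(rgrp.index[j])
                    continue
                # index lab: last position = max charttime, then max input seq
                role[start:hi] = 2
                role[hi - 1] = 1
                rep_records.append(
                    {
                        "elec": rgrp["electrolyte"].iloc[j]
                        if "electrolyte" in rgrp.columns
                        else lgrp["electrolyte"].iloc[0],
                        "idx_pos": hi - 1,
                        "ignored_pos": list(range(start, hi - 1)),
                        "order_t": ot,
                        "dose": rgrp["dose"].iloc[j] if "dose" in rgrp.columns else np.nan,
                    }
                )
                lo = hi

        elec_of = lgrp["electrolyte"].to_numpy() if "electrolyte" in lgrp.columns else None

        # repletion episodes
        for rec in rep_records:
            p = rec["idx_pos"]
            scenario = SCENARIO_ML1R if rec["ignored_pos"] else SCENARIO_1L1R
            # follow-up: earliest draw strictly after the order, within window
            fu_lo = int(np.searchsorted(lt, rec["order_t"], side="right"))
            fu_time = np.nan
            fu_value = np.nan
            fu_delta = np.nan
            if fu_lo < len(lt) and lt[fu_lo] - rec["order_t"] <= w:
                fu_time = lt[fu_lo]
                fu_value = lv[fu_lo]
                fu_delta = float(lt[fu_lo] - rec["order_t"])
            eid = len(episodes)
            ep_of_lab[p] = eid
            for q in rec["ignored_pos"]:
                ep_of_lab[q] = eid
                ignored_rows.append((eid, stay_id, rec["elec"], lt[q], lv[q]))
            episodes.append(
                (
                    eid,
                    stay_id,
                    subject_id,
                    rec["elec"],
                    scenario,
                    lt[p],
                    lv[p],
                    len(rec["ignored_pos"]),
                    rec["order_t"],
                    rec["dose"],
                    float(rec["order_t"] - lt[p]),
                    fu_time,
                    fu_value,
                    fu_delta,
                )
            )

        # leftover draws: NR episodes, unless a repletion sits in the
        # following window (orphan; cannot occur under greedy assignment)
        rt_all = rgrp["_t"].to_numpy() if rgrp is not None else np.empty(0)
        for p in np.nonzero(role == 0)[0]:
            ct = lt[p]
            k = int(np.searchsorted(rt_all, ct, side="left"))
            if k < len(rt_all) and rt_all[k] - ct <= w:
                orphan_idx.append(lidx[p])
                continue
            eid = len(episodes)
            episodes.append(
                (
                    eid,
                    stay_id,
                    subject_id,
                    elec_of[p] if elec_of is not None else None,
                    SCENARIO_NR,
                    ct,
                    lv[p],
                    0,
                    np.nan,
                    np.nan,
                    np.nan,
                    np.nan,
                    np.nan,
                    np.nan,
                )
            )

    # repletions in groups with no labs at all are unanchored
    for rgrp in rep_groups.values():
        unanchored_idx.extend(rgrp.index.tolist())

    ep = pd.DataFrame(episodes, columns=EPISODE_COLUMNS)
    for col in ("index_time", "order_time", "followup_time"):
        ep[col] = pd.to_datetime(ep[col], unit="m")
    ign = pd.DataFrame(
        ignored_rows, columns=["episode_id", "stay_id", "electrolyte", "charttime", "value"]
    )
    if len(ign):
        ign["charttime"] = pd.to_datetime(ign["charttime"], unit="m")
    unanchored = repletions.loc[sorted(unanchored_idx)].reset_index(drop=True)
    orphans = labs.loc[sorted(orphan_idx)].reset_index(drop=True)
    return LinkageResult(ep, ign, unanchored, orphans)


def scenario_frequencies(episodes: pd.DataFrame) -> pd.DataFrame:
    """Scenario counts and percentages per electrolyte.

    ``pct_of_repletions`` is the share among repletion episodes only, so
    the two repletion scenarios sum to 100; it is NaN (undefined, not zero)
    for electrolytes with no repletion episodes.
    """
    rows = []
    for elec, grp in episodes.groupby("electrolyte", sort=True):
        counts = grp["scenario"].value_counts()
        n_rep = int(counts.get(SCENARIO_1L1R, 0) + counts.get(SCENARIO_ML1R, 0))
        for scen in (SCENARIO_NR, SCENARIO_1L1R, SCENARIO_ML1R):
            n = int(counts.get(scen, 0))
            rows.append(
                {
                    "electrolyte": elec,
                    "scenario": scen,
                    "n": n,
                    "pct_of_all": 100.0 * n / len(grp) if len(grp) else np.nan,
                    "pct_of_repletions": (
                        100.0 * n / n_rep if (n_rep and scen != SCENARIO_NR) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["electrolyte", "scenario", "n", "pct_of_all", "pct_of_repletions"])
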