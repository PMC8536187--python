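"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive the contracts with naive O(n^2) scans and
plain linear algebra, sharing no code with the package implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EPOCH = pd.Timestamp("2140-01-01")


def minutes(ts) -> float:
    return (pd.Timestamp(ts) - EPOCH).total_seconds() / 60.0


def brute_force_link(
    labs: pd.DataFrame,
    repletions: pd.DataFrame,
    window: float = 1440.0,
    pre_inclusive: bool = True,
):
    """Exhaustive matcher enumerating all (lab, repletion) pairs.

    Returns (episodes, unanchored, orphans) where episodes is a sorted list
    of tuples ``(stay, elec, scenario, index_t, order_t, ignored_ts,
    followup_t)`` with times in minutes and ``ignored_ts`` a sorted tuple.
    """
    lab_rows = [
        {
            "stay": r["stay_id"],
            "elec": r["electrolyte"],
            "t": minutes(r["charttime"]),
            "value": r["value"],
            "seq": i,
            "consumed": False,
        }
        for i, r in labs.reset_index(drop=True).iterrows()
    ]
    rep_rows = [
        {
            "stay": r["stay_id"],
            "elec": r["electrolyte"],
            "t": minutes(r["ordertime"]),
            "seq": i,
        }
        for i, r in repletions.reset_index(drop=True).iterrows()
    ]
    episodes = []
    unanchored = []
    for rep in sorted(rep_rows, key=lambda r: (r["t"], r["seq"])):
        cands = [
            lab
            for lab in lab_rows
            if lab["stay"] == rep["stay"]
            and lab["elec"] == rep["elec"]
            and not lab["consumed"]
            and (lab["t"] <= rep["t"] if pre_inclusive else lab["t"] < rep["t"])
            and rep["t"] - lab["t"] <= window
        ]
        if not cands:
            unanchored.append((rep["stay"], rep["elec"], rep["t"]))
            continue
        index = max(cands, key=lambda lab: (lab["t"], lab["seq"]))
        ignored = [lab for lab in cands if lab is not index]
        for lab in cands:
            lab["consumed"] = True
        followers = [
            lab
            for lab in lab_rows
            if lab["stay"] == rep["stay"]
            and lab["elec"] == rep["elec"]
            and lab["t"] > rep["t"]
            and lab["t"] - rep["t"] <= window
        ]
        fu = min(followers, key=lambda lab: (lab["t"], lab["seq"]))["t"] if followers else None
        scenario = "ML_1R" if ignored else "1L_1R"
        episodes.append(
            (
                rep["stay"],
                rep["elec"],
                scenario,
                index["t"],
                rep["t"],
                tuple(sorted(lab["t"] for lab in ignored)),
                fu,
            )
        )
    orphans = []
    for lab in lab_rows:
        if lab["consumed"]:
            continue
        following = [
            rep
            for rep in rep_rows
            if rep["stay"] == lab["stay"]
            and rep["elec"] == lab["elec"]
            and lab["t"] <= rep["t"] <= lab["t"] + window
        ]
        if following:
            orphans.append((lab["stay"], lab["elec"], lab["t"]))
        else:
            episodes.append(
                (lab["stay"], lab["elec"], "NR", lab["t"], None, (), None)
            )
    return sorted(episodes, key=_ep_key), sorted(unanchored), sorted(orphans)


def _ep_key(e):
    return (str(e[0]), str(e[1]), e[3], e[2], -1 if e[4] is None else e[4])


def episodes_to_tuples(episodes: pd.DataFrame):
    """Convert the package's episode frame to the oracle's tuple form."""
    out = []
    for _, r in episodes.iterrows():
        order_t = None if pd.isna(r["order_time"]) else minutes(r["order_time"])
        fu_t = None if pd.isna(r["followup_time"]) else minutes(r["followup_time"])
        out.append(
            (r["stay_id"], r["electrolyte"], r["scenario"], minutes(r["index_time"]),
             order_t, int(r["n_ignored"]), fu_t)
        )
    return sorted(out, key=_ep_key)


def tuples_count_ignored(episodes):
    """Replace each oracle episode's ignored-time tuple by its count."""
    return sorted(
        [(e[0], e[1], e[2], e[3], e[4], len(e[5]), e[6]) for e in episodes], key=_ep_key
    )


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """OLS via the normal equations, with SEs from the residual variance."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    df = len(y) - Xd.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    return beta, np.sqrt(np.diag(cov)), resid


def pooled_t_closed_form(a, b):
    """Textbook pooled two-sample t computed step by step."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
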