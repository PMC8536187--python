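"""The three linkage scenarios on a hand-built six-event stay.

A potassium stream: a draw with no order within 24 h (NR), a lone draw
followed by an order (1L -> 1R), and two draws inside one window where the
closest is used and the other ignored (ML -> 1R); plus a follow-up draw
after each order.
"""

import pandas as pd

from repleteaudit.linkage import link_episodes

T0 = pd.Timestamp("2140-03-01 06:00")


def lab(hours, value):
    return dict(subject_id="p1", stay_id="s1", electrolyte="potassium",
                charttime=T0 + pd.Timedelta(hours=hours), value=value)


def order(hours):
    return dict(subject_id="p1", stay_id="s1", electrolyte="potassium",
                ordertime=T0 + pd.Timedelta(hours=hours), dose=40.0)


labs = pd.DataFrame([
    lab(0, 4.1),     # day 1, 06:00 - no order follows within 24 h -> NR
    lab(72, 3.2),    # day 4, 06:00 - lone draw, order 3 h later -> 1L_1R
    lab(78, 3.9),    # follow-up of that order
    lab(168, 3.4),   # day 8, 06:00 - earlier draw, ignored
    lab(172, 3.1),   # day 8, 10:00 - closest draw -> index of ML_1R
    lab(180, 3.8),   # follow-up
])
orders = pd.DataFrame([order(75), order(174)])

res = link_episodes(labs, orders)
cols = ["scenario", "index_time", "index_value", "n_ignored",
        "order_time", "lab_to_order_minutes", "followup_value"]
print(res.episodes[cols].to_string(index=False))
print(f"\nignored draws: {res.ignored_labs['value'].tolist()}")
# Each draw is used exactly once: the 06:00 day-8 draw is 'ignored' because
# the 10:00 draw is closer to the order; follow-up values (3.9, 3.8) are
# the 'post' levels used for effectiveness statistics.  Note the follow-up
# draws themselves become NR episodes - a follow-up is just another lab
# order that happened not to trigger a repletion.
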