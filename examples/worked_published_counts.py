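"""Re-derive a published repletion audit's percentages from its printed counts.

The printed interpretation counts (how many pre-order values fell
below/within/above the nominal range, split by repletion vs not) fully
determine every percentage in the summary table.  This script expands the
counts into synthetic episodes and runs them through the same aggregation
functions used on linked data.
"""

from repleteaudit.classify import (
    interpretation_table,
    near_miss_frequencies,
    repletion_fraction,
    round_half_up,
)
from repleteaudit.datasets import (
    episodes_from_counts,
    published_interpretation_counts,
    published_reference_ranges,
)

counts = published_interpretation_counts()
ranges = published_reference_ranges()
episodes = episodes_from_counts(counts, ranges)

print("Share of lab-order episodes followed by repletion:")
for _, row in repletion_fraction(episodes).iterrows():
    print(
        f"  {row['electrolyte']:<10s} {round_half_up(row['percent']):>6.2f} %"
        f"   ({row['n_repletion']} of {row['n_episodes']} episodes)"
    )
# Only a few percent of draws trigger any intervention: most lab orders
# are pure monitoring.

print("\nPre-order interpretation, repletion episodes only:")
table = interpretation_table(episodes, ranges)
rep = table[table["scenario_group"] == "repletion"]
for _, row in rep.iterrows():
    print(
        f"  {row['electrolyte']:<10s} {row['label']:<7s} n={row['n']:>5d}"
        f"  {round_half_up(row['percent']):>6.2f} %"
    )
# Potassium and magnesium are overwhelmingly replaced while already within
# range; phosphate repletion is almost always a response to hypophosphatemia.

print("\nNear misses (repletion despite an above-range value):")
for _, row in near_miss_frequencies(episodes, ranges).iterrows():
    print(f"  {row['electrolyte']:<10s} {round_half_up(row['percent']):>5.2f} %")
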