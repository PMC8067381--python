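"""Generate a synthetic 190-cow breeding season and look at its shape.

The generator emulates a three-farm autumn-calving cohort in which cows
not seen in estrus before the mating start date (day 0) receive either a
single prostaglandin injection (PGOD, even freeze brands) or a modified
Ovsynch protocol with fixed-time AI at day 10.25 (MOFT, odd brands).
"""
from collections import Counter

from herdbudget import HerdConfig, generate_herd

records = generate_herd(HerdConfig(seed=1, group_sizes_override=(90, 100)))

print(f"cows generated: {len(records)}")
print("per farm:", dict(sorted(Counter(r.farm for r in records).items())))
print("per arm:", dict(Counter(r.treatment for r in records)))

example = next(r for r in records if len(r.service_days) > 1)
print(f"\nexample cow {example.cow_id} ({example.treatment}): "
      f"services on days {example.service_days}, "
      f"conceived day {example.conception_day}")

# Farm sizes are exact; the arm split honours the trial's 90/100 override.
# Service days are offsets from the herd mating start date; a cow without a
# conception day is right-censored at day 84 (end of the breeding season).
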