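"""The four-scenario partial budget, per cow treated.

Scenarios cross dry-off policy (fixed calendar date vs per-cow variable
date) with whether the modified Ovsynch protocol reduces the barren rate.
Under a fixed dry-off date an earlier conception lengthens the next
lactation, so milk income enters; under a variable date it does not.
"""
from dataclasses import asdict

from herdbudget import SCENARIO_LETTERS, net_benefit
from herdbudget.io import bundled_config_path, load_economic_config

econ = load_economic_config(bundled_config_path())

for letter, scenario in SCENARIO_LETTERS.items():
    r = net_benefit(econ.expected, scenario)
    print(f"scenario {letter} ({scenario.dry_off} dry-off, "
          f"{'with' if scenario.barren_improvement else 'no'} barren improvement): "
          f"net benefit GBP {r.net_benefit:+.2f}/cow")
    for component, value in asdict(r).items():
        if component != "net_benefit":
            print(f"    {component:20s} {value:+8.2f}")

# With the expected inputs the fixed-dry-off, improved-barren-rate herd
# nets ~GBP 53.42/cow and the variable-dry-off herd ~GBP 26.54/cow; the
# difference is exactly the gross milk revenue 4 d x 24 L x GBP 0.28.
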