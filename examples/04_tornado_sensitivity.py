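"""One-way (tornado) sensitivity analysis of the net benefit.

Each input moves from its low to its high value with the others held at
expected; the swing is the induced net-benefit range and the contribution
is the squared-swing share of total variation.
"""
from herdbudget import ScenarioConfig, one_way_sweep
from herdbudget.io import bundled_config_path, load_economic_config

econ = load_economic_config(bundled_config_path())

for letter, label in [("a", "fixed dry-off, barren improvement"),
                      ("d", "variable dry-off, no improvement")]:
    scenario = ScenarioConfig("fixed" if letter in "ab" else "variable",
                              letter in "ac")
    entries = one_way_sweep(econ.ranges_for_scenario(letter),
                            econ.expected, scenario)
    print(f"scenario {letter} ({label}):")
    for e in entries:
        print(f"  {e.name:26s} swing GBP {e.swing:6.2f}  "
              f"({e.contribution_pct:5.1f}% of variation)  "
              f"NB {e.nb_low:+.2f} .. {e.nb_high:+.2f}")
    print()

# In scenario a the barren-rate reduction and the replacement-heifer cost
# dominate; in scenario d the beef-calf proportion and the protocol cost
# drive what little is left to vary.
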