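"""Stock-and-flow supply projection for one profession.

Loads the packaged seven-profession configuration and prints the projected
psychologist stock, flows and effective supply.  Effective supply is far
below the licensed stock because only 9.3% of psychologists' clinical time
goes to the planned population and conditions (clinical focus).
"""

import hrhsim as hs

config, _ = hs.packaged_fixture()
trajectory, effective = hs.supply_timeseries(config)

profession = "psychologist"
print(f"{'year':>6} {'stock':>8} {'grads':>7} {'entrants':>9} {'exits':>7} {'FTE supply':>11}")
for year in config.registry.years[:6]:
    print(f"{year:>6} {trajectory.stock_total(profession, year):>8.1f} "
          f"{trajectory.graduates[(profession, year)]:>7.1f} "
          f"{trajectory.entrants[(profession, year)]:>9.1f} "
          f"{trajectory.exits[(profession, year)]:>7.1f} "
          f"{effective[(profession, year)]:>11.2f}")
# Each year the licensed stock loses exits (age-specific rates) and gains
# new graduates (seats, lagged by program length, net of attrition and
# graduate out-migration) plus in-migrants; stock x participation x activity
# x clinical focus is what is actually available to this population.
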