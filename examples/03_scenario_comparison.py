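"""Run the five packaged policy scenarios and compare gaps.

Scenarios are ordered lists of absolute parameter overrides effective from a
given year: two division-of-work shifts (who does which service), two
clinical-focus changes (how much provider time the conditions get), plus the
status quo.  Positive gaps are shortages, negative are surpluses.
"""

import hrhsim as hs

config, scenarios = hs.packaged_fixture()
runs = hs.run(config, scenarios)
comparison = hs.summarize({name: r.gaps for name, r in runs.items()})
print(comparison.display().to_string(index=False))
# Note the social-worker shortage rising from 89 to 107 FTE in the
# focus_reduce_sw scenario, and the registered-nurse gap changing sign
# (shortage -> surplus) when clinical focus increases for all professions
# but social workers.
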