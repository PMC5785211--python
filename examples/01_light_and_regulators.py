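"""Build the four diel light regimes and the regulator responses to them.

Prints the defining values of each light profile and the RpaB~P fold
changes after light steps (RpaA~P, the clock output, ignores them).
"""

import numpy as np

from clocklight import CONDITIONS, make_light_profile, make_regulator_trajectories

profiles = {c: make_light_profile(c) for c in CONDITIONS}

print("Light profiles (umol photons m-2 s-1):")
for name, lp in profiles.items():
    print(f"  {name:15s} min={lp.intensity.min():6.1f}  max={lp.intensity.max():6.1f}  at t=8.5h: {lp.at(8.5):6.1f}")

print("\nRegulator responses:")
for name, lp in profiles.items():
    rpaa, rpab = make_regulator_trajectories(lp)
    print(
        f"  {name:15s} RpaA~P dawn->dusk x{rpaa.values[-1] / rpaa.values[0]:.1f}   "
        f"RpaB~P 8h->8.25h x{rpab.at(8.25) / rpab.at(8.0):.3f}   10h->12h x{rpab.at(12.0) / rpab.at(10.0):.2f}"
    )

# The x0.323 (= 1/3.1) drop under the High Light pulse and x1.9 rise
# under Shade mirror the rapid, light-inverse phosphorylation of RpaB;
# the identical RpaA~P ramp in every condition is the clock's
# light-insensitive output.
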