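"""Whole-body simulation of a single oral overdose.

Runs the coupled PBPK + lobule model for a 393 mg/kg oral dose in a 73 kg
adult, prints the plasma peak, end-of-run lobule viability and where the
necrotic cells sit along the sinusoids (pericentral-first injury).
"""

import numpy as np

from hepatosim import experiments as ex
from hepatosim.whole_body import DoseRegimen, simulate

cal = ex.calibrate_injury(target_lc50=4000.0)

res = simulate(
    DoseRegimen.single_oral(393.0, body_weight=73.0),
    profile=cal.profile, injury=cal.injury,
    duration=2000.0, seed=1,
)

print(f"plasma Cmax: {res.cmax:.0f} mg/L at "
      f"t = {res.times[np.argmax(res.plasma)]:.0f} min")
print(f"lobule viability at 2000 min: {res.final_viability:.3f} "
      f"({len(res.events)} necrosis events)")
print(f"whole-body mass-balance error: {res.mass_balance_error:.2e} of dose")

if len(res.events):
    first = res.events.sort_values("time_exec").head(len(res.events) // 4 + 1)
    print(f"mean position of the earliest quarter of deaths: "
          f"x/L = {first['x_frac'].mean():.2f} (1 = central vein) — "
          "injury begins pericentrally")

nap = res.concentration_map("NAPQI")
by_zone = nap.groupby(nap["x_frac"] > 2 / 3)["cell_uM"].mean()
print(f"mean cellular NAPQI, zones 1-2: {by_zone.get(False, 0.0):.2f} uM; "
      f"zone 3: {by_zone.get(True, 0.0):.2f} uM")
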