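"""Ecoclimatic suitability from weekly climate series.

Scores three synthetic climate profiles with the simplified
ecoclimatic index under the fall armyworm parameter set, then maps EI
over a small synthetic grid and prints the favorability masks (EI >=
30 favorable for establishment; EI >= 33 is the usual map shading).
"""

import numpy as np

from fawkit import ecoclim, synthdata
from fawkit.ecoclim import ClimexParams, ecoclimatic_index

params = ClimexParams()
for profile, kwargs in [
    ("incubator", {}),
    ("seasonal", {"mean_T": 24.0, "amp_T": 8.0}),
    ("frozen", {}),
]:
    clim = synthdata.simulate_climate(profile, **kwargs)
    r = ecoclimatic_index(clim, params)
    print(f"{profile:10s} GI={r.GI:6.2f}  stresses(C,H,D,W)="
          f"({r.CS:.2f},{r.HS:.2f},{r.DS:.2f},{r.WS:.2f})  "
          f"degree-days={r.degree_days:7.1f}  EI(simplified)={r.EI:6.2f}  "
          f"favorable={r.favorable_30}")

print()
T, SM = synthdata.simulate_climate_grid(3, 4, seed=2)
out = ecoclim.map_ei(T, SM, params)
with np.printoptions(precision=1, suppress=True):
    print("EI grid (NaN = missing cell):")
    print(out["EI"])
    print("favorable mask (EI >= 30):")
    print(out["mask_30"])
print()
print("EI is 0-100; 100 is year-round incubator conditions; cells below "
      "600 degree-days cannot complete a generation and score 0")
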