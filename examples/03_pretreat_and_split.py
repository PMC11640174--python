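"""Spectral pretreatment and SPXY calibration/prediction splitting.

Pretreatment parameters (MSC reference, centering means) are learned on
calibration rows only and replayed on prediction rows. The SPXY split
covers the joint spectral/chemical space deterministically at a 3:1 ratio.
"""

import numpy as np

from teaspec import SimulationParams, make_design, simulate_sample_spectra, trim_bands
from teaspec.preprocessing import Pretreatment
from teaspec.sampling import spxy_split

ds = simulate_sample_spectra(make_design(), params=SimulationParams(seed=0))
cal = ds.calibration_set
X, wl = trim_bands((cal.X, cal.wavelengths_nm))

split = spxy_split(X, cal.y, train_fraction=0.75)
print(f"SPXY split: {len(split.train_indices)} calibration / "
      f"{len(split.test_indices)} prediction samples")
tr_y, te_y = cal.y[split.train_indices], cal.y[split.test_indices]
print(f"calibration TFAA range [{tr_y.min():.2f}, {tr_y.max():.2f}] contains "
      f"prediction range [{te_y.min():.2f}, {te_y.max():.2f}]")

for name in ("MSC", "CT", "D1", "SG"):
    chain = Pretreatment([name], spacing_nm=float(wl[1] - wl[0]))
    Xt = chain.fit_apply(X[split.train_indices])
    Xp = chain.apply(X[split.test_indices])
    print(f"  {name}: calibration {Xt.shape}, prediction {Xp.shape}, "
          f"row-1 range [{Xp[0].min():+.3f}, {Xp[0].max():+.3f}]")

# mean centering really uses the calibration means on prediction rows
chain = Pretreatment(["CT"]).fit(X[split.train_indices])
assert np.allclose(chain.apply(X[split.train_indices]).mean(axis=0), 0, atol=1e-12)
print("CT leakage guard: calibration columns centered, prediction rows "
      "shifted by the calibration means")
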