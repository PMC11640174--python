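"""Generate the study-shaped synthetic dataset and inspect its structure.

The design mirrors a three-step tea processing line (fresh-leaf spreading,
steaming fixation, hot-air drying): 3 steps x 30 batches x 3 replicates =
270 samples, each a 951-channel reflectance spectrum over 400-1000 nm with
a reference TFAA value near 4 % dry mass.
"""

import numpy as np

from teaspec import SimulationParams, make_design, simulate_sample_spectra

design = make_design()
ds = simulate_sample_spectra(design, params=SimulationParams(seed=0))
cal = ds.calibration_set

print(f"samples: {cal.n_samples} (3 steps x 30 batches x 3 replicates)")
print(f"channels: {cal.n_bands}, grid {cal.wavelengths_nm[0]:.0f}-"
      f"{cal.wavelengths_nm[-1]:.0f} nm, spacing {np.diff(cal.wavelengths_nm)[0]:.4f} nm")
for step in ("FLS", "SF", "HD"):
    y = cal.for_step(step).y
    print(f"  {step}: TFAA {y.mean():.2f} +/- {y.std(ddof=1):.2f} % dry mass "
          f"(n={len(y)})")
planted_wl = cal.wavelengths_nm[ds.planted_band_indices]
print(f"planted analyte bands: {len(ds.planted_band_indices)} channels, "
      f"{planted_wl.min():.0f}-{planted_wl.max():.0f} nm "
      "(ground truth for wavelength selectors)")
# The mean spectrum shows the two reflectance peaks typical of leaf
# material: green (500-600 nm) and the NIR plateau (750-950 nm).
mean = cal.X.mean(axis=0)
for lo, hi in [(500, 600), (750, 950)]:
    win = (cal.wavelengths_nm >= lo) & (cal.wavelengths_nm <= hi)
    i = np.argmax(mean[win])
    print(f"reflectance peak in {lo}-{hi} nm window: "
          f"{mean[win][i]:.3f} at {cal.wavelengths_nm[win][i]:.0f} nm")
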