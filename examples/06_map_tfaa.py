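"""Pixel-wise TFAA concentration mapping.

A fitted chain (pretreatment + selected bands + model) is applied to every
foreground pixel of a reflectance cube, and the result is rendered as a
pseudo-color PNG with a % dry mass color bar — the per-pixel analogue of
the tabular prediction.
"""

import warnings
from pathlib import Path

import numpy as np

from teaspec import SimulationParams, make_design, simulate_sample_spectra, trim_bands
from teaspec.dataset import CalibrationSet
from teaspec.mapping import mask_background, predict_map, render_pseudocolor
from teaspec.pipeline import run_combination
from teaspec.sampling import stratified_spxy_split
from teaspec.synthetic import simulate_cube

warnings.simplefilter("ignore")

ds = simulate_sample_spectra(make_design(), params=SimulationParams(seed=1))
cal = ds.calibration_set
X, wl = trim_bands((cal.X, cal.wavelengths_nm))
cal = CalibrationSet(X, wl, cal.y, cal.steps, cal.sample_ids)
split = stratified_spxy_split(cal.X, cal.y, cal.steps, 0.75)
train, test = cal.subset(split.train_indices), cal.subset(split.test_indices)

row, _, fitted = run_combination(
    train, test, "CT", {"name": "cars", "N": 65, "folds": 5},
    {"name": "plsr", "max_nlvs": 15, "cv_folds": 10}, seed=1,
)
print(f"model: {row.model_label} (Rp2={row.rp2:.3f}, RPD={row.rpd:.2f})")

# image a held-out sample and map it
i = int(np.argsort(test.y)[len(test.y) // 2])
sim = simulate_cube(test.X[i], test.wavelengths_nm, 48, 48, seed=9)
pmap = predict_map(sim.reflectance, fitted["pretreatment"], fitted["bands"],
                   fitted["model"], mask=mask_background(sim.reflectance),
                   model_label=row.model_label)
fg = pmap.foreground_values
print(f"sample {test.sample_ids[i]}: reference TFAA {test.y[i]:.3f} % dm")
print(f"map: {fg.size} foreground pixels, mean prediction {fg.mean():.3f} "
      f"+/- {fg.std(ddof=1):.3f} % dm")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
png = out / "tfaa_map.png"
render_pseudocolor(pmap, png)
print(f"pseudo-color map written to {png}")
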