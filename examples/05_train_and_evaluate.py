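"""The headline calibration: CT pretreatment + CARS selection + PLSR,
compared with LS-SVR, on the comprehensive-process (CP) model.

Reproduces the workflow on the default synthetic study: stratified SPXY
split, selection on the pretreated calibration rows, CV-tuned models, and
an evaluation row with the RPD credibility class.
"""

import warnings

from teaspec import SimulationParams, make_design, simulate_sample_spectra, trim_bands
from teaspec.dataset import CalibrationSet
from teaspec.pipeline import run_combination
from teaspec.sampling import stratified_spxy_split

warnings.simplefilter("ignore")

ds = simulate_sample_spectra(make_design(), params=SimulationParams(seed=1))
cal = ds.calibration_set
X, wl = trim_bands((cal.X, cal.wavelengths_nm))
cal = CalibrationSet(X, wl, cal.y, cal.steps, cal.sample_ids)

split = stratified_spxy_split(cal.X, cal.y, cal.steps, 0.75)
train, test = cal.subset(split.train_indices), cal.subset(split.test_indices)
print(f"CP model: {train.n_samples} calibration / {test.n_samples} prediction "
      f"samples, {cal.n_bands} bands")

cars = {"name": "cars", "N": 65, "folds": 5}
plsr = {"name": "plsr", "max_nlvs": 15, "cv_folds": 10}
lssvr = {"name": "lssvr", "gamma_grid": [2**e for e in range(-15, 4, 2)],
         "C_grid": [2**e for e in range(-5, 16, 2)], "cv_folds": 10}

for reg in (plsr, lssvr):
    row, selection, fitted = run_combination(train, test, "CT", cars, reg, seed=1)
    print(f"{row.model_label}: Rc2={row.rc2:.4f} RMSEC={row.rmsec:.4f} "
          f"Rp2={row.rp2:.4f} RMSEP={row.rmsep:.4f} RPD={row.rpd:.4f} "
          f"({row.rpd_class}, {row.n_bands} bands)")
    if reg is plsr:
        print(f"  PLSR latent variables: {fitted['model'].n_components}")
    else:
        print(f"  LS-SVR hyperparameters: gamma={fitted['hyper']['gamma']:g}, "
              f"C={fitted['hyper']['C']:g}")
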