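"""Seedable synthetic VNIR data emulating a tea-processing calibration study.

The study shape is 3 processing steps (fresh-leaf spreading FLS, steaming
fixation SF, hot-air drying HD) x 30 batches x 3 replicates = 270 samples,
each a 951-channel reflectance spectrum over 400-1000 nm, with total free
amino acid (TFAA) reference values concentrated near 4 % dry mass.

Spectra are built from a small component library (analyte, chlorophyll-like
pigment, water/background) via Beer-Lambert-style attenuation

    r(lambda) = albedo * exp(-sum_k c_k * profile_k(lambda))

with the analyte coefficient proportional to the sample's TFAA, then
corrupted by polynomial baseline drift, multiplicative/additive scatter
jitter, and iid noise, and clipped to (0, 1]. The analyte absorbs near
947 nm (O-H first overtone) and near 1000 nm (N-H stretch); the pigment
absorbs red (620-780 nm) and blue light and weakly in the green
(490-560 nm), which produces the characteristic dual reflectance peaks in
the 500-600 nm and 750-950 nm windows.

Channels where the analyte profile exceeds half its maximum are recorded as
``planted_band_indices`` — ground truth for validating wavelength
selectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CalibrationSet
from .hsi_io import SpectralCube, write_envi_cube

__all__ = [
    "StudyDesign",
    "ComponentLibrary",
    "SimulationParams",
    "SyntheticDataset",
    "SimulatedCube",
    "make_design",
    "default_library",
    "simulate_sample_spectra",
    "simulate_cube",
    "make_planted_benchmark",
    "write_dataset",
]

PROCESS_STEPS = ("FLS", "SF", "HD")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling roster and wavelength grid of the emulated study."""

    process_steps: tuple = PROCESS_STEPS
    batches_per_step: int = 30
    replicates: int = 3
    wavelength_start_nm: float = 400.0
    wavelength_end_nm: float = 1000.0
    n_channels: int = 951

    def __post_init__(self):
        if self.batches_per_step < 1 or self.replicates < 1 or len(self.process_steps) < 1:
            raise ValueError("counts must be >= 1")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength end must exceed start")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")

    @property
    def n_samples(self) -> int:
        return len(self.process_steps) * self.batches_per_step * self.replicates

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Uniform grid, endpoints inclusive."""
        return np.linspace(self.wavelength_start_nm, self.wavelength_end_nm, self.n_channels)

    def roster(self) -> pd.DataFrame:
        """One row per sample: unique id carrying (step, batch, replicate)."""
        rows = [
            {"sample_id": f"{s}-b{b:02d}-r{r}", "step": s, "batch": b, "replicate": r}
            for s in self.process_steps
            for b in range(1, self.batches_per_step + 1)
            for r in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows)


def make_design(
    steps=PROCESS_STEPS,
    batches: int = 30,
    replicates: int = 3,
    wavelength_start_nm: float = 400.0,
    wavelength_end_nm: float = 1000.0,
    n_channels: int = 951,
) -> StudyDesign:
    return StudyDesign(
        tuple(steps), batches, replicates,
        wavelength_start_nm, wavelength_end_nm, n_channels,
    )


@dataclass
class ComponentLibrary:
    """Unit-normalized Gaussian-band absorption profiles on a fixed grid."""

    wavelengths_nm: np.ndarray
    profiles: dict  # name -> (p,) array, non-negative, max 1

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        for name, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=np.float64)
            if prof.shape != self.wavelengths_nm.shape:
                raise ValueError(f"profile {name!r} not on the library grid")
            if np.any(prof < 0):
                raise ValueError(f"profile {name!r} has negative values")
            self.profiles[name] = prof

    def matches_grid(self, wavelengths_nm) -> bool:
        return np.array_equal(self.wavelengths_nm, np.asarray(wavelengths_nm))


def _gauss_bands(wl: np.ndarray, bands) -> np.ndarray:
    """Sum of Gaussian bands (center_nm, width_nm, amplitude), max-normalized."""
    prof = np.zeros_like(wl)
    for center, width, amp in bands:
        prof += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    m = prof.max()
    return prof / m if m > 0 else prof


# Band placements: analyte O-H first overtone near 947 nm and N-H stretch
# near 1000 nm; pigment Soret-like blue band, weak green shoulder, and the
# red chlorophyll band; water overtone near 970 nm.
_ANALYTE_BANDS = [(947.0, 18.0, 1.0), (1000.0, 25.0, 0.8)]
_PIGMENT_BANDS = [(430.0, 40.0, 1.0), (530.0, 30.0, 0.08), (670.0, 45.0, 0.9)]
_WATER_BANDS = [(760.0, 15.0, 0.08), (970.0, 35.0, 1.0)]


def default_library(wavelengths_nm) -> ComponentLibrary:
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    return ComponentLibrary(
        wl,
        {
            "analyte": _gauss_bands(wl, _ANALYTE_BANDS),
            "pigment": _gauss_bands(wl, _PIGMENT_BANDS),
            "water": _gauss_bands(wl, _WATER_BANDS),
        },
    )


@dataclass
class SimulationParams:
    """Magnitudes of signal and nuisance variation.

    TFAA step means 4.0 / 3.8 / 4.0 % encode levels that are similar across
    steps with a slight dip at the middle step. ``analyte_absorptivity`` is
    the absorption coefficient per % TFAA; nuisance terms emulate
    multiplicative scatter (slope), additive scatter (offset), smooth
    baseline drift, and sensor noise. All standard deviations must be >= 0.
    """

    tfaa_mean_by_step: tuple = (4.0, 3.8, 4.0)
    tfaa_sd: float = 0.5
    analyte_absorptivity: float = 0.06
    component_means: dict = field(default_factory=lambda: {"pigment": 2.2, "water": 0.5})
    component_sds: dict = field(default_factory=lambda: {"pigment": 0.10, "water": 0.04})
    albedo: float = 0.92
    scatter_slope_sd: float = 0.03
    scatter_offset_sd: float = 0.005
    baseline_poly_degree: int = 2
    baseline_coeff_sd: float = 0.004
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self):
        sds = [self.tfaa_sd, self.scatter_slope_sd, self.scatter_offset_sd,
               self.baseline_coeff_sd, self.noise_sd, *self.component_sds.values()]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "SimulationParams":
        """All nuisance variation off: spectra become a deterministic
        function of the sample's TFAA value."""
        base = dict(
            tfaa_sd=overrides.pop("tfaa_sd", 0.5),
            component_sds={"pigment": 0.0, "water": 0.0},
            scatter_slope_sd=0.0,
            scatter_offset_sd=0.0,
            baseline_coeff_sd=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticDataset:
    """Generated calibration set plus selector ground truth and provenance."""

    calibration_set: CalibrationSet
    planted_band_indices: np.ndarray
    provenance: dict

    def __post_init__(self):
        idx = np.asarray(self.planted_band_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("planted band set is empty")
        if idx.min() < 0 or idx.max() >= self.calibration_set.n_bands:
            raise ValueError("planted band index out of range")
        self.planted_band_indices = idx


def simulate_sample_spectra(
    design: StudyDesign,
    library: ComponentLibrary | None = None,
    params: SimulationParams | None = None,
) -> SyntheticDataset:
    """Draw the full study: reference TFAA per sample, then its spectrum.

    Same (design, library, params) including seed gives bit-identical
    output. Reflectance is clipped into (0, 1]; clip events are counted in
    the provenance record and warned about.
    """
    params = params if params is not None else SimulationParams()
    wl = design.wavelengths_nm
    if library is None:
        library = default_library(wl)
    if not library.matches_grid(wl):
        raise ValueError("component library is not defined on the design's grid")
    if "analyte" not in library.profiles:
        raise ValueError("library must contain an 'analyte' profile")
    if len(params.tfaa_mean_by_step) != len(design.process_steps):
        raise ValueError("tfaa_mean_by_step length must match process steps")

    rng = np.random.default_rng(params.seed)
    roster = design.roster()
    n, p = len(roster), design.n_channels
    step_mean = dict(zip(design.process_steps, params.tfaa_mean_by_step))

    tfaa = np.array([
        rng.normal(step_mean[s], params.tfaa_sd) for s in roster["step"]
    ])
    tfaa = np.clip(tfaa, 0.05, None)

    analyte = library.profiles["analyte"]
    others = [k for k in library.profiles if k != "analyte"]
    lam = np.linspace(-1.0, 1.0, p)  # normalized axis for baseline drift

    X = np.empty((n, p))
    n_clipped = 0
    for i in range(n):
        absorbance = params.analyte_absorptivity * tfaa[i] * analyte
        for name in others:
            c = params.component_means.get(name, 0.0)
            sd = params.component_sds.get(name, 0.0)
            if sd > 0:
                c = c + rng.normal(0.0, sd)
            absorbance = absorbance + max(c, 0.0) * library.profiles[name]
        r = params.albedo * np.exp(-absorbance)
        if params.baseline_coeff_sd > 0:
            coeffs = rng.normal(0.0, params.baseline_coeff_sd, params.baseline_poly_degree + 1)
            r = r + np.polyval(coeffs, lam)
        slope = rng.normal(0.0, params.scatter_slope_sd) if params.scatter_slope_sd > 0 else 0.0
        offset = rng.normal(0.0, params.scatter_offset_sd) if params.scatter_offset_sd > 0 else 0.0
        r = r * (1.0 + slope) + offset
        if params.noise_sd > 0:
            r = r + rng.normal(0.0, params.noise_sd, p)
        clipped = (r <= 0.0) | (r > 1.0)
        n_clipped += int(clipped.sum())
        X[i] = np.clip(r, 1e-6, 1.0)

    if n_clipped:
        warnings.warn(f"{n_clipped} reflectance values clipped into (0, 1]", stacklevel=2)

    planted = np.nonzero(analyte >= 0.5 * analyte.max())[0]
    cal = CalibrationSet(
        X, wl, tfaa, roster["step"].to_numpy(), roster["sample_id"].to_numpy()
    )
    prov = {
        "seed": params.seed,
        "params": _params_dict(params),
        "design": asdict(design),
        "n_clipped": n_clipped,
    }
    return SyntheticDataset(cal, planted, prov)


def _params_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["tfaa_mean_by_step"] = list(d["tfaa_mean_by_step"])
    return d


@dataclass
class SimulatedCube:
    """Raw-count cube with companion frames, stored truth, and mask."""

    raw: SpectralCube
    white: SpectralCube
    dark: SpectralCube
    reflectance: SpectralCube
    foreground_mask: np.ndarray


def simulate_cube(
    spectrum: np.ndarray,
    wavelengths_nm: np.ndarray,
    height: int = 32,
    width: int = 32,
    pixel_noise_sd: float = 0.003,
    background_fraction: float = 0.3,
    background_reflectance: float = 0.02,
    sensor_noise_sd: float = 0.001,
    white_level: float = 1.0,
    dark_level: float = 0.02,
    seed: int = 0,
) -> SimulatedCube:
    """Imaging of a single sample: foreground pixels carry the sample
    spectrum plus iid pixel noise, background pixels a low filler
    reflectance; the raw-count cube is constructed so that dark/white
    calibration recovers the stored reflectance exactly (up to the per-band
    mean frames used)."""
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must be in [0, 1]")
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    if spectrum.shape != wl.shape:
        raise ValueError("spectrum and wavelength grid length mismatch")
    rng = np.random.default_rng(seed)
    p = spectrum.size

    # centered ellipse covering ~ (1 - background_fraction) of the image
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    fg_frac = 1.0 - background_fraction
    if fg_frac <= 0:
        mask = np.zeros((height, width), dtype=bool)
    else:
        scale = np.sqrt(fg_frac * height * width / (np.pi * (height / 2.0) * (width / 2.0)))
        a, b = scale * height / 2.0, scale * width / 2.0
        mask = ((yy - cy) / max(a, 1e-9)) ** 2 + ((xx - cx) / max(b, 1e-9)) ** 2 <= 1.0

    refl = np.empty((height, width, p))
    refl[:] = background_reflectance
    if background_reflectance > 0:
        refl += rng.normal(0.0, background_reflectance * 0.2, refl.shape)
    refl[mask] = spectrum
    if pixel_noise_sd > 0 and mask.any():
        refl[mask] += rng.normal(0.0, pixel_noise_sd, (int(mask.sum()), p))
    refl = np.clip(refl, 1e-6, 1.0)

    white = white_level + rng.normal(0.0, sensor_noise_sd, p)
    dark = dark_level + rng.normal(0.0, sensor_noise_sd, p)
    raw = dark + refl * (white - dark)

    def _frame(vec, kind):
        return SpectralCube(vec.reshape(1, 1, p), wl, kind=kind)

    return SimulatedCube(
        raw=SpectralCube(raw, wl, kind="raw"),
        white=_frame(white, "white"),
        dark=_frame(dark, "dark"),
        reflectance=SpectralCube(refl, wl, kind="reflectance"),
        foreground_mask=mask,
    )


def make_planted_benchmark(
    n_samples: int = 80,
    n_bands: int = 100,
    n_planted: int = 5,
    noise_sd: float = 0.0,
    smoothness: float = 2.0,
    seed: int = 0,
):
    """Small selector benchmark with exactly ``n_planted`` informative bands.

    X is a smooth random spectral matrix (Gaussian-filtered white noise plus
    a small independent component, so neighbouring bands correlate as in
    real spectra); y is an exact linear function of the planted columns
    plus optional noise. Returns ``(X, y, planted_indices)``.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    base = gaussian_filter1d(rng.standard_normal((n_samples, n_bands)), smoothness, axis=1)
    X = base + 0.3 * rng.standard_normal((n_samples, n_bands))
    planted = np.sort(rng.choice(n_bands, size=n_planted, replace=False))
    coefs = rng.uniform(0.5, 1.5, n_planted) * rng.choice([-1.0, 1.0], n_planted)
    y = X[:, planted] @ coefs
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_samples)
    return X, y, planted


def write_dataset(ds: SyntheticDataset, out_dir, cubes: int = 0, cube_size: int = 24) -> None:
    """Persist the fixture: chemistry CSV, wide spectra CSV, JSON sidecar,
    and optionally ENVI cube/white/dark triplets for the first ``cubes``
    samples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = ds.calibration_set
    chem = pd.DataFrame({
        "sample_id": cal.sample_ids,
        "step": cal.steps,
        "tfaa_percent": cal.y,
    })
    chem.to_csv(out / "chemistry.csv", index=False)
    cal.to_frame().to_csv(out / "spectra.csv", index=False)
    sidecar = dict(ds.provenance)
    sidecar["planted_band_indices"] = ds.planted_band_indices.tolist()
    (out / "provenance.json").write_text(json.dumps(sidecar, indent=2, default=float))
    for i in range(min(cubes, cal.n_samples)):
        sim = simulate_cube(
            cal.X[i], cal.wavelengths_nm, cube_size, cube_size,
            seed=int(ds.provenance.get("seed", 0)) + i,
        )
        stem = out / f"cube_{cal.sample_ids[i]}"
        write_envi_cube(sim.raw, stem)
        write_envi_cube(sim.white, Path(str(stem) + "_white"))
        write_envi_cube(sim.dark, Path(str(stem) + "_dark"))
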