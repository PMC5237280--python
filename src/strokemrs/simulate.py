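"""Synthetic single-voxel 1H-MRS cohort generator.

Each spectrum is a sum of metabolite lineshapes (Lorentzian/Gaussian)
on the 0-4.5 ppm axis, a class-invariant macromolecule hump, a residual
water tail rising toward 4.5 ppm, a smooth random baseline wiggle and
Gaussian noise, with a small global chemical-shift jitter that the
creatine referencing step is expected to undo.

Amplitudes are lognormal.  The generator works on the normalized
(UL2CA) scale and is calibrated so that (a) the noiseless
non-infarcted ("contralateral") spectrum has Euclidean norm 100 —
which is exactly what UL2CA normalization enforces — and (b) the
class-conditional heights at the diagnostic datapoints (0.85, 1.33,
3.04/3.05 and 3.62 ppm) match configured per-class median/IQR targets.
Raw (unnormalized) intensities are produced by applying an arbitrary
per-animal gain, which the normalization divides out again.

Two scenarios are provided: `infarct_evolution` (non-infarcted
parenchyma / acute infarct / subacute infarct, class-separating
heights at 1.33, 3.05 and 0.85 ppm) and `brain_regions` (non-infarcted
/ subventricular zone / infarcted, separating at 3.05, 3.62 and
3.04 ppm).  Non-diagnostic resonances carry no class signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Cohort, SpectrumRecord, default_axis, ppm_to_index
from .evaluate import chronological_split

__all__ = [
    "PeakSpec",
    "SimConfig",
    "default_config",
    "simulate_spectrum",
    "simulate_cohort",
    "lognormal_from_median_iqr",
    "lorentzian",
    "gaussian",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Lorentzian profile with unit peak height."""
    return 1.0 / (1.0 + (2.0 * (x - center) / fwhm) ** 2)


def gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Gaussian profile with unit peak height."""
    return np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and quartile ratio.

    mu = ln(median); sigma = ln(q75/q25) / (2 * z_0.75).  Only the
    quartile ratio enters sigma, so strongly skewed printed IQRs are
    matched in spread rather than in each bound.
    """
    if median <= 0 or q25 <= 0 or q75 <= q25:
        raise ValueError("need 0 < q25 < q75 and median > 0")
    return float(np.log(median)), float(np.log(q75 / q25) / (2.0 * _Z75))


@dataclass
class PeakSpec:
    """One resonance (possibly a composite of co-located components).

    `amplitudes` maps class label -> (median, sigma) of the lognormal
    peak amplitude on the UL2CA scale.  `components` lists
    (lineshape, fwhm, height_fraction) tuples summing to unit height at
    the centre; a plain singlet is one component.
    """

    name: str
    ppm: float
    lineshape: str = "lorentzian"
    fwhm: float = 0.05
    components: list = None
    amplitudes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"{self.name}: fwhm must be positive")
        if not 0.0 <= self.ppm <= 4.5:
            raise ValueError(f"{self.name}: ppm outside [0, 4.5]")
        if self.components is None:
            self.components = [(self.lineshape, self.fwhm, 1.0)]

    def profile(self, x: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """Unit-height lineshape evaluated at `x` (centre shifted by `shift`)."""
        shape = {"lorentzian": lorentzian, "gaussian": gaussian}
        out = np.zeros_like(np.asarray(x, dtype=float))
        for kind, fwhm, frac in self.components:
            out = out + frac * shape[kind](x, self.ppm + shift, fwhm)
        return out


def _mm_hump(x: np.ndarray) -> np.ndarray:
    """Fixed macromolecule background shape (unit scale, class-invariant)."""
    return (
        0.6 * gaussian(x, 0.9, 0.5)
        + 0.5 * gaussian(x, 1.4, 0.6)
        + 0.7 * gaussian(x, 2.1, 0.9)
        + 0.45 * gaussian(x, 3.0, 1.2)
    )


def _water_tail(x: np.ndarray) -> np.ndarray:
    """Residual water shoulder rising toward the 4.5 ppm edge (unit height)."""
    return np.exp((x - 4.5) / 0.25)


_APOD_FWHM_PPM = 4.0 / 300.3  # 4 Hz exponential line broadening at 7 T (~0.013 ppm)


def _broadened_noise(rng: np.random.Generator, axis: np.ndarray, sd: float) -> np.ndarray:
    """White noise convolved with the 4 Hz line-broadening kernel.

    Apodization of the FID smooths the spectral noise over neighbouring
    datapoints; the kernel has unit L2 norm so `sd` remains the
    per-point standard deviation after broadening.
    """
    white = rng.normal(0.0, sd, size=axis.size)
    step = abs(axis[1] - axis[0])
    half = max(1, int(round(3 * _APOD_FWHM_PPM / step)))
    t = np.arange(-half, half + 1) * step
    kernel = lorentzian(t, 0.0, _APOD_FWHM_PPM)
    kernel /= np.linalg.norm(kernel)
    return np.convolve(white, kernel, mode="same")


@dataclass
class SimConfig:
    scenario: str
    class_labels: list
    peaks: list
    class_sizes: tuple
    n_points: int = 1383
    noise_sd: float = 0.3  # UL2CA units
    shift_jitter_sd: float = 0.004  # ppm, global per-spectrum
    baseline_amplitude: float = 0.25  # UL2CA units, random smooth wiggle
    mm_amplitude: float = 1.0  # macromolecule hump scale
    mm_sigma: float = 0.15  # lognormal spread of the hump (varies biologically)
    water_amplitude: float = 0.0  # filled by calibration
    water_sigma: float = 0.15  # lognormal spread of the water tail
    gain_median: float = 500.0  # raw-unit per-animal gain
    gain_sigma: float = 0.3
    seed: int = 0
    diagnostic_targets: list = field(default_factory=list)  # (peak, ppm, {cls: (med, q25, q75)})

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class_sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return default_axis(self.n_points)


# per-class (median, q25, q75) of the total datapoint height at the
# diagnostic chemical shifts, on the UL2CA scale
_TARGETS = {
    "infarct_evolution": {
        "classes": ("non_infarcted", "acute", "subacute"),
        "rows": [
            ("LacML", 1.33, [(2.78, 2.38, 3.21), (7.39, 6.67, 8.90), (19.88, 10.38, 22.11)]),
            ("TCr", 3.05, [(3.83, 3.42, 4.18), (1.96, 1.63, 2.36), (2.01, 1.62, 2.31)]),
            ("ML", 0.85, [(3.32, 3.09, 3.95), (3.02, 2.33, 4.27), (12.30, 8.39, 15.52)]),
        ],
        "class_sizes": (48, 20, 14),
    },
    "brain_regions": {
        "classes": ("non_infarcted", "svz", "infarcted"),
        "rows": [
            ("TCr", 3.05, [(5.80, 5.31, 6.04), (5.74, 5.26, 6.44), (2.43, 2.01, 3.32)]),
            ("TCr", 3.04, [(6.92, 6.47, 7.37), (6.91, 6.38, 7.70), (2.84, 1.95, 3.80)]),
            ("Myo", 3.62, [(2.73, 2.31, 2.93), (3.45, 3.15, 3.91), (1.61, 1.41, 2.01)]),
        ],
        "class_sizes": (48, 82, 34),
    },
}

_INVARIANT_QR = 1.35  # q75/q25 ratio for class-invariant resonances


def _base_peaks() -> list:
    """Canonical rat-brain resonances with class-invariant default heights."""
    return [
        PeakSpec("ML", 0.85, "lorentzian", 0.05),
        PeakSpec(
            "LacML",
            1.33,
            components=[("lorentzian", 0.035, 0.45), ("lorentzian", 0.065, 0.55)],
        ),
        PeakSpec("NAA", 2.02, "lorentzian", 0.06),
        PeakSpec("Glx", 2.35, "gaussian", 0.20),
        PeakSpec("TCr", 3.03, "lorentzian", 0.077),
        PeakSpec("Cho", 3.21, "lorentzian", 0.045),
        PeakSpec("TauGlc", 3.42, "gaussian", 0.15),
        PeakSpec("Myo", 3.62, "lorentzian", 0.05),
        PeakSpec("TCr2", 3.93, "lorentzian", 0.06),
    ]


_INVARIANT_HEIGHTS = {
    "ML": 3.3,
    "LacML": 3.0,
    "NAA": 8.0,
    "Glx": 2.5,
    "TCr": 4.0,
    "Cho": 3.2,
    "TauGlc": 2.0,
    "Myo": 2.7,
    "TCr2": 3.0,
}


def _noiseless_spectrum(config: SimConfig, label: str, exclude: Optional[str] = None) -> np.ndarray:
    x = config.axis
    out = config.mm_amplitude * _mm_hump(x) + config.water_amplitude * _water_tail(x)
    for p in config.peaks:
        if p.name == exclude:
            continue
        med = np.exp(p.amplitudes[label][0])
        out = out + med * p.profile(x)
    return out


def _calibrate(config: SimConfig, targets: dict, n_iter: int = 12) -> None:
    """Solve peak-amplitude medians from datapoint targets and the water
    amplitude from the norm-100 constraint, by fixed-point iteration.

    Targets are total heights at the datapoint nearest each listed ppm;
    the peak amplitude absorbs what the background and the other peaks
    do not explain (least squares over the peak's target datapoints,
    floored at 5% of the target to stay positive).
    """
    x = config.axis
    by_name = {p.name: p for p in config.peaks}
    control = config.class_labels[0]
    # seed: class-invariant heights everywhere
    for p in config.peaks:
        med = _INVARIANT_HEIGHTS[p.name]
        sig = np.log(_INVARIANT_QR) / (2.0 * _Z75)
        p.amplitudes = {c: (float(np.log(med)), sig) for c in config.class_labels}

    # group targets by peak: peak -> [(snapped index, {class: (m, q25, q75)})]
    grouped: dict[str, list] = {}
    for name, ppm, rows in targets["rows"]:
        idx = ppm_to_index(x, ppm)
        per_class = dict(zip(config.class_labels, rows))
        grouped.setdefault(name, []).append((idx, per_class))

    for _ in range(n_iter):
        for name, tgt_list in grouped.items():
            peak = by_name[name]
            prof = peak.profile(x)
            for c in config.class_labels:
                rest = _noiseless_spectrum(config, c, exclude=name)
                num = den = 0.0
                sigmas = []
                for idx, per_class in tgt_list:
                    med, q25, q75 = per_class[c]
                    resid = max(med - rest[idx], 0.05 * med)
                    num += prof[idx] * resid
                    den += prof[idx] ** 2
                    sigmas.append(np.log(q75 / q25) / (2.0 * _Z75))
                amp = num / den
                peak.amplitudes[c] = (float(np.log(amp)), float(np.mean(sigmas)))
        # water tail fills the control spectrum's energy up to norm 100
        base = _noiseless_spectrum(config, control) - config.water_amplitude * _water_tail(x)
        h = _water_tail(x)
        a = float(h @ h)
        b = 2.0 * float(base @ h)
        cc = float(base @ base) - 100.0**2
        disc = b * b - 4.0 * a * cc
        if cc >= 0 or disc <= 0:
            warnings.warn("metabolite energy already exceeds norm 100; no water tail")
            config.water_amplitude = 0.0
        else:
            config.water_amplitude = float((-b + np.sqrt(disc)) / (2.0 * a))

    config.diagnostic_targets = [
        (name, ppm, dict(zip(config.class_labels, rows)))
        for name, ppm, rows in targets["rows"]
    ]


def default_config(scenario: str, seed: int = 0, **overrides) -> SimConfig:
    """Calibrated simulator configuration for one of the two scenarios.

    Class-conditional target medians/IQRs at the diagnostic datapoints
    come from the published training-set summaries; study-sized cohorts
    (48/20/14 and 48/82/34 spectra) are the defaults.
    """
    if scenario not in _TARGETS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {sorted(_TARGETS)}")
    spec = _TARGETS[scenario]
    config = SimConfig(
        scenario=scenario,
        class_labels=list(spec["classes"]),
        peaks=_base_peaks(),
        class_sizes=spec["class_sizes"],
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(config, k):
            raise TypeError(f"unknown SimConfig field {k!r}")
        setattr(config, k, v)
    _calibrate(config, spec)
    return config


def simulate_spectrum(
    label: str,
    config: SimConfig,
    rng: np.random.Generator,
    gain: float = 1.0,
    animal_id: str = "1",
    spectrum_id: str = "sim",
    region: str = "non_infarcted",
    phase: str = "healthy",
    hemisphere: str = "n/a",
) -> SpectrumRecord:
    """Draw one unnormalized spectrum of the given class."""
    x = config.axis
    shift = rng.normal(0.0, config.shift_jitter_sd) if config.shift_jitter_sd > 0 else 0.0
    mm_amp = config.mm_amplitude * np.exp(rng.normal(0.0, config.mm_sigma))
    out = mm_amp * _mm_hump(x - shift)
    w_amp = config.water_amplitude * np.exp(rng.normal(0.0, config.water_sigma))
    out = out + w_amp * _water_tail(x)
    for p in config.peaks:
        mu, sigma = p.amplitudes[label]
        amp = np.exp(rng.normal(mu, sigma)) if sigma > 0 else np.exp(mu)
        out = out + amp * p.profile(x, shift=shift)
    if config.baseline_amplitude > 0:
        t = x / 4.5
        for j in (1, 2, 3):
            out = out + (
                config.baseline_amplitude
                * rng.normal(0.0, 1.0)
                / j
                * np.cos(j * np.pi * t + rng.uniform(0.0, 2.0 * np.pi))
            )
    if config.noise_sd > 0:
        out = out + _broadened_noise(rng, x, config.noise_sd)
    return SpectrumRecord(
        animal_id=animal_id,
        spectrum_id=spectrum_id,
        region=region,
        phase=phase,
        label=label,
        hemisphere=hemisphere,
        ppm_axis=x,
        intensities=gain * out,
        normalized=False,
    )


_SCENARIO_ANATOMY = {
    # label -> (region, phase) for the two lesion classes of each scenario
    "infarct_evolution": {"acute": ("infarcted", "acute"), "subacute": ("infarcted", "subacute")},
    "brain_regions": {"svz": ("svz", "subacute"), "infarcted": ("infarcted", "subacute")},
}


def simulate_cohort(config: SimConfig, train_fraction: float = 2.0 / 3.0) -> Cohort:
    """Generate a full cohort with contralateral pairing and a 2/3 chronological split.

    Each of the first-class animals contributes one non-infarcted
    spectrum that doubles as the contralateral reference; lesion-class
    spectra are spread evenly over the animal-ID range so every class
    straddles the chronological split in roughly the same proportion.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    labels = config.class_labels
    n0 = config.class_sizes[0]
    gains = {
        str(i): config.gain_median * np.exp(rng.normal(0.0, config.gain_sigma))
        for i in range(1, n0 + 1)
    }
    records, cmap = [], {}
    control_id = {}
    for i in range(1, n0 + 1):
        sid = f"A{i:03d}-{labels[0]}"
        rec = simulate_spectrum(
            labels[0],
            config,
            rng,
            gain=gains[str(i)],
            animal_id=str(i),
            spectrum_id=sid,
            region="non_infarcted",
            phase="healthy",
            hemisphere="left",
        )
        records.append(rec)
        control_id[str(i)] = sid
        cmap[sid] = sid
    for ci, label in enumerate(labels[1:], start=1):
        m = config.class_sizes[ci]
        region, phase = _SCENARIO_ANATOMY[config.scenario][label]
        for j in range(m):
            animal = str((j * n0) // m + 1)
            sid = f"A{int(animal):03d}-{label}-{j:02d}"
            rec = simulate_spectrum(
                label,
                config,
                rng,
                gain=gains[animal],
                animal_id=animal,
                spectrum_id=sid,
                region=region,
                phase=phase,
                hemisphere="right" if j % 2 == 0 else "left",
            )
            records.append(rec)
            cmap[sid] = control_id[animal]
    cohort = Cohort(records, list(labels), cmap)
    return chronological_split(cohort, train_fraction)
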