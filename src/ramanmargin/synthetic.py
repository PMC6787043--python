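"""Synthetic tissue Raman spectra with the statistical structure the
analysis assumes.

The generator emulates what the two portable instruments see when pointed at
resected breast tissue:

* a smooth fluorescence background that is flat through the fingerprint
  region and rises increasingly below 400 cm^-1, hitting ~39.9 cps at
  400 cm^-1 for the 1064 nm system and ~83.7 cps for the 785 nm system;
* Gaussian Raman bands at the reference band positions, with class-dependent
  amplitudes: tumor tissue shows elevated nucleic-acid/protein bands (742,
  941, 1002/1006, 1331, 1448/1453, 1663 cm^-1) and depressed lipid bands
  (1062/1063, 1082, 1302/1303, 1439/1442, 1653/1657, 1746, 2850, 2893 cm^-1);
* between-spectrum biochemical variability modelled as two correlated
  lognormal pool factors (lipid pool, protein/nucleic pool) shared by the
  bands of each pool, plus independent per-band lognormal jitter;
* iid Gaussian channel noise, Poisson-count cosmic-ray spikes, and optional
  surgical-marking-ink peaks at 693, 1260, 1348, 1398, 1541 and 1597 cm^-1.

Every output is a pure function of (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, LabelError
from .spectra import PROFILES, InstrumentProfile, RamanSpectrum

DYE_CENTERS = (693.0, 1260.0, 1348.0, 1398.0, 1541.0, 1597.0)

#: fluorescence level (cps) at 400 cm^-1, per excitation wavelength
PLATEAU_AT_400 = {1064: 39.9, 785: 83.7}


@dataclass(frozen=True)
class BandComponent:
    """One Gaussian Raman band with class-dependent amplitude.

    ``healthy_amp``/``tumor_amp`` are peak heights in counts per second; the
    sign of their difference encodes the direction of the tumor-minus-healthy
    difference spectrum at this band.  ``pool`` names the biochemical pool
    whose between-spectrum abundance factor multiplies this band ("lipid" or
    "protein").
    """

    center: float
    width: float  # Gaussian sigma, cm^-1
    healthy_amp: float
    tumor_amp: float
    assignment: str = ""
    pool: str = "protein"

    def __post_init__(self) -> None:
        if self.healthy_amp < 0 or self.tumor_amp < 0:
            raise ValueError("band amplitudes must be >= 0")
        if not (math.isfinite(self.healthy_amp) and math.isfinite(self.tumor_amp)):
            raise ValueError("band amplitudes must be finite")


# (center, healthy_amp, tumor_amp, pool, assignment)
# Amplitudes are the generator's defaults: lipid bands stronger in healthy
# tissue, nucleic-acid/protein bands stronger in tumor, magnitudes chosen to
# land the pipeline in the published 88-96% accuracy regime.
_BANDS_785 = [
    (742.0, 8.0, 14.0, "protein", "Ring breathing of DNA/RNA bases; tryptophan"),
    (870.0, 14.0, 12.0, "protein", "C-C stretch, collagen backbone / proline"),
    (941.0, 12.0, 20.0, "protein", "Proline, nu(C-C) collagen backbone; polysaccharides"),
    (1002.0, 10.0, 16.0, "protein", "Phenylalanine ring breathing"),
    (1062.0, 22.0, 16.0, "lipid", "Chain C-C stretch in lipids; O-P-O in DNA/RNA"),
    (1082.0, 14.0, 11.0, "lipid", "Nucleic acids; C-C/C-O in phospholipids"),
    (1302.0, 30.0, 20.0, "lipid", "CH2 twist of lipids/fatty acids/collagen"),
    (1331.0, 8.0, 15.0, "protein", "DNA, phospholipids"),
    (1439.0, 40.0, 26.0, "lipid", "CH2 bend, normal breast tissue"),
    (1448.0, 18.0, 26.0, "protein", "CH2 bend, malignant breast tissue"),
    (1640.0, 12.0, 15.0, "protein", "Amide I"),
    (1657.0, 28.0, 18.0, "lipid", "C=C of lipids in healthy tissue"),
    (1682.0, 8.0, 11.0, "protein", "Amide I disorder, collagen"),
    (1746.0, 18.0, 11.0, "lipid", "nu(C=O) of phospholipids"),
    (2850.0, 60.0, 36.0, "lipid", "CH2 symmetric stretch of lipids"),
    (2893.0, 45.0, 32.0, "lipid", "CH2 asymmetric stretch, lipids+proteins"),
    (2933.0, 30.0, 35.0, "protein", "CH3 asymmetric stretch of proteins"),
]

_BANDS_1064 = [
    (941.0, 12.0, 20.0, "protein", "Proline, nu(C-C) collagen backbone; polysaccharides"),
    (1006.0, 10.0, 16.0, "protein", "Phenylalanine ring breathing"),
    (1063.0, 22.0, 16.0, "lipid", "Chain C-C stretch in lipids; O-P-O in DNA/RNA"),
    (1081.0, 14.0, 11.0, "lipid", "Nucleic acids; C-C/C-O in phospholipids"),
    (1303.0, 30.0, 20.0, "lipid", "CH2 twist of lipids/fatty acids/collagen"),
    (1442.0, 40.0, 26.0, "lipid", "CH2 bend, normal breast tissue"),
    (1453.0, 18.0, 26.0, "protein", "CH2 bend, malignant breast tissue"),
    (1627.0, 10.0, 12.0, "protein", "Amide I"),
    (1653.0, 28.0, 18.0, "lipid", "C=C of lipids in healthy tissue"),
    (1663.0, 8.0, 13.0, "protein", "Nucleic acid modes; amide I"),
    (1683.0, 8.0, 11.0, "protein", "Amide I disorder, collagen"),
    (1746.0, 18.0, 11.0, "lipid", "nu(C=O) of phospholipids"),
]


def default_bands(profile: InstrumentProfile) -> list[BandComponent]:
    """Default class-dependent band list for a profile.

    Band widths default to 2x the instrument resolution, so the coarse
    1064 nm system produces broader, more blended peaks than the 785 nm one.
    """
    table = _BANDS_1064 if profile.excitation_nm == 1064 else _BANDS_785
    width = 2.0 * profile.resolution
    return [
        BandComponent(center=c, width=width, healthy_amp=h, tumor_amp=t,
                      assignment=a, pool=p)
        for (c, h, t, p, a) in table
    ]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-spectrum generator.

    baseline is (amplitude, decay, plateau): the fluorescence background is
    ``flat + amplitude * exp(-(shift - shift_min) / decay)`` with ``flat``
    chosen so that the background equals ``plateau`` cps at 400 cm^-1.

    ``amp_cv`` is the per-band lognormal jitter cv; ``pool_cv`` the cv of the
    two shared biochemical pool factors.  ``cosmic_ray_rate`` is the expected
    Poisson number of spikes per spectrum.  ``mixed_fraction`` is the tumor
    fraction used for label="mixed".
    """

    profile: InstrumentProfile
    bands: list[BandComponent] = field(default_factory=list)
    baseline: tuple[float, float, float] | None = None  # None -> profile default
    noise_sd: float = 0.3
    amp_cv: float = 0.015
    pool_cv: float = 0.22
    cosmic_ray_rate: float = 0.1
    dye_centers: tuple[float, ...] = DYE_CENTERS
    dye_amplitude: float = 15.0
    dye_probability: float = 0.0
    mixed_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bands:
            self.bands = default_bands(self.profile)
        if self.baseline is None:
            amp = 90.0 if self.profile.excitation_nm == 785 else 35.0
            self.baseline = (amp, 250.0, PLATEAU_AT_400[self.profile.excitation_nm])
        for name in ("noise_sd", "amp_cv", "pool_cv", "cosmic_ray_rate",
                     "dye_amplitude", "dye_probability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mixed_fraction <= 1.0:
            raise ValueError("mixed_fraction must be in [0, 1]")

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


def default_config(excitation_nm: int = 785, **changes) -> GeneratorConfig:
    return GeneratorConfig(profile=PROFILES[excitation_nm]).with_(**changes)


def baseline_curve(cfg: GeneratorConfig, shift: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless fluorescence background on an axis."""
    amp, decay, plateau = cfg.baseline
    x0 = cfg.profile.shift_min
    flat = plateau - amp * math.exp(-(400.0 - x0) / decay)
    return flat + amp * np.exp(-(shift - x0) / decay)


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def peak_model(cfg: GeneratorConfig, label: str, shift: np.ndarray) -> np.ndarray:
    """Noiseless sum of class-amplitude Gaussian bands (no baseline)."""
    amps = _class_amplitudes(cfg, label)
    out = np.zeros_like(shift)
    for band, a in zip(cfg.bands, amps):
        out += a * _gaussian(shift, band.center, band.width)
    return out


def _class_amplitudes(cfg: GeneratorConfig, label: str) -> np.ndarray:
    if label == "healthy":
        return np.array([b.healthy_amp for b in cfg.bands])
    if label == "tumor":
        return np.array([b.tumor_amp for b in cfg.bands])
    if label == "mixed":
        f = cfg.mixed_fraction
        return np.array(
            [(1.0 - f) * b.healthy_amp + f * b.tumor_amp for b in cfg.bands]
        )
    raise LabelError(f"unknown tissue label {label!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean lognormal draw(s); degenerate at 1 when cv=0."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_spectrum(
    label: str,
    cfg: GeneratorConfig,
    seed: int | np.random.SeedSequence,
    site_id: str = "",
    position: tuple[float, float] | None = None,
) -> RamanSpectrum:
    """Generate one raw spectrum for a tissue class.

    The random stream is consumed identically for every label, so two labels
    generated from the same seed differ only through their class amplitudes
    (zero effect size => bitwise-identical spectra).
    """
    base_amps = _class_amplitudes(cfg, label)  # validates label first
    rng = np.random.default_rng(seed)
    shift = cfg.profile.axis()

    pool_factors = {
        "lipid": _lognormal_factor(rng, cfg.pool_cv),
        "protein": _lognormal_factor(rng, cfg.pool_cv),
    }
    jitter = _lognormal_factor(rng, cfg.amp_cv, size=len(cfg.bands))

    intensity = baseline_curve(cfg, shift).copy()
    for band, a, j in zip(cfg.bands, base_amps, jitter):
        amp = a * pool_factors.get(band.pool, 1.0) * j
        intensity += amp * _gaussian(shift, band.center, band.width)

    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=shift.size)
    else:
        rng.normal(0.0, 1.0, size=shift.size)  # keep stream alignment

    n_spikes = int(rng.poisson(cfg.cosmic_ray_rate))
    spike_channels: list[int] = []
    for _ in range(n_spikes):
        ch = int(rng.integers(0, shift.size))
        factor = rng.uniform(5.0, 15.0)
        intensity[ch] = abs(intensity[ch]) * factor
        spike_channels.append(ch)

    has_dye = rng.uniform() < cfg.dye_probability
    if has_dye and cfg.dye_amplitude > 0:
        width = 2.0 * cfg.profile.resolution
        for c in cfg.dye_centers:
            if cfg.profile.shift_min <= c <= cfg.profile.shift_max:
                intensity += cfg.dye_amplitude * _gaussian(shift, c, width)

    intensity = np.clip(intensity, 0.0, None)
    return RamanSpectrum(
        shift=shift,
        intensity=intensity,
        excitation_nm=cfg.profile.excitation_nm,
        mode="microscope",
        label=label,
        site_id=site_id,
        position=position,
        stage="raw",
        meta={
            "synthetic": True,
            "spike_channels": spike_channels,
            "n_spikes": n_spikes,
            "dye": bool(has_dye),
        },
    )


def simulate_cohort(
    n_healthy: int,
    n_tumor: int,
    n_mixed: int,
    cfg: GeneratorConfig,
) -> list[RamanSpectrum]:
    """Generate a labeled cohort; per-spectrum seeds derive from cfg.seed."""
    if min(n_healthy, n_tumor, n_mixed) < 0:
        raise ValueError("cohort counts must be >= 0")
    if n_healthy + n_tumor + n_mixed == 0:
        raise EmptyInputError("at least one cohort count must be > 0")
    plan = (
        [("healthy", i) for i in range(n_healthy)]
        + [("tumor", i) for i in range(n_tumor)]
        + [("mixed", i) for i in range(n_mixed)]
    )
    spectra = []
    for idx, (label, k) in enumerate(plan):
        seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, idx))
        spectra.append(
            simulate_spectrum(label, cfg, seed, site_id=f"{label[0]}{k + 1:02d}")
        )
    return spectra


def simulate_transit(
    site_labels: Sequence[str],
    cfg: GeneratorConfig,
) -> list[RamanSpectrum]:
    """Generate an ordered margin-crossing transit, one site per mm.

    Site ``i`` sits at position (i, 0) mm; the ground-truth class sequence is
    the input label list, carried on each spectrum for change-point scoring.
    """
    if len(site_labels) == 0:
        raise EmptyInputError("transit needs at least one site label")
    if len(site_labels) < 2:
        raise EmptyInputError("a transit needs at least 2 sites")
    spectra = []
    for i, label in enumerate(site_labels):
        seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, i))
        s = simulate_spectrum(
            label, cfg, seed, site_id=f"s{i + 1}", position=(float(i), 0.0)
        )
        s.meta["transit_index"] = i
        spectra.append(s)
    return spectra


TRANSIT_1 = ["healthy", "healthy", "mixed", "healthy", "healthy",
             "tumor", "tumor", "tumor", "tumor", "tumor"]
"""Label pattern of the first published margin transit (sites s6-s15):
healthy at s6-s7, a mixed signature at s8, healthy again at s9-s10, then
tumor from s11 through s15."""
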