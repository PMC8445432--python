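"""Synthetic Raman spectrum generator emulating a two-entity tissue study.

The generator reproduces the statistical structure the downstream analysis
assumes: two tumor entities (PA, benign pleomorphic adenoma; ACC, malignant
adenoid cystic carcinoma), ten samples per entity, thirty measurements per
sample, entity-specific band intensities in the fingerprint region, a
per-sample multiplicative intensity signature, a smooth fluorescence baseline
per spectrum, additive detector noise, and occasional contamination
(residual paraffin at 1126 cm^-1, formalin at 907 cm^-1, glass-like outlier
spectra with a broad band near 1080 cm^-1).

Entity templates are calibrated: band amplitudes are jointly adjusted so
that the noise-free template, evaluated at the grid point nearest each band
center, equals the configured per-entity mean intensity exactly, despite
overlap of Lorentzian tails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectra_io import (
    ACC,
    PA,
    Spectrum,
    SpectrumSet,
    WavenumberGrid,
    canonical_fingerprint_grid,
)

# Entity-dependent mean band intensities (counts) with biochemical
# assignments; ranges are intensity-comparison windows, singletons are peak
# positions.  The peak center used for simulation is the range midpoint.
TABLE_BANDS: list[dict] = [
    {"low": 1644.0, "high": 1670.0, "pa": 960.0, "acc": 1155.0,
     "assignment": "Amide, nucleic acids"},
    {"low": 1428.0, "high": 1456.0, "pa": 1280.0, "acc": 2960.0,
     "assignment": "Proteins, lipids"},
    {"low": 1284.0, "high": 1294.0, "pa": 475.0, "acc": 845.0,
     "assignment": "Nucleic acid"},
    {"low": 1213.0, "high": 1248.0, "pa": 630.0, "acc": 845.0,
     "assignment": "Amide"},
    {"low": 1193.0, "high": 1207.0, "pa": 310.0, "acc": 450.0,
     "assignment": "Nucleic acids"},
    {"low": 1111.0, "high": 1124.0, "pa": 900.0, "acc": 1130.0,
     "assignment": "RNA, glucose"},
    {"low": 1047.0, "high": 1060.0, "pa": 690.0, "acc": 930.0,
     "assignment": "Lipids, proteins, glycogen"},
    {"low": 1030.0, "high": 1030.0, "pa": 240.0, "acc": 301.0,
     "assignment": "Phenylalanine"},
    {"low": 1003.0, "high": 1003.0, "pa": 1490.0, "acc": 1850.0,
     "assignment": "Phenylalanine"},
    {"low": 914.0, "high": 935.0, "pa": 740.0, "acc": 575.0,
     "assignment": "Proteins, collagen"},
    {"low": 888.0, "high": 900.0, "pa": 420.0, "acc": 230.0,
     "assignment": "Proteins, saccharides"},
]

GLASS_CENTER = 1080.0  # cm^-1, broad borosilicate band
GLASS_WIDTH = 120.0    # HWHM, cm^-1
PARAFFIN_CENTER = 1126.0
FORMALIN_CENTER = 907.0


@dataclass(frozen=True)
class BandTemplate:
    """One Raman band: peak center, half-width and per-entity amplitude."""

    center: float           # cm^-1
    width: float            # half-width at half-maximum, cm^-1
    amplitude_pa: float     # counts
    amplitude_acc: float    # counts
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude_pa < 0 or self.amplitude_acc < 0:
            raise ValueError("band amplitudes must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, w: np.ndarray) -> np.ndarray:
        """Unit-height line shape evaluated at wavenumbers ``w``."""
        d = np.asarray(w, dtype=float) - self.center
        if self.shape == "lorentzian":
            return self.width**2 / (d**2 + self.width**2)
        sigma = self.width / np.sqrt(2.0 * np.log(2.0))
        return np.exp(-0.5 * (d / sigma) ** 2)

    def amplitude(self, entity: str) -> float:
        if entity == PA:
            return self.amplitude_pa
        if entity == ACC:
            return self.amplitude_acc
        raise ValueError(f"no amplitude defined for entity {entity!r}")


def default_band_templates(width: float = 8.0) -> list[BandTemplate]:
    """Band templates from the built-in assignment table (range midpoints)."""
    return [
        BandTemplate(
            center=(row["low"] + row["high"]) / 2.0,
            width=width,
            amplitude_pa=row["pa"],
            amplitude_acc=row["acc"],
        )
        for row in TABLE_BANDS
    ]


@dataclass
class BaselineConfig:
    """Per-spectrum smooth fluorescence background.

    A random polynomial of the given degree is drawn, shifted to be
    non-negative, and scaled so its span is a uniform fraction (within
    ``magnitude_range``) of the largest band amplitude.
    """

    degree: int = 3
    magnitude_range: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self):
        lo, hi = self.magnitude_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid baseline magnitude range")
        if self.degree < 0:
            raise ValueError("baseline degree must be >= 0")


@dataclass
class ContaminationConfig:
    """Per-spectrum contamination probabilities."""

    paraffin_prob: float = 0.02
    formalin_prob: float = 0.02
    glass_prob: float = 0.01
    peak_amplitude: float = 300.0   # counts added at 1126 / 907 cm^-1
    glass_amplitude: float = 2000.0  # counts, height of the glass band

    def __post_init__(self):
        for p in (self.paraffin_prob, self.formalin_prob, self.glass_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("contamination probabilities must be in [0, 1]")
        if self.peak_amplitude < 0 or self.glass_amplitude < 0:
            raise ValueError("contamination amplitudes must be non-negative")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic measurement campaign.

    Defaults mirror the emulated study design: 10 samples per entity with 30
    spectra each (600 spectra total), a 10% relative SD per-sample intensity
    factor, additive Gaussian noise with SD 30 counts, a cubic fluorescence
    baseline, and low-rate paraffin/formalin/glass contamination.
    """

    bands: list[BandTemplate] = field(default_factory=default_band_templates)
    n_samples_per_entity: int = 10
    n_spectra_per_sample: int = 30
    sample_effect_sd: float = 0.10
    noise_sd: float = 30.0
    baseline: BaselineConfig | None = field(default_factory=BaselineConfig)
    contamination: ContaminationConfig | None = field(
        default_factory=ContaminationConfig
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_entity < 1 or self.n_spectra_per_sample < 1:
            raise ValueError("sample and spectrum counts must be positive")
        if self.sample_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not self.bands:
            raise ValueError("at least one band template is required")

    @classmethod
    def noise_free(cls, seed: int = 0) -> "SyntheticConfig":
        """Deterministic configuration: templates only, no nuisance terms."""
        return cls(
            sample_effect_sd=0.0,
            noise_sd=0.0,
            baseline=None,
            contamination=None,
            seed=seed,
        )


def _calibrated_amplitudes(
    bands: list[BandTemplate], grid: WavenumberGrid, entity: str
) -> np.ndarray:
    """Solve for band heights so the summed template hits each configured
    intensity exactly at the grid point nearest the band center."""
    w = grid.values
    anchors = np.array(
        [w[np.argmin(np.abs(w - b.center))] for b in bands]
    )
    A = np.column_stack([b.profile(anchors) for b in bands])
    target = np.array([b.amplitude(entity) for b in bands])
    amps = np.linalg.solve(A, target)
    if np.any(amps < 0):
        raise ValueError(
            "band overlap too strong: calibrated amplitudes went negative"
        )
    return amps


def entity_template(
    entity: str,
    grid: WavenumberGrid | None = None,
    bands: list[BandTemplate] | None = None,
) -> np.ndarray:
    """Noise-free entity spectrum on ``grid`` (canonical grid by default)."""
    grid = grid or canonical_fingerprint_grid()
    bands = bands if bands is not None else default_band_templates()
    amps = _calibrated_amplitudes(bands, grid, entity)
    w = grid.values
    template = np.zeros_like(w)
    for amp, b in zip(amps, bands):
        template += amp * b.profile(w)
    return template


def glass_signature(grid: WavenumberGrid | None = None) -> np.ndarray:
    """Unit-height glass-like reference: broad Gaussian at 1080 cm^-1."""
    grid = grid or canonical_fingerprint_grid()
    d = grid.values - GLASS_CENTER
    sigma = GLASS_WIDTH / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * (d / sigma) ** 2)


def _random_baseline(
    rng: np.random.Generator, n: int, cfg: BaselineConfig, max_amp: float
) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    coeffs = rng.uniform(-1.0, 1.0, size=cfg.degree + 1)
    curve = np.polynomial.polynomial.polyval(t, coeffs)
    span = curve.max() - curve.min()
    if span < 1e-12:
        curve = np.zeros(n)
        span = 1.0
    lo, hi = cfg.magnitude_range
    magnitude = rng.uniform(lo, hi) * max_amp
    return (curve - curve.min()) / span * magnitude


def _contamination_peak(grid: WavenumberGrid, center: float, amp: float) -> np.ndarray:
    b = BandTemplate(center=center, width=8.0, amplitude_pa=0.0, amplitude_acc=0.0)
    return amp * b.profile(grid.values)


def generate_dataset(
    cfg: SyntheticConfig, grid: WavenumberGrid | None = None
) -> tuple[SpectrumSet, dict]:
    """Generate a labeled synthetic spectrum set plus a ground-truth record.

    Each spectrum is ``sum(band profiles) * sample_factor + baseline + noise``
    with optional contamination; glass-contaminated spectra are replaced
    outright by the glass signature plus noise.  One global seed drives
    per-sample and per-spectrum randomness through NumPy ``SeedSequence``
    spawning (sample streams in generation order), so regeneration with the
    same seed is bit-identical.

    Returns the set and a ground-truth dict with per-sample factors, glass
    outlier indices, contamination events and a config echo.
    """
    grid = grid or canonical_fingerprint_grid()
    templates = {e: entity_template(e, grid, cfg.bands) for e in (PA, ACC)}
    max_amp = max(
        max(b.amplitude_pa, b.amplitude_acc) for b in cfg.bands
    )
    glass = glass_signature(grid)

    root_ss = np.random.SeedSequence(cfg.seed)
    n_samples = 2 * cfg.n_samples_per_entity
    sample_seeds = root_ss.spawn(n_samples)

    spectra: list[Spectrum] = []
    sample_factors: dict[str, float] = {}
    glass_indices: list[int] = []
    events: list[dict] = []
    idx = 0
    for e_i, entity in enumerate((PA, ACC)):
        for s_i in range(cfg.n_samples_per_entity):
            sid = f"{entity}{s_i + 1:02d}"
            rng = np.random.default_rng(
                sample_seeds[e_i * cfg.n_samples_per_entity + s_i]
            )
            if cfg.sample_effect_sd > 0:
                factor = float(
                    np.clip(rng.normal(1.0, cfg.sample_effect_sd), 0.1, None)
                )
            else:
                factor = 1.0
            sample_factors[sid] = factor
            for m in range(1, cfg.n_spectra_per_sample + 1):
                y = templates[entity] * factor
                if cfg.baseline is not None:
                    y = y + _random_baseline(rng, len(grid), cfg.baseline, max_amp)
                if cfg.contamination is not None:
                    c = cfg.contamination
                    if rng.uniform() < c.glass_prob:
                        y = c.glass_amplitude * glass.copy()
                        glass_indices.append(idx)
                        events.append(
                            {"index": idx, "sample_id": sid, "kind": "glass"}
                        )
                    else:
                        if rng.uniform() < c.paraffin_prob:
                            y = y + _contamination_peak(
                                grid, PARAFFIN_CENTER, c.peak_amplitude
                            )
                            events.append(
                                {"index": idx, "sample_id": sid, "kind": "paraffin"}
                            )
                        if rng.uniform() < c.formalin_prob:
                            y = y + _contamination_peak(
                                grid, FORMALIN_CENTER, c.peak_amplitude
                            )
                            events.append(
                                {"index": idx, "sample_id": sid, "kind": "formalin"}
                            )
                if cfg.noise_sd > 0:
                    y = y + rng.normal(0.0, cfg.noise_sd, size=len(grid))
                spectra.append(Spectrum(grid, y, sid, m, entity))
                idx += 1

    truth = {
        "sample_factors": sample_factors,
        "glass_outlier_indices": glass_indices,
        "contamination_events": events,
        "config": _config_echo(cfg),
    }
    return SpectrumSet(spectra), truth


def inject_outliers(
    sset: SpectrumSet, rate: float, seed: int, glass_amplitude: float = 2000.0
) -> tuple[SpectrumSet, list[int]]:
    """Replace a random fraction of spectra with glass-like outliers.

    Each spectrum is independently replaced (probability ``rate``) by the
    glass reference signature scaled to ``glass_amplitude`` plus mild noise.
    Returns a new set and the replaced indices.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    glass = glass_amplitude * glass_signature(sset.grid)
    replaced: list[int] = []
    new_spectra: list[Spectrum] = []
    for i, s in enumerate(sset):
        if rate > 0 and rng.uniform() < rate:
            noise = rng.normal(0.0, 0.01 * glass_amplitude, size=len(sset.grid))
            new_spectra.append(s.with_intensities(glass + noise))
            replaced.append(i)
        else:
            new_spectra.append(s)
    return SpectrumSet(new_spectra), replaced


def _config_echo(cfg: SyntheticConfig) -> dict:
    echo = asdict(cfg)
    echo["bands"] = [asdict(b) for b in cfg.bands]
    return echo


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return path
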