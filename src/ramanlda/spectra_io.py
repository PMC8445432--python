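"""Spectrum containers, file I/O, grid resampling and fingerprint cropping.

A spectrum is an intensity vector (arbitrary detector counts) on an ascending
wavenumber grid in cm^-1.  All downstream analysis assumes a shared grid; the
canonical fingerprint grid spans 600-1700 cm^-1 with exactly 249 uniformly
spaced points (spacing 1100/248 cm^-1).

File dialect: per-spectrum files are two-column numeric text (wavenumber,
intensity), comma- or tab/whitespace-delimited, with optional '#' comment
lines.  A manifest is a CSV with header ``sample_id,entity,file``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PA = "PA"
ACC = "ACC"
UNKNOWN = "UNKNOWN"
ENTITIES = (PA, ACC, UNKNOWN)

FINGERPRINT_LOW = 600.0
FINGERPRINT_HIGH = 1700.0
FINGERPRINT_N_POINTS = 249


def parse_entity(label: str) -> str:
    """Parse an entity label case-insensitively; empty/missing -> UNKNOWN."""
    s = str(label).strip().upper()
    if s in ("", "NA", "NAN", "NONE"):
        return UNKNOWN
    if s not in ENTITIES:
        raise ValueError(f"unknown entity label {label!r}; expected one of {ENTITIES}")
    return s


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis (cm^-1)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid values must be finite")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def canonical_fingerprint_grid() -> WavenumberGrid:
    """The canonical 249-point uniform grid over [600, 1700] cm^-1."""
    return WavenumberGrid(
        np.linspace(FINGERPRINT_LOW, FINGERPRINT_HIGH, FINGERPRINT_N_POINTS)
    )


@dataclass
class Spectrum:
    """One Raman measurement: intensities on a grid plus sample metadata."""

    grid: WavenumberGrid
    intensities: np.ndarray
    sample_id: str
    measurement_index: int = 1
    entity: str = UNKNOWN

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.grid):
            raise ValueError(
                f"intensities length {y.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        if self.measurement_index < 1:
            raise ValueError("measurement_index must be >= 1")
        self.intensities = y
        self.entity = parse_entity(self.entity)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one wavenumber grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self):
        if not self.spectra:
            raise ValueError("SpectrumSet must contain at least one spectrum")
        g0 = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid != g0:
                raise ValueError("all spectra in a set must share one grid")
        ent: dict[str, str] = {}
        for s in self.spectra:
            prev = ent.setdefault(s.sample_id, s.entity)
            if prev != s.entity:
                raise ValueError(
                    f"sample {s.sample_id!r} carries inconsistent entity labels "
                    f"({prev} vs {s.entity})"
                )

    @property
    def grid(self) -> WavenumberGrid:
        return self.spectra[0].grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_variables) matrix."""
        return np.vstack([s.intensities for s in self.spectra])

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    def entities(self) -> list[str]:
        return [s.entity for s in self.spectra]

    def subset(self, indices: Iterable[int]) -> "SpectrumSet":
        idx = list(indices)
        return SpectrumSet([self.spectra[i] for i in idx])

    def map_intensities(self, func) -> "SpectrumSet":
        return SpectrumSet([s.with_intensities(func(s)) for s in self.spectra])


def _read_xy_file(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column numeric text file; '#' lines are comments."""
    wn, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                wn.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    if len(wn) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    w = np.asarray(wn)
    y = np.asarray(inten)
    if w[0] > w[-1]:  # store ascending regardless of file order
        w, y = w[::-1], y[::-1]
    return w, y


def resample_to_grid(s: Spectrum, g: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid.

    Exact where grids coincide; raises if the target extends beyond the
    source range (no extrapolation).
    """
    if g == s.grid:
        return s
    src = s.grid.values
    if g.values[0] < src[0] or g.values[-1] > src[-1]:
        raise ValueError(
            f"target grid [{g.values[0]}, {g.values[-1]}] extends beyond source "
            f"range [{src[0]}, {src[-1]}]"
        )
    y = np.interp(g.values, src, s.intensities)
    return Spectrum(g, y, s.sample_id, s.measurement_index, s.entity)


def read_spectra(
    manifest_path: str | Path,
    base_dir: str | Path | None = None,
    grid: WavenumberGrid | None = None,
) -> SpectrumSet:
    """Read a manifest CSV (sample_id, entity, file) and all spectrum files.

    All spectra are resampled onto `grid`, or onto the grid of the first file
    when no grid is supplied.  Measurement indices count file order within
    each sample.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"sample_id", "entity", "file"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
        )
    spectra: list[Spectrum] = []
    counters: dict[str, int] = {}
    for _, row in df.iterrows():
        path = base / row["file"]
        if not path.exists():
            raise FileNotFoundError(f"spectrum file not found: {path}")
        w, y = _read_xy_file(path)
        sid = str(row["sample_id"])
        counters[sid] = counters.get(sid, 0) + 1
        s = Spectrum(
            WavenumberGrid(w), y, sid, counters[sid], parse_entity(row["entity"])
        )
        if grid is None:
            grid = s.grid
        spectra.append(resample_to_grid(s, grid))
    return SpectrumSet(spectra)


def write_spectra(
    sset: SpectrumSet, out_dir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write one file per spectrum plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sset:
        fname = f"{s.sample_id}_{s.measurement_index:03d}.txt"
        with open(out / fname, "w") as fh:
            fh.write("# wavenumber_cm1,intensity\n")
            for w, y in zip(s.grid.values, s.intensities):
                fh.write(f"{float(w)!r},{float(y)!r}\n")
        rows.append({"sample_id": s.sample_id, "entity": s.entity, "file": fname})
    mpath = out / manifest_name
    with open(mpath, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sample_id", "entity", "file"])
        writer.writeheader()
        writer.writerows(rows)
    return mpath


def crop_fingerprint(
    sset: SpectrumSet,
    low: float = FINGERPRINT_LOW,
    high: float = FINGERPRINT_HIGH,
) -> SpectrumSet:
    """Crop every spectrum to the fingerprint region [low, high], closed ends."""
    w = sset.grid.values
    mask = (w >= low) & (w <= high)
    if not mask.any():
        raise ValueError(
            f"grid [{w[0]}, {w[-1]}] has no overlap with crop range [{low}, {high}]"
        )
    if mask.sum() < 2:
        raise ValueError("fewer than 2 grid points remain after cropping")
    g = WavenumberGrid(w[mask])
    return SpectrumSet(
        [
            Spectrum(g, s.intensities[mask], s.sample_id, s.measurement_index, s.entity)
            for s in sset
        ]
    )


def write_mean_spectra_csv(
    means: Sequence, path: str | Path
) -> Path:
    """Export mean spectra as a wide CSV: wavenumber column + one column per group.

    Mirrors the usual deposited layout of group mean-spectrum tables.
    """
    path = Path(path)
    grid = means[0].grid.values
    data = {"wavenumber_cm1": grid}
    for m in means:
        data[f"{m.group_key}_mean"] = m.mean
        data[f"{m.group_key}_sd"] = m.sd
    pd.DataFrame(data).to_csv(path, index=False)
    return path
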