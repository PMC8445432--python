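"""Loading-based wavenumber band selection, biochemical annotation, and
PCA recalculation on selected spectral ranges.

The selection rule mirrors how chemometricians read loadings plots: grid
points where a component's loading exceeds +threshold or falls below
-threshold are the variables driving group separation; maximal runs of
contiguous selected points (same sign) become reported wavenumber ranges.
A built-in reference table maps such ranges to biochemical species
(nucleic acids, lipids, amides, phenylalanine, collagens, saccharides) and
to common contaminants (paraffin at 1126 cm^-1, formalin at 907 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .chemometrics import PCAModel, fit_pca_nipals
from .spectra_io import SpectrumSet


@dataclass(frozen=True)
class Band:
    """A wavenumber range [low, high] (cm^-1), optionally annotated.

    Singleton reference bands (low == high) are allowed; they mark a single
    peak position rather than a range.
    """

    low: float
    high: float
    assignment: str = ""
    pc: int | None = None   # 1-based PC that selected the band, if any
    sign: str | None = None  # '+' or '-' loading sign, if selected

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"band low {self.low} > high {self.high}")

    def overlaps(self, other: "Band") -> bool:
        return not (self.high < other.low or self.low > other.high)


class BandTable:
    """An ordered collection of bands with CSV round-trip."""

    def __init__(self, bands: Sequence[Band] = ()):
        self.bands = list(bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterator[Band]:
        return iter(self.bands)

    def __getitem__(self, i: int) -> Band:
        return self.bands[i]

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points covered by any band (closed ranges)."""
        w = np.asarray(wavenumbers, dtype=float)
        m = np.zeros(w.size, dtype=bool)
        for b in self.bands:
            m |= (w >= b.low) & (w <= b.high)
        return m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "range_low": b.low,
                    "range_high": b.high,
                    "sign": b.sign or "",
                    "pc": "" if b.pc is None else f"PC-{b.pc}",
                    "assignment": b.assignment,
                }
                for b in self.bands
            ]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "BandTable":
        df = pd.read_csv(path, dtype={"assignment": str})
        bands = []
        for _, row in df.iterrows():
            pc = None
            raw_pc = str(row.get("pc", row.get("source_pc", "")) or "")
            if raw_pc.startswith("PC-") and raw_pc[3:].isdigit():
                pc = int(raw_pc[3:])
            sign = str(row["sign"]) if "sign" in df.columns and pd.notna(row.get("sign")) else None
            bands.append(
                Band(
                    low=float(row["range_low"]),
                    high=float(row["range_high"]),
                    assignment="" if pd.isna(row.get("assignment")) else str(row["assignment"]),
                    pc=pc,
                    sign=sign or None,
                )
            )
        return cls(bands)


def default_reference_table() -> BandTable:
    """The built-in biochemical assignment table (discriminative ranges and
    entity-comparison bands of the fingerprint region)."""
    with resources.as_file(
        resources.files("ramanlda").joinpath("data/band_assignments.csv")
    ) as p:
        return BandTable.from_csv(p)


def select_bands(
    model: PCAModel,
    pcs: Sequence[int] = (2, 6),
    threshold: float = 0.1,
) -> BandTable:
    """Select wavenumber ranges where loadings exceed +/- threshold.

    For each listed (1-based) PC, grid points with loading > +threshold or
    < -threshold are selected; maximal runs of contiguous selected points of
    one sign become ranges, tagged with the PC and the loading sign.  Range
    endpoints are the wavenumbers of the outermost selected grid points.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if model.variable_wavenumbers is None:
        raise ValueError("model carries no variable wavenumbers; fit with them")
    w = np.asarray(model.variable_wavenumbers, dtype=float)
    bands: list[Band] = []
    for pc in pcs:
        if not 1 <= pc <= model.n_components:
            raise ValueError(f"PC-{pc} not fitted (model has {model.n_components})")
        loading = model.loadings[pc - 1]
        state = np.where(loading > threshold, 1, np.where(loading < -threshold, -1, 0))
        start = None
        for i in range(len(state) + 1):
            cur = state[i] if i < len(state) else 0
            prev = state[i - 1] if i > 0 else 0
            if cur != prev:
                if prev != 0 and start is not None:
                    bands.append(
                        Band(
                            low=float(w[start]),
                            high=float(w[i - 1]),
                            pc=pc,
                            sign="+" if prev > 0 else "-",
                        )
                    )
                start = i if cur != 0 else None
    return BandTable(bands)


def assign_bands(bands: BandTable, reference: BandTable) -> BandTable:
    """Annotate each band with every overlapping reference assignment.

    Overlap is on closed intervals; annotations are deduplicated and sorted,
    so the result does not depend on reference row order.  A band overlapping
    nothing is annotated "not defined".
    """
    if len(reference) == 0:
        raise ValueError("reference table is empty")
    out = []
    for b in bands:
        hits = sorted(
            {r.assignment for r in reference if r.assignment and b.overlaps(r)}
        )
        out.append(replace(b, assignment="; ".join(hits) if hits else "not defined"))
    return BandTable(out)


def recalc_pca_on_bands(
    sset: SpectrumSet, bands: BandTable, n_components: int = 7
) -> PCAModel:
    """Refit PCA on the variables inside the selected band ranges only."""
    w = sset.grid.values
    mask = bands.mask(w)
    if mask.sum() < 2:
        raise ValueError(
            f"bands select {int(mask.sum())} grid point(s); need at least 2"
        )
    X = sset.to_matrix()[:, mask]
    return fit_pca_nipals(
        X, n_components=min(n_components, min(X.shape)),
        variable_wavenumbers=w[mask],
    )
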