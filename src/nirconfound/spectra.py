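"""Spectral data model and the preprocessing chain.

A diffuse-reflectance NIR measurement of a tissue-engineered construct is a
vector of intensities on a fixed wavelength grid.  Each construct (sample)
carries up to three technical replicate spectra plus binary metadata flags for
the four non-neotissue constituents under study: the M-PER lysis buffer, the
HAV N-cadherin mimetic peptide conjugated to the scaffold, and the growth
factors BMP-9 and TGF-beta1.  All downstream analyses operate on
Savitzky-Golay first-derivative spectra.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SampleRecord",
    "Inventory",
    "PreprocessParams",
    "CONSTITUENTS",
    "default_grid",
    "sg_first_derivative",
    "average_replicates",
    "drop_zero_variance_channels",
    "impute_missing_replicates",
    "preprocess_inventory",
]

#: The four non-neotissue constituent flags, in canonical order.
CONSTITUENTS = ("mper", "hav", "bmp9", "tgfb1")

#: Span of the spectrometer used in the study design this package emulates.
GRID_MIN_NM = 943.8
GRID_MAX_NM = 2491.0
GRID_CHANNELS = 256


class SpectraError(ValueError):
    """Raised for malformed spectral data or metadata."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength grid in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise SpectraError("wavelength grid must be a 1-D array with >= 2 channels")
        if not np.all(np.diff(values) > 0):
            raise SpectraError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(self.values, other.values)


def default_grid(n_channels: int = GRID_CHANNELS) -> WavelengthGrid:
    """The 943.8-2491 nm grid of the reference instrument (256 channels)."""
    return WavelengthGrid(np.linspace(GRID_MIN_NM, GRID_MAX_NM, n_channels))


@dataclass(frozen=True)
class Spectrum:
    """One replicate measurement: intensities on a shared grid."""

    grid: WavelengthGrid
    intensities: np.ndarray
    replicate_index: int = 1

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        if intens.shape != (len(self.grid),):
            raise SpectraError(
                f"intensities length {intens.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(intens)):
            raise SpectraError("intensities must all be finite")
        if self.replicate_index < 1:
            raise SpectraError("replicate_index must be >= 1")
        object.__setattr__(self, "intensities", intens)


@dataclass
class SampleRecord:
    """A construct: metadata flags plus its technical replicate spectra.

    ``bmp9`` and ``tgfb1`` are mutually exclusive (media were supplemented
    with one growth factor or neither), and control samples carry no cells,
    growth factors or HAV conjugation.
    """

    sample_id: str
    day: int
    is_control: bool = False
    mper: bool = False
    hav: bool = False
    bmp9: bool = False
    tgfb1: bool = False
    replicates: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.day not in (7, 28):
            raise SpectraError(
                f"sample {self.sample_id!r}: day must be 7 or 28, got {self.day}"
            )
        if self.bmp9 and self.tgfb1:
            raise SpectraError(
                f"sample {self.sample_id!r}: BMP-9 and TGF-beta1 cannot co-occur"
            )
        if self.is_control and (self.hav or self.bmp9 or self.tgfb1):
            raise SpectraError(
                f"sample {self.sample_id!r}: controls carry no HAV or growth factors"
            )

    def flag(self, constituent: str) -> bool:
        if constituent not in CONSTITUENTS:
            raise SpectraError(f"unknown constituent {constituent!r}; expected one of {CONSTITUENTS}")
        return bool(getattr(self, constituent))


@dataclass
class Inventory:
    """The full sample roster, all spectra on one shared grid."""

    samples: list[SampleRecord]
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectraError(f"duplicate sample_ids: {dupes}")
        for s in self.samples:
            for spec in s.replicates:
                if spec.grid != self.grid:
                    raise SpectraError(
                        f"sample {s.sample_id!r}: replicate grid differs from inventory grid"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, sample_ids) -> "Inventory":
        wanted = set(sample_ids)
        return Inventory([s for s in self.samples if s.sample_id in wanted], self.grid)

    def n_spectra(self) -> int:
        return sum(len(s.replicates) for s in self.samples)


@dataclass(frozen=True)
class PreprocessParams:
    """Savitzky-Golay smoothing/derivative settings.

    Defaults follow the standard chemometrics choice for this assay:
    window of 13 channels, second-order polynomial, first derivative.
    The derivative is taken per channel index (the grid is treated as
    evenly indexed), not per nm.
    """

    window_length: int = 13
    poly_order: int = 2
    derivative_order: int = 1

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1 or self.window_length < 3:
            raise SpectraError("window_length must be an odd integer >= 3")
        if not (0 <= self.poly_order < self.window_length):
            raise SpectraError("poly_order must satisfy 0 <= poly_order < window_length")
        if not (0 <= self.derivative_order <= self.poly_order):
            raise SpectraError("derivative_order must satisfy 0 <= derivative_order <= poly_order")


def sg_first_derivative(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Savitzky-Golay smoothed derivative of a spectrum.

    Each output channel is the analytic derivative (of ``p.derivative_order``)
    of the least-squares polynomial of degree ``p.poly_order`` fitted to the
    ``p.window_length`` channels centred there.  Edge channels are obtained by
    evaluating the polynomial fitted to the first/last full window at the edge
    positions, so the output length equals the input length.
    """
    if len(s.grid) < p.window_length:
        raise SpectraError(
            f"spectrum has {len(s.grid)} channels, shorter than window {p.window_length}"
        )
    out = savgol_filter(
        s.intensities,
        window_length=p.window_length,
        polyorder=p.poly_order,
        deriv=p.derivative_order,
        delta=1.0,
        mode="interp",
    )
    return Spectrum(s.grid, out, s.replicate_index)


def average_replicates(r: SampleRecord) -> Spectrum:
    """Channel-wise arithmetic mean over a sample's available replicates."""
    if not r.replicates:
        raise SpectraError(f"sample {r.sample_id!r} has no replicates to average")
    stacked = np.stack([spec.intensities for spec in r.replicates])
    return Spectrum(r.replicates[0].grid, stacked.mean(axis=0), 1)


def drop_zero_variance_channels(inv: Inventory) -> tuple[Inventory, np.ndarray]:
    """Remove channels whose intensity is identical across every spectrum.

    Returns the reduced inventory and the surviving channel indices.
    Idempotent: a second application keeps everything.
    """
    mats = [spec.intensities for s in inv.samples for spec in s.replicates]
    if not mats:
        raise SpectraError("inventory contains no spectra")
    stacked = np.stack(mats)
    keep = ~np.all(stacked == stacked[0], axis=0)
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        raise SpectraError("degenerate dataset: every channel is constant")
    if kept_idx.size == len(inv.grid):
        return inv, kept_idx
    new_grid = WavelengthGrid(inv.grid.values[kept_idx])
    new_samples = []
    for s in inv.samples:
        reps = [
            Spectrum(new_grid, spec.intensities[kept_idx], spec.replicate_index)
            for spec in s.replicates
        ]
        new_samples.append(dataclasses.replace(s, replicates=reps))
    return Inventory(new_samples, new_grid), kept_idx


def impute_missing_replicates(inv: Inventory, target_count: int = 3) -> Inventory:
    """Bring every sample up to ``target_count`` replicates by simple replacement.

    Missing replicates are filled by duplicating the sample's first available
    replicate, mirroring the cleaning step applied before Monte Carlo
    cross-validation.
    """
    new_samples = []
    for s in inv.samples:
        if not s.replicates:
            raise SpectraError(f"sample {s.sample_id!r} has no replicates")
        reps = list(s.replicates)
        while len(reps) < target_count:
            first = reps[0]
            reps.append(Spectrum(first.grid, first.intensities, len(reps) + 1))
        new_samples.append(dataclasses.replace(s, replicates=reps))
    return Inventory(new_samples, inv.grid)


def preprocess_inventory(inv: Inventory, p: PreprocessParams = PreprocessParams()) -> Inventory:
    """Apply the Savitzky-Golay derivative to every replicate spectrum."""
    new_samples = []
    for s in inv.samples:
        reps = [sg_first_derivative(spec, p) for spec in s.replicates]
        new_samples.append(dataclasses.replace(s, replicates=reps))
    return Inventory(new_samples, inv.grid)
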