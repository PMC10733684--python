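"""Synthetic construct roster and NIR-like spectra.

The generator emulates the study design this package is built around:
69 test constructs (41 harvested at Day 7, 28 at Day 28) plus 12 cell-free
controls (6 per day), three technical replicates each with a couple of
replicates missing, measured on a 943.8-2491 nm / 256-channel grid.

Only the per-day one-way marginals of the four constituent flags are part of
the published design; the generator therefore takes explicit joint cell
counts over (growth factor x HAV x M-PER) per day, with a shipped default
allocation (largest-remainder proportional fitting) that reproduces every
marginal exactly.  Spectra are phenomenological: a smooth scaffold baseline,
a broad maturity shift for Day-28 cell-containing samples, a strong narrow
M-PER band near 1050 nm, subtle broadband signatures for HAV/BMP-9/TGF-beta1,
plus per-replicate baseline drift and channel noise.  No radiative-transfer
realism is attempted or needed: the point is controllable effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    Inventory,
    SampleRecord,
    SpectraError,
    Spectrum,
    WavelengthGrid,
    default_grid,
)

__all__ = [
    "EffectModel",
    "GeneratorConfig",
    "default_joint_counts",
    "generate_roster",
    "render_spectra",
    "generate_dataset",
    "TABLE1_MARGINALS",
]

GROWTH_FACTORS = ("none", "bmp9", "tgfb1")

#: Per-day design marginals of the study roster: total n, and counts of
#: samples carrying M-PER, HAV, BMP-9 and TGF-beta1.
TABLE1_MARGINALS = {
    7: {"n": 41, "mper": 11, "hav": 24, "bmp9": 22, "tgfb1": 14},
    28: {"n": 28, "mper": 10, "hav": 16, "bmp9": 12, "tgfb1": 7},
}


def _largest_remainder(total: int, weights: list[int]) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    wsum = sum(weights)
    if wsum == 0:
        if total:
            raise SpectraError("cannot apportion a positive total over empty cells")
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    alloc = [int(q) for q in quotas]
    remainders = sorted(
        range(len(weights)), key=lambda i: (-(quotas[i] - alloc[i]), i)
    )
    for i in remainders[: total - sum(alloc)]:
        alloc[i] += 1
    return alloc


def default_joint_counts(day: int) -> dict[tuple[str, bool, bool], int]:
    """A feasible joint (growth factor, HAV, M-PER) table for one day.

    HAV and M-PER totals are apportioned across the three growth-factor
    cells by largest remainder; within each cell the HAV-and-M-PER overlap is
    the rounded independence expectation, clipped to feasibility.  The
    resulting table reproduces every per-day marginal exactly.
    """
    m = TABLE1_MARGINALS[day]
    n_gf = [m["n"] - m["bmp9"] - m["tgfb1"], m["bmp9"], m["tgfb1"]]
    if min(n_gf) < 0:
        raise SpectraError(f"day {day}: growth-factor counts exceed total n")
    hav_by_gf = _largest_remainder(m["hav"], n_gf)
    mper_by_gf = _largest_remainder(m["mper"], n_gf)
    counts: dict[tuple[str, bool, bool], int] = {}
    for gf, n, h, p in zip(GROWTH_FACTORS, n_gf, hav_by_gf, mper_by_gf):
        lo, hi = max(0, h + p - n), min(h, p)
        both = min(hi, max(lo, round(h * p / n))) if n else 0
        counts[(gf, True, True)] = both
        counts[(gf, True, False)] = h - both
        counts[(gf, False, True)] = p - both
        counts[(gf, False, False)] = n - h - p + both
    return counts


def _validate_joint(day: int, counts: dict[tuple[str, bool, bool], int]) -> None:
    for key, c in counts.items():
        if c < 0:
            raise SpectraError(f"day {day}: negative cell count for {key}")


@dataclass
class GeneratorConfig:
    """Roster design: joint cell counts per day plus replicate settings."""

    day7_counts: dict[tuple[str, bool, bool], int] = field(
        default_factory=lambda: default_joint_counts(7)
    )
    day28_counts: dict[tuple[str, bool, bool], int] = field(
        default_factory=lambda: default_joint_counts(28)
    )
    n_controls_per_day: int = 6
    replicates: int = 3
    n_missing_replicates: int = 2
    n_channels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_joint(7, self.day7_counts)
        _validate_joint(28, self.day28_counts)
        if self.replicates < 1:
            raise SpectraError("replicates must be >= 1")
        if self.n_missing_replicates < 0:
            raise SpectraError("n_missing_replicates must be >= 0")


def _shape(grid_nm: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Gaussian-mixture shape normalised to unit maximum magnitude."""
    out = np.zeros_like(grid_nm)
    for center, width, weight in bands:
        out += weight * np.exp(-0.5 * ((grid_nm - center) / width) ** 2)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


@dataclass
class EffectModel:
    """Amplitudes and shapes of the spectral effects.

    All amplitudes are in raw reflectance units on a baseline of order 1.
    The M-PER signature is a single narrow band (1050 nm) at >= 5x the
    amplitude of the subtle broadband HAV/BMP-9/TGF-beta1 signatures; the
    maturity shift sits in between, so that constituent detection, maturity
    detection and confounding are all simultaneously realistic.
    """

    base_offset: float = 0.55
    base_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1450.0, 90.0, 0.18),
            (1940.0, 130.0, 0.30),
            (1150.0, 220.0, 0.10),
        ]
    )
    maturity_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1500.0, 120.0, 1.0),
            (2100.0, 150.0, 0.7),
            (1180.0, 100.0, -0.5),
        ]
    )
    maturity_amplitude: float = 0.03
    mper_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1050.0, 25.0, 1.0)]
    )
    mper_amplitude: float = 0.05
    hav_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1100.0, 200.0, 1.0),
            (1700.0, 250.0, -0.6),
            (2200.0, 250.0, 0.8),
        ]
    )
    hav_amplitude: float = 0.006
    bmp9_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1250.0, 220.0, 1.0),
            (1650.0, 300.0, -0.7),
            (2250.0, 200.0, 0.9),
        ]
    )
    bmp9_amplitude: float = 0.010
    tgfb1_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1050.0, 250.0, 0.8),
            (1550.0, 280.0, -1.0),
            (2100.0, 260.0, 0.6),
        ]
    )
    tgfb1_amplitude: float = 0.004
    replicate_noise_sd: float = 0.002
    channel_noise_sd: float = 0.004
    baseline_drift_sd: float = 0.003

    def __post_init__(self) -> None:
        for name in (
            "maturity_amplitude",
            "mper_amplitude",
            "hav_amplitude",
            "bmp9_amplitude",
            "tgfb1_amplitude",
            "replicate_noise_sd",
            "channel_noise_sd",
            "baseline_drift_sd",
        ):
            if getattr(self, name) < 0:
                raise SpectraError(f"{name} must be >= 0")

    def constituent_amplitude(self, constituent: str) -> float:
        return getattr(self, f"{constituent}_amplitude")

    def with_amplitudes(self, **amplitudes: float) -> "EffectModel":
        """Copy with selected ``<effect>_amplitude`` fields replaced."""
        import dataclasses

        return dataclasses.replace(
            self, **{f"{k}_amplitude": v for k, v in amplitudes.items()}
        )


def generate_roster(cfg: GeneratorConfig) -> Inventory:
    """Build the sample roster (metadata only; no spectra yet).

    Deterministic: samples are laid out cell by cell in a canonical order.
    With the default config the per-day marginal cross-tabs reproduce the
    study design exactly and 12 controls (6 per day) are appended.
    """
    grid = default_grid(cfg.n_channels)
    samples: list[SampleRecord] = []
    for day, counts in ((7, cfg.day7_counts), (28, cfg.day28_counts)):
        i = 0
        for gf in GROWTH_FACTORS:
            for hav in (True, False):
                for mper in (True, False):
                    for _ in range(counts.get((gf, hav, mper), 0)):
                        i += 1
                        samples.append(
                            SampleRecord(
                                sample_id=f"D{day:02d}-S{i:02d}",
                                day=day,
                                is_control=False,
                                mper=mper,
                                hav=hav,
                                bmp9=(gf == "bmp9"),
                                tgfb1=(gf == "tgfb1"),
                            )
                        )
    for day in (7, 28):
        for j in range(1, cfg.n_controls_per_day + 1):
            samples.append(
                SampleRecord(
                    sample_id=f"CTRL-D{day:02d}-{j:02d}",
                    day=day,
                    is_control=True,
                )
            )
    return Inventory(samples, grid)


def render_spectra(
    roster: Inventory,
    eff: EffectModel,
    seed: int,
    replicates: int = 3,
    n_missing_replicates: int = 2,
) -> Inventory:
    """Render replicate spectra for every sample in a roster.

    Each spectrum = scaffold baseline + maturity shift (Day-28, cell-containing
    samples only; controls keep the immature baseline) + active constituent
    signatures + smooth per-replicate baseline drift + iid channel noise.
    Exactly ``n_missing_replicates`` non-control samples (seeded draw) are
    left with one replicate fewer.  Deterministic given the seed.
    """
    grid_nm = roster.grid.values
    t = np.linspace(-1.0, 1.0, grid_nm.size)

    base = eff.base_offset + sum(
        w * np.exp(-0.5 * ((grid_nm - c) / s) ** 2) for c, s, w in eff.base_bands
    )
    maturity = eff.maturity_amplitude * _shape(grid_nm, eff.maturity_bands)
    signatures = {
        name: eff.constituent_amplitude(name) * _shape(grid_nm, getattr(eff, f"{name}_bands"))
        for name in ("mper", "hav", "bmp9", "tgfb1")
    }

    noise_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    missing_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))

    non_control_ids = [s.sample_id for s in roster.samples if not s.is_control]
    if n_missing_replicates > len(non_control_ids):
        raise SpectraError("more missing replicates requested than non-control samples")
    short_ids = set(
        missing_rng.choice(non_control_ids, size=n_missing_replicates, replace=False)
    ) if n_missing_replicates else set()

    import dataclasses

    out = []
    for s in roster.samples:
        clean = base.copy()
        if s.day == 28 and not s.is_control:
            clean = clean + maturity
        for name, sig in signatures.items():
            if getattr(s, name):
                clean = clean + sig
        n_reps = replicates - (1 if s.sample_id in short_ids else 0)
        reps = []
        for r in range(1, replicates + 1):
            # draw every replicate's noise so the roster position of a sample
            # never shifts another sample's stream, then keep the first n_reps
            offset = noise_rng.normal(0.0, eff.replicate_noise_sd)
            drift_coef = noise_rng.normal(0.0, eff.baseline_drift_sd, size=4)
            drift = drift_coef[0] + drift_coef[1] * t + drift_coef[2] * t**2 + drift_coef[3] * t**3
            noise = noise_rng.normal(0.0, eff.channel_noise_sd, size=grid_nm.size)
            if r <= n_reps:
                reps.append(Spectrum(roster.grid, clean + offset + drift + noise, r))
        out.append(dataclasses.replace(s, replicates=reps))
    return Inventory(out, roster.grid)


def generate_dataset(cfg: GeneratorConfig, eff: EffectModel | None = None) -> Inventory:
    """Roster + rendered spectra, deterministic given ``cfg.seed``."""
    if eff is None:
        eff = EffectModel()
    roster = generate_roster(cfg)
    return render_spectra(
        roster,
        eff,
        seed=cfg.seed,
        replicates=cfg.replicates,
        n_missing_replicates=cfg.n_missing_replicates,
    )
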