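"""CSV readers and writers for spectra and sample metadata.

Canonical dialect: a long-format spectra table with columns
``sample_id, replicate, wavelength_nm, intensity`` plus a metadata table with
one row per sample (``sample_id, day, is_control, mper, hav, bmp9, tgfb1``,
flags coded 0/1).  A wide spectra table (one column per wavelength, headers =
wavelengths in nm) is also accepted.  Wavelengths are written with one
decimal; intensities at full precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    CONSTITUENTS,
    Inventory,
    SampleRecord,
    SpectraError,
    Spectrum,
    WavelengthGrid,
)

__all__ = ["read_inventory", "write_inventory"]

_META_COLS = ["sample_id", "day", "is_control", "mper", "hav", "bmp9", "tgfb1"]
_LONG_COLS = ["sample_id", "replicate", "wavelength_nm", "intensity"]


def _read_metadata(metadata_table: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_table, dtype={"sample_id": str})
    missing = [c for c in _META_COLS if c not in meta.columns]
    if missing:
        raise SpectraError(f"metadata table {metadata_table}: missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SpectraError(f"metadata table: duplicated sample_ids {dupes}")
    return meta


def _spectra_long(spectra: pd.DataFrame) -> pd.DataFrame:
    """Normalise a spectra table to long format, detecting the dialect."""
    if set(_LONG_COLS).issubset(spectra.columns):
        return spectra[_LONG_COLS].copy()
    if {"sample_id", "replicate"}.issubset(spectra.columns):
        wl_cols = [c for c in spectra.columns if c not in ("sample_id", "replicate")]
        try:
            wavelengths = [float(c) for c in wl_cols]
        except ValueError as exc:
            raise SpectraError(
                "wide spectra table: non-numeric wavelength column headers"
            ) from exc
        long = spectra.melt(
            id_vars=["sample_id", "replicate"],
            value_vars=wl_cols,
            var_name="wavelength_nm",
            value_name="intensity",
        )
        long["wavelength_nm"] = long["wavelength_nm"].map(dict(zip(wl_cols, wavelengths)))
        return long
    raise SpectraError(
        f"spectra table: expected columns {_LONG_COLS} (long) or "
        "sample_id, replicate + wavelength headers (wide)"
    )


def read_inventory(spectra_table: str | Path, metadata_table: str | Path) -> Inventory:
    """Read and validate an :class:`~nirconfound.spectra.Inventory` from CSV.

    Raises :class:`~nirconfound.spectra.SpectraError` naming the offending
    sample/key on malformed input: missing columns, non-numeric intensities,
    duplicate (sample, replicate, wavelength) keys, spectra for unknown
    sample_ids, or metadata invariant violations.
    """
    meta = _read_metadata(metadata_table)
    spectra = pd.read_csv(spectra_table, dtype={"sample_id": str})
    long = _spectra_long(spectra)

    long["intensity"] = pd.to_numeric(long["intensity"], errors="coerce")
    if long["intensity"].isna().any():
        bad = long.loc[long["intensity"].isna()].iloc[0]
        raise SpectraError(
            f"non-numeric or missing intensity for sample {bad['sample_id']!r}, "
            f"replicate {bad['replicate']}, wavelength {bad['wavelength_nm']}"
        )
    long["wavelength_nm"] = pd.to_numeric(long["wavelength_nm"], errors="raise")

    dup = long.duplicated(subset=["sample_id", "replicate", "wavelength_nm"])
    if dup.any():
        bad = long.loc[dup].iloc[0]
        raise SpectraError(
            f"duplicated key (sample {bad['sample_id']!r}, replicate {bad['replicate']}, "
            f"wavelength {bad['wavelength_nm']})"
        )

    known = set(meta["sample_id"])
    unknown = sorted(set(long["sample_id"]) - known)
    if unknown:
        raise SpectraError(f"spectra rows reference unknown sample_ids: {unknown}")

    grid_values = np.sort(long["wavelength_nm"].unique())
    grid = WavelengthGrid(grid_values)

    samples: list[SampleRecord] = []
    by_sample = dict(tuple(long.groupby("sample_id", sort=False)))
    for row in meta.itertuples(index=False):
        sid = row.sample_id
        replicates: list[Spectrum] = []
        if sid in by_sample:
            for rep_idx, rep_df in sorted(by_sample[sid].groupby("replicate")):
                rep_df = rep_df.sort_values("wavelength_nm")
                if not np.array_equal(rep_df["wavelength_nm"].to_numpy(), grid.values):
                    raise SpectraError(
                        f"sample {sid!r} replicate {rep_idx}: wavelength grid "
                        "differs from the shared grid"
                    )
                replicates.append(
                    Spectrum(grid, rep_df["intensity"].to_numpy(), int(rep_idx))
                )
        samples.append(
            SampleRecord(
                sample_id=sid,
                day=int(row.day),
                is_control=bool(row.is_control),
                mper=bool(row.mper),
                hav=bool(row.hav),
                bmp9=bool(row.bmp9),
                tgfb1=bool(row.tgfb1),
                replicates=replicates,
            )
        )
    return Inventory(samples, grid)


def write_inventory(
    inv: Inventory, spectra_table: str | Path, metadata_table: str | Path
) -> None:
    """Write an inventory as the canonical long-format spectra + metadata CSVs."""
    rows = {
        "sample_id": [],
        "replicate": [],
        "wavelength_nm": [],
        "intensity": [],
    }
    wl = [f"{v:.1f}" for v in inv.grid.values]
    for s in inv.samples:
        for spec in s.replicates:
            rows["sample_id"].extend([s.sample_id] * len(inv.grid))
            rows["replicate"].extend([spec.replicate_index] * len(inv.grid))
            rows["wavelength_nm"].extend(wl)
            rows["intensity"].extend(np.asarray(spec.intensities).tolist())
    pd.DataFrame(rows).to_csv(spectra_table, index=False)

    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in inv.samples],
            "day": [s.day for s in inv.samples],
            "is_control": [int(s.is_control) for s in inv.samples],
            **{
                c: [int(getattr(s, c)) for s in inv.samples]
                for c in CONSTITUENTS
            },
        }
    )
    meta.to_csv(metadata_table, index=False)
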