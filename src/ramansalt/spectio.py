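"""Containers and plain-text I/O for Raman spectra.

A :class:`Spectrum` is a single measurement (shift axis in cm^-1 plus
intensities in arbitrary units); a :class:`SpectrumSet` is a stack of spectra
sharing one bitwise-identical shift axis, with an optional per-spectrum
metadata table (week, NaCl concentration of the growth medium in mM,
replicate, scan coordinates).

Two plain-text dialects are supported:

* ``wide``  — column 1 is ``shift_cm-1``; every further column is one spectrum,
  its header the spectrum id.
* ``long``  — columns ``spectrum_id``, ``shift_cm-1``, ``intensity``.

Metadata lives in a sidecar CSV (``spectrum_id``, ``week``,
``concentration_mM``, optional ``replicate``, ``x_um``, ``y_um``), keeping the
spectral matrix purely numeric.  Shift-axis equality across spectra is
required exactly; resampling (:func:`ramansalt.preprocess.resample_to_grid`)
is the only sanctioned way to merge mismatched axes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    AxisError,
    FormatError,
    MetadataError,
    ValidationError,
)

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_metadata",
    "attach_metadata",
]

SHIFT_COLUMN = "shift_cm-1"
META_REQUIRED = ("spectrum_id", "week", "concentration_mM")
META_OPTIONAL = ("replicate", "x_um", "y_um")


def _validate_axis(shift: np.ndarray) -> None:
    if shift.ndim != 1 or shift.size < 2:
        raise AxisError(f"shift axis must be 1-D with >= 2 points, got shape {shift.shape}")
    if not np.all(np.isfinite(shift)):
        raise AxisError("shift axis contains non-finite values")
    if not np.all(np.diff(shift) > 0):
        raise AxisError("shift axis must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """One Raman measurement: strictly increasing shift axis + intensities."""

    shift: np.ndarray
    intensity: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        _validate_axis(self.shift)
        if self.intensity.shape != self.shift.shape:
            raise ValidationError(
                f"intensity length {self.intensity.shape} != shift length {self.shift.shape}"
            )

    @property
    def n_points(self) -> int:
        return self.shift.size

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class SpectrumSet:
    """Aligned spectra (n_spectra x n_points) with optional sample metadata.

    ``meta``, when present, is indexed positionally in the same order as the
    intensity rows and always carries a ``spectrum_id`` column equal to
    ``ids``.
    """

    shift: np.ndarray
    intensities: np.ndarray
    ids: tuple[str, ...]
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=float))
        object.__setattr__(self, "intensities", np.atleast_2d(np.asarray(self.intensities, dtype=float)))
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        _validate_axis(self.shift)
        n, p = self.intensities.shape if self.intensities.size else (len(self.ids), self.shift.size)
        if self.intensities.size == 0:
            object.__setattr__(
                self, "intensities", np.empty((len(self.ids), self.shift.size), dtype=float)
            )
            n, p = self.intensities.shape
        if p != self.shift.size:
            raise AlignmentError(f"intensity row length {p} != axis length {self.shift.size}")
        if n != len(self.ids):
            raise ValidationError(f"{n} intensity rows but {len(self.ids)} ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("spectrum ids must be unique")
        if self.meta is not None:
            if len(self.meta) != n:
                raise MetadataError(f"{len(self.meta)} metadata rows for {n} spectra")
            if list(self.meta["spectrum_id"]) != list(self.ids):
                raise MetadataError("metadata spectrum_id order does not match spectra")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_spectra(self) -> int:
        return len(self.ids)

    @property
    def n_points(self) -> int:
        return self.shift.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.shift, self.intensities[i], self.ids[i])

    def __iter__(self):
        return (self.spectrum(i) for i in range(len(self)))

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return replace(self, intensities=intensities)

    def subset(self, indices: np.ndarray) -> "SpectrumSet":
        """Row-subset by integer indices, carrying metadata along."""
        indices = np.asarray(indices, dtype=int)
        meta = None
        if self.meta is not None:
            meta = self.meta.iloc[indices].reset_index(drop=True)
        return SpectrumSet(
            self.shift,
            self.intensities[indices],
            tuple(self.ids[i] for i in indices),
            meta,
        )


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_spectrum_table(path: str | Path, dialect: str = "wide") -> SpectrumSet:
    """Read a plain-text spectral table (TSV/CSV, delimiter sniffed).

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"wide"`` or ``"long"`` (see module docstring).
    """
    path = Path(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing values in table")

    if dialect == "wide":
        if df.shape[1] < 1 or df.columns[0] != SHIFT_COLUMN:
            raise FormatError(f"{path}: wide table must start with a {SHIFT_COLUMN!r} column")
        shift = df.iloc[:, 0].to_numpy(dtype=float)
        _validate_axis(shift)
        ids = tuple(str(c) for c in df.columns[1:])
        intensities = df.iloc[:, 1:].to_numpy(dtype=float).T
        if len(ids) == 0:
            intensities = np.empty((0, shift.size))
        return SpectrumSet(shift, intensities, ids)

    needed = {"spectrum_id", SHIFT_COLUMN, "intensity"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: long table needs columns {sorted(needed)}")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    shift_ref: np.ndarray | None = None
    for sid, grp in df.groupby("spectrum_id", sort=False):
        shift = grp[SHIFT_COLUMN].to_numpy(dtype=float)
        _validate_axis(shift)
        if shift_ref is None:
            shift_ref = shift
        elif shift.size != shift_ref.size or not np.array_equal(shift, shift_ref):
            raise AlignmentError(
                f"{path}: spectrum {sid!r} uses a shift grid different from the first spectrum"
            )
        ids.append(str(sid))
        rows.append(grp["intensity"].to_numpy(dtype=float))
    if shift_ref is None:
        raise FormatError(f"{path}: long table holds no spectra")
    return SpectrumSet(shift_ref, np.vstack(rows), tuple(ids))


def write_spectrum_table(sset: SpectrumSet, path: str | Path, dialect: str = "wide") -> None:
    """Write a SpectrumSet as tab-separated text, round-trippable to full float precision."""
    path = Path(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sset.n_spectra and not np.all(np.isfinite(sset.intensities)):
        raise ValidationError("refusing to write non-finite intensities")
    if dialect == "wide":
        data = {SHIFT_COLUMN: sset.shift}
        for i, sid in enumerate(sset.ids):
            data[sid] = sset.intensities[i]
        df = pd.DataFrame(data)
    else:
        frames = [
            pd.DataFrame(
                {"spectrum_id": sid, SHIFT_COLUMN: sset.shift, "intensity": sset.intensities[i]}
            )
            for i, sid in enumerate(sset.ids)
        ]
        if not frames:
            df = pd.DataFrame(columns=["spectrum_id", SHIFT_COLUMN, "intensity"])
        else:
            df = pd.concat(frames, ignore_index=True)
    # 17 significant digits guarantee exact float64 round trips
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metadata(meta_path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata CSV."""
    meta_path = Path(meta_path)
    sep = _sniff_delimiter(meta_path)
    meta = pd.read_csv(meta_path, sep=sep)
    missing_cols = [c for c in META_REQUIRED if c not in meta.columns]
    if missing_cols:
        raise MetadataError(f"{meta_path}: missing metadata columns {missing_cols}")
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)
    if (meta["concentration_mM"] < 0).any():
        raise MetadataError("concentration_mM must be non-negative")
    if (meta["week"] < 0).any():
        raise MetadataError("week must be non-negative")
    dup = meta["spectrum_id"][meta["spectrum_id"].duplicated()]
    if len(dup):
        raise MetadataError(f"duplicate spectrum_id rows in metadata: {sorted(set(dup))}")
    return meta


def attach_metadata(sset: SpectrumSet, meta_path: str | Path) -> SpectrumSet:
    """Attach a sidecar metadata table; every spectrum must match exactly one row."""
    meta = read_metadata(meta_path)
    indexed = meta.set_index("spectrum_id")
    missing = [sid for sid in sset.ids if sid not in indexed.index]
    if missing:
        raise MetadataError(f"metadata rows missing for spectra: {missing}")
    ordered = indexed.loc[list(sset.ids)].reset_index()
    return replace(sset, meta=ordered)
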