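"""CSV reading and writing for spectrum collections.

Two spectral layouts are supported, both UTF-8, comma-separated, '.' decimal,
with a mandatory header row:

* wide  -- first column holds the axis values, every further column one
  spectrum, header cells are sample_ids;
* long  -- three columns ``sample_id, axis, intensity``.

Per-spectrum metadata travels in a companion CSV keyed by sample_id with
columns ``sample_id, excitation_nm, power_mw, acquisition_order,
genus_label, habit_label`` (difference spectra add ``k, lambda_1_nm,
lambda_2_nm, normalized``).  sample_ids are unique per spectrum; when a
particle was measured at several excitations the convention
``<particle>#<excitation>`` keeps the ids distinct while preserving the
grouping (see :func:`serdskit.serds.pair_spectra`).

Values are serialized with 17 significant digits, so read(write(x)) is the
identity for doubles.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .spectra import CalibratedSpectrum, DifferenceSpectrum, SpectrumCollection

__all__ = ["SpectraParseError", "read_spectra", "write_spectra", "default_metadata_path"]

_FLOAT_FMT = "%.17g"
_META_COLUMNS = [
    "sample_id",
    "kind",
    "excitation_nm",
    "power_mw",
    "acquisition_order",
    "genus_label",
    "habit_label",
    "k",
    "lambda_1_nm",
    "lambda_2_nm",
    "normalized",
]


class SpectraParseError(ValueError):
    """Malformed spectra or metadata file; the message names the offending record."""


def default_metadata_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.csv")


def _fmt(x) -> str:
    return _FLOAT_FMT % float(x)


def _meta_row(s) -> dict:
    row = {
        "sample_id": s.sample_id,
        "genus_label": "" if s.genus_label is None else s.genus_label,
        "habit_label": "" if s.habit_label is None else s.habit_label,
    }
    if isinstance(s, DifferenceSpectrum):
        row.update(
            kind="difference",
            excitation_nm="",
            power_mw="",
            acquisition_order="",
            k=_fmt(s.k),
            lambda_1_nm=_fmt(s.lambda_pair_nm[0]),
            lambda_2_nm=_fmt(s.lambda_pair_nm[1]),
            normalized=str(bool(s.normalized)),
        )
    else:
        row.update(
            kind="calibrated",
            excitation_nm=_fmt(s.excitation_nm),
            power_mw=_fmt(s.power_mw),
            acquisition_order=str(int(s.acquisition_order)),
            k="",
            lambda_1_nm="",
            lambda_2_nm="",
            normalized="",
        )
    return row


def write_spectra(collection: SpectrumCollection, path, fmt: str = "wide",
                  metadata_path=None) -> None:
    """Serialize a collection as wide or long CSV plus a metadata CSV."""
    if fmt not in ("wide", "long"):
        raise ValueError(f"unknown format {fmt!r}; expected 'wide' or 'long'")
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    ids = collection.labels("sample_id")
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique within a collection")
    path = Path(path)
    metadata_path = default_metadata_path(path) if metadata_path is None else Path(metadata_path)

    axis = collection.axis
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if fmt == "wide":
            writer.writerow(["axis"] + ids)
            mat = collection.matrix()
            for j in range(axis.size):
                writer.writerow([_fmt(axis[j])] + [_fmt(v) for v in mat[:, j]])
        else:
            writer.writerow(["sample_id", "axis", "intensity"])
            for s in collection:
                for x, y in zip(s.axis, s.values):
                    writer.writerow([s.sample_id, _fmt(x), _fmt(y)])

    with open(metadata_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_META_COLUMNS)
        writer.writeheader()
        for s in collection:
            writer.writerow(_meta_row(s))


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise SpectraParseError(f"{path}: malformed CSV ({exc})") from exc


def _check_axis(axis: np.ndarray, path, sample_id: Optional[str] = None) -> None:
    label = f"{path}" if sample_id is None else f"{path} (sample_id {sample_id!r})"
    if np.any(~np.isfinite(axis)):
        raise SpectraParseError(f"{label}: non-numeric axis value")
    if np.any(np.diff(axis) <= 0):
        bad = int(np.flatnonzero(np.diff(axis) <= 0)[0]) + 1
        raise SpectraParseError(f"{label}: axis not strictly increasing at row {bad}")


def _opt(value: str) -> Optional[str]:
    return None if value == "" else value


def _build_spectrum(meta: dict, axis: np.ndarray, values: np.ndarray, path):
    sid = meta["sample_id"]
    kind = meta.get("kind", "calibrated") or "calibrated"
    try:
        if kind == "difference":
            return DifferenceSpectrum(
                wavenumber_cm1=axis,
                value=values,
                k=float(meta["k"]),
                lambda_pair_nm=(float(meta["lambda_1_nm"]), float(meta["lambda_2_nm"])),
                normalized=meta["normalized"] == "True",
                sample_id=sid,
                genus_label=_opt(meta.get("genus_label", "")),
                habit_label=_opt(meta.get("habit_label", "")),
            )
        if kind == "calibrated":
            return CalibratedSpectrum(
                wavenumber_cm1=axis,
                intensity=values,
                excitation_nm=float(meta["excitation_nm"]),
                power_mw=float(meta["power_mw"]),
                acquisition_order=int(meta["acquisition_order"]),
                sample_id=sid,
                genus_label=_opt(meta.get("genus_label", "")),
                habit_label=_opt(meta.get("habit_label", "")),
            )
    except (KeyError, ValueError) as exc:
        raise SpectraParseError(f"{path}: bad metadata for sample_id {sid!r}: {exc}") from exc
    raise SpectraParseError(f"{path}: unknown spectrum kind {kind!r} for sample_id {sid!r}")


def read_spectra(path, fmt: str = "wide", metadata_path=None) -> SpectrumCollection:
    """Read a wide or long CSV plus its metadata CSV into a collection.

    Spectra are returned in metadata-file order; every sample_id in the
    metadata must appear in the spectral file and vice versa.
    """
    if fmt not in ("wide", "long"):
        raise ValueError(f"unknown format {fmt!r}; expected 'wide' or 'long'")
    path = Path(path)
    metadata_path = default_metadata_path(path) if metadata_path is None else Path(metadata_path)

    meta = _read_table(metadata_path)
    if "sample_id" not in meta.columns:
        raise SpectraParseError(f"{metadata_path}: missing sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise SpectraParseError(f"{metadata_path}: duplicated sample_id {dup!r}")

    table = _read_table(path)
    if fmt == "wide":
        if table.shape[1] < 2:
            raise SpectraParseError(f"{path}: wide CSV needs an axis column plus spectra")
        try:
            data = table.astype(float)
        except ValueError as exc:
            raise SpectraParseError(f"{path}: non-numeric value ({exc})") from exc
        axis = data.iloc[:, 0].to_numpy()
        _check_axis(axis, path)
        per_id = {col: data[col].to_numpy() for col in table.columns[1:]}
    else:
        expected = {"sample_id", "axis", "intensity"}
        if not expected.issubset(table.columns):
            raise SpectraParseError(f"{path}: long CSV needs columns {sorted(expected)}")
        per_id = {}
        axis = None
        for sid, grp in table.groupby("sample_id", sort=False):
            try:
                ax = grp["axis"].astype(float).to_numpy()
                vals = grp["intensity"].astype(float).to_numpy()
            except ValueError as exc:
                raise SpectraParseError(f"{path}: non-numeric value for sample_id {sid!r}") from exc
            _check_axis(ax, path, sid)
            if axis is None:
                axis = ax
            elif ax.shape != axis.shape or not np.array_equal(ax, axis):
                raise SpectraParseError(f"{path}: sample_id {sid!r} not on the common axis")
            per_id[sid] = vals
        if axis is None:
            raise SpectraParseError(f"{path}: empty long CSV")

    meta_ids = list(meta["sample_id"])
    unknown = [sid for sid in meta_ids if sid not in per_id]
    if unknown:
        raise SpectraParseError(f"{metadata_path}: unknown sample_id {unknown[0]!r} (no spectrum)")
    orphan = [sid for sid in per_id if sid not in set(meta_ids)]
    if orphan:
        raise SpectraParseError(f"{path}: spectrum {orphan[0]!r} has no metadata row")

    spectra = []
    for _, row in meta.iterrows():
        values = per_id[row["sample_id"]]
        if np.any(~np.isfinite(values)):
            raise SpectraParseError(f"{path}: non-finite intensity for sample_id {row['sample_id']!r}")
        spectra.append(_build_spectrum(dict(row), axis.copy(), values, metadata_path))
    return SpectrumCollection(spectra)
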