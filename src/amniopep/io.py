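"""Delimited-file I/O for the peptidome triple (catalog, samples, matrix).

Two matrix layouts are supported:

* ``wide`` — rows are peptides, the first column is ``catalog_id``, remaining
  columns are sample IDs. Empty cells mean "not detected" and are read as 0.
* ``long`` — columns ``sample_id``, ``catalog_id``, ``abundance``; absent
  (sample, peptide) rows are materialized as 0.

The delimiter is sniffed from the extension: ``.tsv``/``.tab``/``.txt`` are
tab-separated, everything else comma-separated. Files are UTF-8 with '.' as
the decimal separator.

:func:`read_peptidome` / :func:`write_peptidome` exchange a whole cohort as a
directory of three files: ``catalog.csv``, ``samples.csv`` and
``abundance.csv`` (or ``.tsv``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CATALOG_COLUMNS,
    SAMPLE_COLUMNS,
    Peptidome,
    check_sample_totals,
    make_catalog,
    validate_matrix,
    validate_samples,
)
from .errors import DataError, FormatError

_TAB_EXT = {".tsv", ".tab", ".txt"}

LONG_COLUMNS = ("sample_id", "catalog_id", "abundance")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in _TAB_EXT else ","


def _require_columns(df: pd.DataFrame, required, path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def read_matrix(path: str | Path, layout: str = "wide") -> pd.DataFrame:
    """Read an abundance matrix (samples x peptides) from a delimited file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _sep_for(path)
    if layout == "wide":
        raw = pd.read_csv(path, sep=sep, dtype={0: str})
        if raw.shape[1] < 2:
            raise FormatError(f"{path}: wide layout needs a catalog_id column plus samples")
        id_col = raw.columns[0]
        if raw[id_col].duplicated().any():
            raise DataError(f"{path}: duplicate peptide rows in wide matrix")
        mat = raw.set_index(id_col)
        mat.index = mat.index.astype(str)
        mat.index.name = "catalog_id"
        mat = _coerce_numeric(mat, path).T
        mat.index.name = "sample_id"
        return mat
    if layout == "long":
        raw = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "catalog_id": str})
        _require_columns(raw, LONG_COLUMNS, path)
        ab = pd.to_numeric(raw["abundance"], errors="coerce")
        bad = raw.index[ab.isna() & raw["abundance"].notna()]
        if len(bad):
            raise DataError(f"{path}: non-numeric abundance at row(s) {list(bad[:5])}")
        raw = raw.assign(abundance=ab.fillna(0.0))
        dup = raw.duplicated(subset=["sample_id", "catalog_id"], keep=False)
        if dup.any():
            conflicting = (
                raw[dup]
                .groupby(["sample_id", "catalog_id"])["abundance"]
                .nunique()
                .pipe(lambda s: s[s > 1])
            )
            if len(conflicting):
                raise DataError(
                    f"{path}: conflicting duplicate cells for "
                    f"{conflicting.index.tolist()[:5]}"
                )
            raw = raw.drop_duplicates(subset=["sample_id", "catalog_id"])
        mat = raw.pivot(index="sample_id", columns="catalog_id", values="abundance")
        mat = mat.fillna(0.0)
        mat.columns.name = None
        return mat
    raise FormatError(f"unknown layout '{layout}' (expected 'wide' or 'long')")


def _coerce_numeric(mat: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = mat.apply(pd.to_numeric, errors="coerce")
    introduced = out.isna() & mat.notna()
    if introduced.any().any():
        row = int(np.argmax(introduced.any(axis=1).to_numpy()))
        raise DataError(f"{path}: non-numeric abundance at data row {row}")
    return out.fillna(0.0)


def write_matrix(path: str | Path, matrix: pd.DataFrame, layout: str = "wide") -> None:
    path = Path(path)
    sep = _sep_for(path)
    if layout == "wide":
        wide = matrix.T
        wide.index.name = "catalog_id"
        wide.to_csv(path, sep=sep)
    elif layout == "long":
        long = matrix.stack().rename("abundance").reset_index()
        long.columns = list(LONG_COLUMNS)
        long = long[long["abundance"] != 0]
        long.to_csv(path, sep=sep, index=False)
    else:
        raise FormatError(f"unknown layout '{layout}'")


def read_catalog(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype={"catalog_id": str})
    _require_columns(raw, ("catalog_id", "mass_da"), path)
    return make_catalog(raw)


def write_catalog(path: str | Path, catalog: pd.DataFrame) -> None:
    path = Path(path)
    catalog.loc[:, list(CATALOG_COLUMNS)].to_csv(path, sep=_sep_for(path), index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "patient_id": str})
    _require_columns(raw, ("sample_id", "fluid", "gestational_age_wa"), path)
    for col in SAMPLE_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    out = raw.loc[:, list(SAMPLE_COLUMNS)]
    validate_samples(out)
    return out


def write_samples(path: str | Path, samples: pd.DataFrame) -> None:
    path = Path(path)
    samples.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, sep=_sep_for(path), index=False)


def read_peptidome(path: str | Path, layout: str = "wide") -> Peptidome:
    """Read a cohort directory (catalog/samples/abundance) into a triple.

    ``path`` is a directory containing ``catalog``, ``samples`` and
    ``abundance`` files with a ``.csv`` or ``.tsv`` extension.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"no such cohort directory: {path}")

    def find(stem: str) -> Path:
        for ext in (".csv", ".tsv"):
            cand = path / f"{stem}{ext}"
            if cand.exists():
                return cand
        raise FormatError(f"{path}: missing {stem}.csv/.tsv")

    catalog = read_catalog(find("catalog"))
    samples = read_samples(find("samples"))
    matrix = read_matrix(find("abundance"), layout=layout)
    validate_matrix(matrix, samples, catalog)
    check_sample_totals(matrix)
    return Peptidome(catalog=catalog, samples=samples, matrix=matrix)


def write_peptidome(
    path: str | Path,
    peptidome: Peptidome,
    layout: str = "wide",
    delimiter: str = "csv",
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ext = f".{delimiter}"
    write_catalog(path / f"catalog{ext}", peptidome.catalog)
    write_samples(path / f"samples{ext}", peptidome.samples)
    write_matrix(path / f"abundance{ext}", peptidome.matrix, layout=layout)
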