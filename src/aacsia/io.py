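"""Reading and writing long-format sample tables.

The canonical on-disk format is a delimited text table with one row per
sample x amino acid x isotope system:

    sample_id, amino_acid, isotope, value, sd, n_reps,
    distance_km, tow_depth_m, habitat, season, year, size_fraction

Only the first four columns are required; metadata columns may be absent
or empty. A column-mapping "dialect" (a YAML file or a dict mapping
canonical names to the file's actual column names) adapts foreign
headers. Values are per-mil, distances km, depths m.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import AMINO_ACIDS, ISOTOPES, Dataset, SampleRecord
from .exceptions import RowParseError, SchemaError

REQUIRED_COLUMNS = ("sample_id", "amino_acid", "isotope", "value")
OPTIONAL_COLUMNS = ("sd", "n_reps", "distance_km", "tow_depth_m",
                    "habitat", "season", "year", "size_fraction")
_METADATA_FIELDS = ("distance_km", "tow_depth_m", "habitat", "season",
                    "year", "size_fraction")


def load_dialect(path) -> dict[str, str]:
    """Load a canonical-name -> file-column-name mapping from YAML."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError(f"dialect file {path} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_sample_table(path, dialect: dict[str, str] | str | Path | None = None,
                      sep: str | None = None) -> Dataset:
    """Read a long-format delimited table into a validated :class:`Dataset`.

    Parameters
    ----------
    path : path-like
        CSV or TSV file with a header row.
    dialect : dict or path, optional
        Mapping from canonical column names to the file's column names,
        either as a dict or a YAML file path.
    sep : str, optional
        Field delimiter; inferred from the extension by default
        (``.tsv`` -> tab, otherwise comma).

    Raises
    ------
    SchemaError
        Missing required column, unknown amino-acid code, duplicate
        (sample, amino acid, isotope) key, or empty file.
    RowParseError
        Unparseable numeric field, reported with its row index.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(dialect, (str, Path)):
        dialect = load_dialect(dialect)

    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, comment="#",
                            skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")

    records: dict[str, SampleRecord] = {}
    for idx, row in frame.iterrows():
        sid = _req_str(row, "sample_id", idx)
        aa = _req_str(row, "amino_acid", idx)
        iso = _req_str(row, "isotope", idx)
        if aa not in AMINO_ACIDS:
            raise SchemaError(f"row {idx}: unknown amino-acid code {aa!r}")
        if iso not in ISOTOPES:
            raise SchemaError(f"row {idx}: unknown isotope system {iso!r}")
        value = _num(row, "value", idx, required=True)
        sd = _num(row, "sd", idx) or 0.0
        n_reps_f = _num(row, "n_reps", idx)
        n_reps = int(n_reps_f) if n_reps_f is not None else 1

        if sid not in records:
            records[sid] = SampleRecord(
                sample_id=sid,
                distance_km=_num(row, "distance_km", idx),
                tow_depth_m=_num(row, "tow_depth_m", idx),
                habitat=_opt_str(row, "habitat"),
                season=_opt_str(row, "season"),
                year=_opt_int(row, "year", idx),
                size_fraction=_opt_str(row, "size_fraction"),
            )
        rec = records[sid]
        if rec.has(aa, iso):
            raise SchemaError(
                f"row {idx}: duplicate measurement ({sid}, {aa}, {iso})"
            )
        rec.set(aa, iso, value, sd=sd, n_reps=n_reps)

    return Dataset(records=list(records.values()))


def write_sample_table(dataset: Dataset, path, sep: str | None = None) -> None:
    """Write a dataset back to the canonical long format.

    Round-trip contract: ``read_sample_table(write_sample_table(d))``
    reproduces ``d`` exactly (floats are written with ``repr``
    precision). Records with no measurements are invalid and rejected.
    """
    dataset.require_nonempty("write_sample_table")
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for rec in dataset.records:
        if not rec.measurements:
            raise SchemaError(
                f"sample {rec.sample_id!r} has no measurements; dataset invalid"
            )
        for (aa, iso), m in rec.measurements.items():
            rows.append({
                "sample_id": rec.sample_id,
                "amino_acid": aa,
                "isotope": iso,
                "value": _fmt(m.value),
                "sd": _fmt(m.sd),
                "n_reps": m.n_reps,
                "distance_km": _fmt(rec.distance_km),
                "tow_depth_m": _fmt(rec.tow_depth_m),
                "habitat": rec.habitat or "",
                "season": rec.season or "",
                "year": rec.year if rec.year is not None else "",
                "size_fraction": rec.size_fraction or "",
            })
    frame = pd.DataFrame(rows, columns=REQUIRED_COLUMNS[:3] + ("value",) + OPTIONAL_COLUMNS)
    frame.to_csv(path, sep=sep, index=False)


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _req_str(row, col, idx) -> str:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        raise RowParseError(idx, f"missing value in column {col!r}")
    return str(v).strip()


def _opt_str(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        return None
    return str(v).strip()


def _num(row, col, idx, required: bool = False):
    v = _opt_str(row, col)
    if v is None:
        if required:
            raise RowParseError(idx, f"missing numeric value in column {col!r}")
        return None
    try:
        return float(v)
    except ValueError:
        raise RowParseError(idx, f"unparseable numeric {v!r} in column {col!r}") from None


def _opt_int(row, col, idx):
    v = _num(row, col, idx)
    return int(v) if v is not None else None
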