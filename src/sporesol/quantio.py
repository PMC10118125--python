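"""Tabular I/O with strict schema validation.

All pipeline inputs are delimited text (comma or tab) with a header row.
Canonical in-memory representation is a :class:`pandas.DataFrame` with
fixed column names; readers validate and normalize, writers emit plain
CSV plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

#: canonical column order of a fraction-quant table
FRACTION_COLUMNS = (
    "protein_id",
    "time_point",
    "replicate",
    "fraction",
    "abundance",
    "n_peptides",
    "coverage",
)

#: canonical column order of a phosphopeptide table
PHOSPHO_COLUMNS = ("protein_id", "site_label", "time_point", "replicate", "intensity")

_FRACTION_ALIASES = {
    "supernatant": "supernatant",
    "sup": "supernatant",
    "s": "supernatant",
    "pellet": "pellet",
    "p": "pellet",
}


def _sniff_delimiter(path: Path) -> str:
    """Pick tab or comma based on the header line."""
    header = path.open("r", encoding="utf-8").readline()
    if header.count("\t") > header.count(","):
        return "\t"
    return ","


def _read_delimited(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _to_numeric(df: pd.DataFrame, column: str, allow_missing: bool = False) -> pd.Series:
    """Parse a string column to float; report row indices that fail."""
    raw = df[column].str.strip()
    missing = raw == ""
    values = pd.to_numeric(raw.mask(missing), errors="coerce")
    bad = values.isna() & ~missing
    if bad.any():
        rows = [int(i) for i in df.index[bad][:20]]
        raise ValidationError(
            f"column {column!r}: unparseable numeric value(s) at row(s) {rows}"
        )
    if missing.any() and not allow_missing:
        rows = [int(i) for i in df.index[missing][:20]]
        raise ValidationError(f"column {column!r}: missing value(s) at row(s) {rows}")
    return values.astype(float)


def normalize_fraction(value: str) -> str:
    """Map a free-form fraction label onto ``supernatant``/``pellet``."""
    key = value.strip().lower()
    if key not in _FRACTION_ALIASES:
        raise ValidationError(f"unrecognized fraction label {value!r}")
    return _FRACTION_ALIASES[key]


def read_fraction_quant(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    time_order: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a per-protein fractionation quant table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Mapping from canonical names (``protein_id``, ``time_point``,
        ``replicate``, ``fraction``, ``abundance``, ``n_peptides``,
        ``coverage``) to the column names used in the file.  Identity
        mapping by default.
    time_order
        Optional explicit ordering of time-point labels; when given the
        ``time_point`` column becomes an ordered categorical.
    delimiter
        Tab or comma; auto-detected when omitted.

    Returns
    -------
    pandas.DataFrame
        Canonical long-form table.  Missing abundance cells are NaN,
        deliberately distinct from 0.
    """
    schema = dict(schema or {})
    mapping = {name: schema.get(name, name) for name in FRACTION_COLUMNS}
    raw = _read_delimited(path, delimiter)
    missing_cols = [src for src in mapping.values() if src not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mapped column(s): {missing_cols}")

    df = pd.DataFrame(
        {canon: raw[src] for canon, src in mapping.items()}
    )
    df["protein_id"] = df["protein_id"].str.strip()
    df["time_point"] = df["time_point"].str.strip()
    df["fraction"] = df["fraction"].map(normalize_fraction)
    df["replicate"] = _to_numeric(df, "replicate").astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate indices must be positive integers")
    df["abundance"] = _to_numeric(df, "abundance", allow_missing=True)
    if (df["abundance"].dropna() < 0).any():
        raise ValidationError("abundance must be non-negative")
    df["n_peptides"] = _to_numeric(df, "n_peptides").astype(int)
    if (df["n_peptides"] < 0).any():
        raise ValidationError("n_peptides must be non-negative")
    df["coverage"] = _to_numeric(df, "coverage")
    if ((df["coverage"] < 0) | (df["coverage"] > 1)).any():
        raise ValidationError("coverage must lie in [0, 1]")

    key = ["protein_id", "time_point", "replicate", "fraction"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(f"duplicate record key {first}")

    if time_order is not None:
        unknown = set(df["time_point"]) - set(time_order)
        if unknown:
            raise ValidationError(f"time point(s) {sorted(unknown)} not in time_order")
        df["time_point"] = pd.Categorical(df["time_point"], categories=list(time_order), ordered=True)
    return df


def read_phospho(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a phosphopeptide intensity table (long form)."""
    schema = dict(schema or {})
    mapping = {name: schema.get(name, name) for name in PHOSPHO_COLUMNS}
    raw = _read_delimited(path, delimiter)
    missing_cols = [src for src in mapping.values() if src not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mapped column(s): {missing_cols}")
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    df["protein_id"] = df["protein_id"].str.strip()
    df["replicate"] = _to_numeric(df, "replicate").astype(int)
    df["intensity"] = _to_numeric(df, "intensity")
    if (df["intensity"] < 0).any():
        raise ValidationError("intensity must be non-negative")
    return df


def read_trajectory_matrix(
    path: str | Path,
    time_order: Sequence[str] | None = None,
    id_column: str | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a wide proteins x time-points solubility matrix.

    One row per protein, one column per time point, values in [0, 1] or
    missing (empty cells become NaN and are never imputed).  Row order
    follows the file; column order follows ``time_order`` when given.
    """
    raw = _read_delimited(path, delimiter)
    if id_column is None:
        id_column = raw.columns[0]
    if id_column not in raw.columns:
        raise SchemaError(f"missing id column {id_column!r}")
    matrix = raw.set_index(raw[id_column].str.strip()).drop(columns=[id_column])
    matrix.index.name = "protein_id"
    for col in matrix.columns:
        col_raw = matrix[col].str.strip()
        missing = col_raw == ""
        values = pd.to_numeric(col_raw.mask(missing), errors="coerce")
        bad = values.isna() & ~missing
        if bad.any():
            raise ValidationError(
                f"unparseable value in column {col!r} for protein "
                f"{matrix.index[bad][0]!r}"
            )
        out_of_range = (values < 0) | (values > 1)
        if out_of_range.any():
            raise ValidationError(
                f"value outside [0, 1] in column {col!r} for protein "
                f"{matrix.index[out_of_range.fillna(False)][0]!r}"
            )
        matrix[col] = values
    if time_order is not None:
        missing_tp = [t for t in time_order if t not in matrix.columns]
        if missing_tp:
            raise SchemaError(f"time point column(s) {missing_tp} absent from file")
        matrix = matrix[list(time_order)]
    return matrix


def read_annotation_map(path: str | Path, delimiter: str | None = None) -> dict[str, dict]:
    """Read term -> members annotations.

    Accepts a 2- or 3-column table (``term_id`` [, ``term_name``],
    ``protein_id``) or GMT (tab-separated: term, description, members...).
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        terms: dict[str, dict] = {}
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            term, name, members = parts[0], parts[1], parts[2:]
            terms[term] = {"term_name": name or term, "members": set(m for m in members if m)}
        return _validated_terms(terms)
    df = _read_delimited(path, delimiter)
    cols = list(df.columns)
    if len(cols) == 2:
        term_col, name_col, member_col = cols[0], None, cols[1]
    elif len(cols) >= 3:
        term_col, name_col, member_col = cols[0], cols[1], cols[2]
    else:
        raise SchemaError("annotation table needs at least 2 columns (term, protein)")
    terms = {}
    for _, row in df.iterrows():
        term = row[term_col].strip()
        entry = terms.setdefault(
            term,
            {"term_name": (row[name_col].strip() if name_col else term), "members": set()},
        )
        entry["members"].add(row[member_col].strip())
    return _validated_terms(terms)


def _validated_terms(terms: dict[str, dict]) -> dict[str, dict]:
    empty = [t for t, e in terms.items() if not e["members"]]
    if empty:
        raise ValidationError(f"annotation term(s) with empty member set: {empty[:5]}")
    return terms


def read_edge_list(path: str | Path, delimiter: str | None = None) -> list[tuple[str, str]]:
    """Read an undirected interaction edge list (first two columns).

    Self-edges are dropped; pairs are stored order-independent (sorted)
    and deduplicated, preserving first-occurrence order.
    """
    df = _read_delimited(path, delimiter)
    if df.shape[1] < 2:
        raise SchemaError("edge list needs at least 2 columns")
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = a.strip(), b.strip()
        if a == b:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair not in seen:
            seen.add(pair)
            edges.append(pair)
    return edges


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write one CSV per table plus a JSON manifest.

    The manifest maps table name to file name, row count and SHA-256
    checksum of the written bytes; identical inputs always yield
    identical checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in sorted(tables):
        df = tables[name]
        target = out_dir / f"{name}.csv"
        text = df.to_csv(index=False, lineterminator="\n")
        target.write_text(text, encoding="utf-8")
        manifest[name] = {
            "file": target.name,
            "n_rows": int(df.shape[0]),
            "sha256": hashlib.sha256(text.encode("utf-8")).hexdigest(),
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
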