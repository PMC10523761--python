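"""Readers and writers for the pipeline's tabular inputs and outputs.

All on-disk formats are plain TSV with a mandatory header row; lines
beginning with ``#`` are comments.  The six input schemas are:

========== ==========================================
schema     columns
========== ==========================================
edges      p1, p2            (header may be a comment)
expression gene, fpkm
annotation term_id, term_name, gene
dea        gene, log2fc, padj
splicing   gene, fdr
disease    gene, linked      (linked in {0, 1})
========== ==========================================

Loaders return plain Python containers (dicts keyed by gene identifier,
lists of records) so downstream stages are independent of any file
dialect.  Writers emit canonically sorted rows with floats formatted to
six significant digits, which makes repeated writes byte-identical.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Sequence

__all__ = [
    "ParseError",
    "SchemaError",
    "read_edge_list",
    "read_table",
    "write_edge_list",
    "write_table",
    "format_float",
    "write_tsv",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class SchemaError(ValueError):
    """An input file does not conform to its declared schema."""


SCHEMAS: dict[str, tuple[str, ...]] = {
    "expression": ("gene", "fpkm"),
    "annotation": ("term_id", "term_name", "gene"),
    "dea": ("gene", "log2fc", "padj"),
    "splicing": ("gene", "fdr"),
    "disease": ("gene", "linked"),
}

#: Strings interpreted as a missing adjusted p-value / FDR.
NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A", "None", "."}


def format_float(x: float) -> str:
    """Render ``x`` with 6 significant digits (deterministic output)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a two-column interaction edge list.

    Duplicate and reversed-duplicate pairs are kept as-is; collapsing to
    a simple graph is the network builder's job.  Extra columns (e.g.
    evidence annotations from an interaction database export) are
    ignored.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"tokens, got {line!r}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path) -> None:
    rows = sorted(tuple(p) for p in pairs)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#p1\tp2\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# typed tables


def _parse_float(token: str) -> float | None:
    if token.strip() in NA_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def _iter_rows(path):
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                yield lineno, "header", header
            else:
                yield lineno, "row", fields


def read_table(path, schema: str):
    """Read a typed TSV table.

    Parameters
    ----------
    path
        File to read.
    schema
        One of ``expression``, ``annotation``, ``dea``, ``splicing``,
        ``disease`` (see module docstring for the columns).

    Returns
    -------
    ``annotation`` yields a list of ``(term_id, term_name, gene)``
    records with duplicate ``(term_id, gene)`` pairs collapsed; every
    other schema yields a dict keyed by gene:

    * ``expression``: gene -> fpkm (float, >= 0)
    * ``dea``: gene -> (log2fc, padj-or-None)
    * ``splicing``: gene -> fdr
    * ``disease``: gene -> bool
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    required = SCHEMAS[schema]
    col_idx: dict[str, int] = {}
    records: list[tuple] = []
    for lineno, kind, fields in _iter_rows(path):
        if kind == "header":
            for col in required:
                if col not in fields:
                    raise SchemaError(
                        f"{path}: missing required column {col!r} for schema "
                        f"{schema!r} (header: {fields})"
                    )
            col_idx = {col: fields.index(col) for col in required}
            continue
        if len(fields) < len(col_idx):
            raise ParseError(f"{path}: line {lineno}: too few columns")
        records.append(tuple(fields[col_idx[c]].strip() for c in required))
    if not col_idx:
        raise SchemaError(f"{path}: empty file, header row required")
    return _typed(path, schema, records)


def _typed(path, schema, records):
    if schema == "annotation":
        seen: dict[tuple[str, str], tuple[str, str, str]] = {}
        for term_id, term_name, gene in records:
            seen.setdefault((term_id, gene), (term_id, term_name, gene))
        return sorted(seen.values())

    out: dict = {}

    def check_unique(gene, lineno_hint):
        if gene in out:
            raise SchemaError(f"{path}: duplicate gene row {gene!r}")

    if schema == "expression":
        for gene, fpkm in records:
            check_unique(gene, None)
            value = _parse_float(fpkm)
            if value is None or value < 0:
                raise SchemaError(f"{path}: invalid FPKM {fpkm!r} for {gene!r}")
            out[gene] = value
    elif schema == "dea":
        for gene, log2fc, padj in records:
            check_unique(gene, None)
            fc = _parse_float(log2fc)
            if fc is None:
                raise SchemaError(f"{path}: invalid log2fc {log2fc!r} for {gene!r}")
            p = _parse_float(padj)
            if p is not None and not (0.0 <= p <= 1.0):
                raise SchemaError(f"{path}: padj out of [0,1] for {gene!r}")
            out[gene] = (fc, p)
    elif schema == "splicing":
        for gene, fdr in records:
            check_unique(gene, None)
            f = _parse_float(fdr)
            if f is None:
                f = 1.0  # unparseable FDR treated as non-significant
            if not (0.0 <= f <= 1.0):
                raise SchemaError(f"{path}: fdr out of [0,1] for {gene!r}")
            out[gene] = f
    elif schema == "disease":
        for gene, linked in records:
            check_unique(gene, None)
            if linked not in {"0", "1"}:
                raise SchemaError(f"{path}: linked must be 0 or 1, got {linked!r}")
            out[gene] = linked == "1"
    return out


def write_table(table, schema: str, path) -> None:
    """Write a typed table back to TSV (inverse of :func:`read_table`)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    header = SCHEMAS[schema]
    rows: list[tuple[str, ...]] = []
    if schema == "annotation":
        rows = [tuple(rec) for rec in sorted(table)]
    elif schema == "expression":
        rows = [(g, format_float(v)) for g, v in sorted(table.items())]
    elif schema == "dea":
        rows = [
            (g, format_float(fc), format_float(p) if p is not None else "NA")
            for g, (fc, p) in sorted(table.items())
        ]
    elif schema == "splicing":
        rows = [(g, format_float(f)) for g, f in sorted(table.items())]
    elif schema == "disease":
        rows = [(g, "1" if v else "0") for g, v in sorted(table.items())]
    write_tsv(path, header, rows)


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    """Write header + rows as TSV. Rows must already be strings and sorted."""
    buf = io.StringIO()
    buf.write("\t".join(header) + "\n")
    for row in rows:
        buf.write("\t".join(row) + "\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
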