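"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (with an optional parallel
``<stem>.detection.tsv`` carrying per-cell detection p-values) or as GCT 1.2
(accepted without detection values).  Gene sets are GMT; weighted signatures
are a three-column TSV (signature, gene, weight); sample annotation is CSV;
the GO-style DAG is an "OBO-lite" TSV with one term per row.  All readers
uppercase-normalise gene symbols and all reader/writer pairs round-trip
losslessly.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    GeneSignature,
    GoDag,
    GoTerm,
    validate_annotation,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_signatures",
    "write_signatures",
    "read_annotation",
    "write_annotation",
    "read_go_dag",
    "write_go_dag",
]

_GENE_COL = "gene_symbol"
_PROBE_COL = "probe_id"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def _detection_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".detection.tsv") if path.suffix != ".tsv" \
        else path.with_name(path.stem + ".detection.tsv")


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    TSV layout: optional ``# key: value`` header comments (``# scale: log2``
    or ``# scale: raw``; ``# slides: s1,s1,s2,...`` aligned with the sample
    columns), then a header row ``probe_id[<TAB>gene_symbol]<TAB>samples...``.
    A companion ``<stem>.detection.tsv`` of identical probe/sample layout, if
    present next to the file, supplies detection p-values.

    GCT 1.2: ``#1.2`` line, a dims line, then ``Name<TAB>Description`` plus
    sample columns; the Description column is taken as the gene symbol and
    the dims line is validated against the parsed table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "gct":
        return _read_gct(path)
    raise ValueError(f"unknown expression format {format!r}")


def _read_tsv(path: Path) -> ExpressionMatrix:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
    raw_samples = [c for c in header[1:] if c != _GENE_COL]
    if len(set(raw_samples)) != len(raw_samples):
        raise ParseError(f"{path}: duplicate sample id in header line {skip + 1}")
    table = pd.read_csv(path, sep="\t", skiprows=skip, dtype={0: str})
    if table.columns[0] != _PROBE_COL:
        raise ParseError(
            f"{path}: header line {skip + 1} must start with {_PROBE_COL!r}, "
            f"got {table.columns[0]!r}"
        )
    if table[_PROBE_COL].duplicated().any():
        raise ParseError(f"{path}: duplicate probe ids")
    sample_cols = [c for c in table.columns[1:] if c != _GENE_COL]
    values = table.set_index(_PROBE_COL)[sample_cols].astype(float)
    values.index.name = None
    symbols = None
    if _GENE_COL in table.columns:
        symbols = table.set_index(_PROBE_COL)[_GENE_COL].astype("string")
        symbols.index.name = None
    detection = None
    det_path = _detection_path(path)
    if det_path.exists():
        det = pd.read_csv(det_path, sep="\t", index_col=0)
        det.index.name = None
        if not det.index.equals(values.index) or list(det.columns) != sample_cols:
            raise ParseError(f"{det_path}: layout does not match {path}")
        detection = det.astype(float)
    slide_of = None
    if "slides" in meta:
        labels = [s.strip() for s in meta["slides"].split(",")]
        if len(labels) != len(sample_cols):
            raise ParseError(f"{path}: '# slides:' lists {len(labels)} labels "
                             f"for {len(sample_cols)} samples")
        slide_of = pd.Series(labels, index=sample_cols)
    return ExpressionMatrix(
        values=values,
        gene_symbols=symbols,
        detection_p=detection,
        slide_of=slide_of,
        is_log2=meta.get("scale", "raw") == "log2",
    )


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: line 1: expected '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}: line 2: expected '<n_probes> <n_samples>'")
        n_probes, n_samples = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", dtype={0: str, 1: str})
    if list(table.columns[:2]) != ["Name", "Description"]:
        raise ParseError(f"{path}: line 3 must start with 'Name\\tDescription'")
    sample_cols = list(table.columns[2:])
    if len(set(sample_cols)) != len(sample_cols):
        raise ParseError(f"{path}: duplicate sample id on line 3")
    if table.shape[0] != n_probes or len(sample_cols) != n_samples:
        raise ParseError(
            f"{path}: dims line says ({n_probes}, {n_samples}) but table is "
            f"({table.shape[0]}, {len(sample_cols)})"
        )
    if table["Name"].duplicated().any():
        raise ParseError(f"{path}: duplicate probe ids")
    values = table.set_index("Name")[sample_cols].astype(float)
    values.index.name = None
    symbols = table.set_index("Name")["Description"].astype("string")
    symbols.index.name = None
    return ExpressionMatrix(values=values, gene_symbols=symbols, is_log2=False)


def write_expression(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix as TSV (+ companion detection file) or GCT 1.2."""
    path = Path(path)
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.values.copy()
            desc = matrix.gene_symbols if matrix.gene_symbols is not None \
                else pd.Series("na", index=out.index)
            out.insert(0, "Description", desc)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
        return
    if format != "tsv":
        raise ValueError(f"unknown expression format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# scale: {'log2' if matrix.is_log2 else 'raw'}\n")
        if matrix.slide_of is not None:
            fh.write("# slides: " + ",".join(map(str, matrix.slide_of)) + "\n")
        out = matrix.values.copy()
        if matrix.gene_symbols is not None:
            out.insert(0, _GENE_COL, matrix.gene_symbols)
        out.index.name = _PROBE_COL
        out.to_csv(fh, sep="\t")
    if matrix.detection_p is not None:
        det = matrix.detection_p.copy()
        det.index.name = _PROBE_COL
        det.to_csv(_detection_path(path), sep="\t")


# -- gene sets -----------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    "at least one gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "na")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# -- weighted signatures -------------------------------------------------------

def read_signatures(path) -> dict[str, GeneSignature]:
    """Read weighted signatures from a ``signature<TAB>gene<TAB>weight`` TSV."""
    table = pd.read_csv(path, sep="\t")
    required = {"signature", "gene", "weight"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, GeneSignature] = {}
    for name, grp in table.groupby("signature", sort=False):
        out[str(name)] = GeneSignature(
            name=str(name),
            genes=tuple(grp["gene"].astype(str)),
            weights=tuple(grp["weight"].astype(float)),
        )
    return out


def write_signatures(signatures: dict[str, GeneSignature], path) -> None:
    rows = [
        {"signature": sig.name, "gene": g, "weight": w}
        for sig in signatures.values()
        for g, w in zip(sig.genes, sig.weights)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- annotation ----------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read and validate a sample-annotation CSV (one row per sample)."""
    ann = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str,
                                   "stage": str})
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


# -- GO-style DAG --------------------------------------------------------------

def read_go_dag(path) -> GoDag:
    """Read an OBO-lite TSV DAG.

    Columns: ``term_id``, ``name``, ``parents`` (``|``-separated, empty for
    roots), ``genes`` (``|``-separated direct annotations).  Annotations are
    propagated to ancestors at load (true-path rule); a cyclic file is
    rejected.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"term_id", "name", "parents", "genes"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    terms = []
    for _, row in table.iterrows():
        parents = tuple(p for p in row["parents"].split("|") if p)
        genes = frozenset(g.upper() for g in row["genes"].split("|") if g)
        terms.append(GoTerm(row["term_id"], row["name"], parents, genes))
    return GoDag(terms)


def write_go_dag(dag: GoDag, path) -> None:
    rows = []
    for tid in sorted(dag.topological_order()):
        t = dag.term(tid)
        rows.append({
            "term_id": t.term_id,
            "name": t.name,
            "parents": "|".join(t.parents),
            "genes": "|".join(sorted(t.genes)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
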