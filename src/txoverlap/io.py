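"""Readers and writers for every tabular artifact the pipeline touches.

Canonical dialect is TSV, UTF-8, '.' decimal separator (unambiguous for gene
symbols containing commas). Readers validate strictly and reject rather than
coerce; error messages carry file and line number. Write->read round trips
are identity for every format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    DiseaseSignature,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    HomologTable,
    ProbeAnnotation,
    SampleDesign,
    normalize_symbol,
)

# Expression values round-trip exactly through repr (shortest float repr).
_FLOAT_FMT = "%.17g"


def _read_lines(path) -> list[str]:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as e:
        raise FormatError(f"{path}: cannot read file: {e}") from e
    return text.splitlines()


def read_expression(path) -> ExpressionMatrix:
    """Read a probes x samples log2 expression TSV (header row = sample ids)."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    n_cols = len(header)
    probes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_cols})"
            )
        probes.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError:
            bad = next(f for f in fields[1:] if not _is_float(f))
            raise FormatError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
    seen: set[str] = set()
    for lineno, p in enumerate(probes, start=2):
        if p in seen:
            raise FormatError(f"{path}:{lineno}: duplicate probe id {p!r}")
        seen.add(p)
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=probes, columns=sample_ids)
    try:
        return ExpressionMatrix(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for probe, row in zip(df.index, df.to_numpy()):
            fh.write(str(probe) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_design(path) -> SampleDesign:
    """Read a sample design TSV: sample_id, group, dataset, taxon.

    Group values are parsed case-insensitively ("CASE" == "case").
    """
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    expected = ["sample_id", "group", "dataset", "taxon"]
    if header != expected:
        raise FormatError(f"{path}:1: header must be {expected}, got {header}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        sample, group, dataset, taxon = (f.strip() for f in fields)
        group_lc = group.lower()
        if group_lc not in (CASE, CONTROL):
            raise FormatError(f"{path}:{lineno}: unknown group value {group!r}")
        records.append((sample, group_lc, dataset, taxon))
    df = pd.DataFrame(records, columns=expected).set_index("sample_id")
    try:
        return SampleDesign(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_design(design: SampleDesign, path) -> None:
    df = design.table.reset_index()
    df.columns = ["sample_id", "group", "dataset", "taxon"]
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> ProbeAnnotation:
    """Read a probe annotation TSV: probe_id, gene_symbol, taxon.

    Empty gene_symbol marks an unannotated probe. Symbols are upper-cased.
    """
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    expected = ["probe_id", "gene_symbol", "taxon"]
    if header != expected:
        raise FormatError(f"{path}:1: header must be {expected}, got {header}")
    probes, genes, taxa = [], [], set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        probe, gene, taxon = (f.strip() for f in fields)
        probes.append(probe)
        genes.append(normalize_symbol(gene) if gene else "")
        taxa.add(taxon)
    if len(taxa) != 1:
        raise FormatError(f"{path}: annotation must carry exactly one taxon, got {sorted(taxa)}")
    try:
        return ProbeAnnotation(pd.Series(genes, index=probes, dtype=object), taxon=taxa.pop())
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": annotation.mapping.index,
            "gene_symbol": annotation.mapping.values,
            "taxon": annotation.taxon,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_homologs(path) -> HomologTable:
    """Read a HomoloGene-style TSV: group_id, taxon_id, symbol."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    expected = ["group_id", "taxon_id", "symbol"]
    if header != expected:
        raise FormatError(f"{path}:1: header must be {expected}, got {header}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        group, taxon, symbol = (f.strip() for f in fields)
        records.append((group, taxon, normalize_symbol(symbol)))
    df = pd.DataFrame(records, columns=expected)
    try:
        return HomologTable(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_homologs(table: HomologTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in standard GMT format (name, description, members...).

    Members are upper-cased and deduplicated within a set.
    """
    lines = _read_lines(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, desc = fields[0].strip(), fields[1].strip()
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        members = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_signature(signature: DiseaseSignature, path) -> None:
    rows = [
        (g, signature.directions[g], signature.pvalues.get(g, float("nan")))
        for g in sorted(signature.directions)
    ]
    df = pd.DataFrame(rows, columns=["gene", "direction", "p_value"])
    df.insert(0, "label", signature.label)
    df.insert(1, "taxon", signature.taxon)
    df.to_csv(path, sep="\t", index=False)


def read_signature(path) -> DiseaseSignature:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str})
    required = {"label", "taxon", "gene", "direction", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: signature table missing columns {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: empty signature table")
    labels = df["label"].unique()
    taxa = df["taxon"].unique()
    if len(labels) != 1 or len(taxa) != 1:
        raise FormatError(f"{path}: signature file must hold exactly one label and taxon")
    directions = {normalize_symbol(g): int(d) for g, d in zip(df["gene"], df["direction"])}
    pvalues = {normalize_symbol(g): float(p) for g, p in zip(df["gene"], df["p_value"])}
    return DiseaseSignature(
        label=str(labels[0]), taxon=str(taxa[0]), directions=directions, pvalues=pvalues
    )


def write_tables(tables: dict[str, pd.DataFrame], out_dir, summary: dict | None = None) -> None:
    """Write result DataFrames as TSVs plus an optional JSON run summary.

    Column order is the DataFrame's; rows are written as given (callers sort
    deterministically before calling).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if summary is not None:
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
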