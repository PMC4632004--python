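"""Readers and writers for the tabular formats the pipeline exchanges.

Supported formats: tab-delimited expression tables (genes in rows, first
column = gene symbol), GCT v1.2, GMT gene-set files, tab-delimited survival
tables, and a TSV edge list for transcriptional networks. All writers emit
TSV with a header row and round-trip losslessly with their paired reader.

Gene symbols are matched case-sensitively after whitespace trimming; no
alias mapping is attempted. Duplicate gene rows are collapsed by keeping the
row with the largest variance (the most informative probe for a symbol).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, SurvivalTable

if TYPE_CHECKING:  # pragma: no cover
    from .network import TranscriptionalNetwork

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, format: str = "tsv",
                    dataset_id: str | None = None) -> ExpressionMatrix:
    """Read a log2 expression matrix from TSV or GCT v1.2.

    Duplicate gene symbols are collapsed to the single most variable row.
    Non-numeric cells raise a :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if format not in ("tsv", "gct"):
        raise ParseError(f"unknown expression format {format!r}")
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ParseError(f"{path}: line 1: expected GCT '#1.2' header, "
                             f"got {version!r}")
        raw = pd.read_csv(path, sep="\t", skiprows=2, dtype=str,
                          keep_default_na=False)
        if raw.shape[1] < 3:
            raise ParseError(f"{path}: GCT needs Name, Description and "
                             "at least one sample column")
        gene_col = raw.columns[0]
        data_cols = list(raw.columns[2:])
        header_lines = 3
    else:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if raw.shape[1] < 2:
            raise ParseError(f"{path}: expected gene column plus sample "
                             "columns in the header")
        gene_col = raw.columns[0]
        data_cols = list(raw.columns[1:])
        header_lines = 1

    # pandas mangles duplicate header names, so check the raw header line
    with open(path) as fh:
        for _ in range(header_lines - 1):
            fh.readline()
        header_fields = [c.strip() for c in
                         fh.readline().rstrip("\n").split("\t")]
    raw_samples = header_fields[len(header_fields) - len(data_cols):]
    if len(set(raw_samples)) != len(raw_samples):
        raise ParseError(f"{path}: duplicate sample id in header")
    sample_ids = raw_samples

    genes = raw[gene_col].astype(str).str.strip()
    values = np.empty((len(raw), len(data_cols)))
    for j, col in enumerate(data_cols):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: line {i + header_lines + 1}: non-numeric value "
                f"{raw[col].iloc[i]!r} for gene {genes.iloc[i]!r}, "
                f"sample {sample_ids[j]!r}")
        values[:, j] = converted.to_numpy()

    gene_list, values = _collapse_duplicate_genes(list(genes), values)
    return ExpressionMatrix(gene_list, sample_ids, values,
                            dataset_id or path.stem)


def _collapse_duplicate_genes(genes: list[str], values: np.ndarray
                              ) -> tuple[list[str], np.ndarray]:
    """Keep the max-variance row per symbol, preserving first-seen order."""
    if len(set(genes)) == len(genes):
        return genes, values
    variances = values.var(axis=1)
    best: dict[str, int] = {}
    order: list[str] = []
    for i, g in enumerate(genes):
        if g not in best:
            best[g] = i
            order.append(g)
        elif variances[i] > variances[best[g]]:
            best[g] = i
    rows = [best[g] for g in order]
    logger.info("collapsed %d duplicate gene rows", len(genes) - len(order))
    return order, values[rows]


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: str = "tsv") -> None:
    path = Path(path)
    df = matrix.to_frame()
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ParseError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs at least "
                    f"3 tab-separated fields, got {len(fields)}")
            members = [m for m in fields[2:] if m]
            if len(set(members)) != len(members):
                logger.warning("%s: line %d: duplicate members in gene set "
                               "%r de-duplicated", path, lineno, fields[0])
            sets.append(GeneSet(fields[0], fields[1], frozenset(members)))
    return sets


def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# survival


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival table (sample_id, time, event[, cohort_id])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "cohort_id" not in df.columns:
        df["cohort_id"] = path.stem
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks

NETWORK_COLUMNS = ("tf", "target", "mi", "mode", "bootstrap_support")


def write_network(network: "TranscriptionalNetwork", path: str | Path) -> None:
    """Write a network as a TSV edge list (tf, target, mi, mode, support)."""
    rows = []
    for reg in network.regulons:
        for target, edge in sorted(reg.targets.items()):
            rows.append((reg.tf, target, edge.mi, edge.mode,
                         edge.bootstrap_support))
    df = pd.DataFrame(rows, columns=list(NETWORK_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path,
                 universe: set[str] | None = None) -> "TranscriptionalNetwork":
    """Read an edge-list TSV written by :func:`write_network`."""
    from .network import Edge, Regulon, TranscriptionalNetwork

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing network columns {missing}")
    regulons: dict[str, dict[str, Edge]] = {}
    for row in df.itertuples(index=False):
        regulons.setdefault(str(row.tf), {})[str(row.target)] = Edge(
            mi=float(row.mi), mode=int(row.mode),
            bootstrap_support=float(row.bootstrap_support))
    regs = [Regulon(tf, targets) for tf, targets in regulons.items()]
    if universe is None:
        universe = {str(t) for t in df["target"]} | {str(t) for t in df["tf"]}
    return TranscriptionalNetwork(regulons=regs, universe=universe)
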