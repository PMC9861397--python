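"""Readers and writers for the plain tab-separated table formats.

Layouts (all TSV, one header row):

* β matrix — first column ``site_id``, remaining columns sample IDs.
* labels — two columns ``sample_id``, ``group`` (tumor/normal).
* interactions — five columns ``rna_a``, ``rna_b``, ``type_a``, ``type_b``,
  ``confidence``.
* site-gene map — two columns ``site_id``, ``gene``.
* expression — first column ``gene_id``, remaining columns sample IDs.
* clinical — three columns ``sample_id``, ``time``, ``event``.
* gene sets — two columns ``pathway`` (``id:name``) and ``genes``
  (comma-separated symbols); an optional ``#background:`` comment line lists
  the background universe, otherwise the union of all sets is used.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    RNA_TYPES,
    BetaMatrix,
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    RnaInteractionTable,
    SiteGeneMap,
    ValidationError,
    normalize_site_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_beta_matrix", "write_beta_matrix",
    "read_labels", "write_labels",
    "read_interactions", "write_interactions",
    "read_site_gene_map", "write_site_gene_map",
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_gene_sets", "write_gene_sets",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        # round_trip float parsing: written values must re-read bit-for-bit
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a parseable TSV ({exc})") from exc


def read_labels(path) -> pd.Series:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(f"{path}: expected columns sample_id, group")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_beta_matrix(path, label_path) -> BetaMatrix:
    """Load a sites x samples β TSV, dropping rows with any missing value.

    Rows containing NA or non-numeric entries are removed (with a logged
    count); values outside [0, 1] are an error, not clipped.
    """
    df = _read_tsv(path, index_col=0)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty or headerless β matrix")
    df = df.apply(pd.to_numeric, errors="coerce")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d/%d sites with missing or non-numeric β values", n_dropped, n_before)
    labels = read_labels(label_path)
    return BetaMatrix(values=df, group_labels=labels)


def write_beta_matrix(beta: BetaMatrix, path, label_path=None) -> None:
    out = beta.values.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    if label_path is not None:
        write_labels(beta.group_labels, label_path)


def read_interactions(path, min_confidence: float = 0.75) -> RnaInteractionTable:
    """Load RNA-RNA interactions, keeping confidence strictly > min_confidence.

    Unknown RNA-type tokens are coerced to "other" with a warning; self-pairs
    are dropped; unordered duplicates collapse to the maximum confidence.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    df = _read_tsv(path)
    required = ["rna_a", "rna_b", "type_a", "type_b", "confidence"]
    if df.empty and df.columns.empty:
        logger.warning("%s: empty interaction file", path)
        df = pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: interaction table missing columns {missing}")
    df = df[required].copy()
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise").astype(float)
    if len(df) and ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValidationError(f"{path}: confidence outside [0, 1]")
    for col in ("type_a", "type_b"):
        unknown = ~df[col].isin(RNA_TYPES)
        if unknown.any():
            logger.warning(
                "%s: %d unknown RNA-type tokens in %s coerced to 'other'", path, int(unknown.sum()), col
            )
            df.loc[unknown, col] = "other"
    df = df[df["confidence"] > min_confidence]
    selfpairs = df["rna_a"] == df["rna_b"]
    if selfpairs.any():
        logger.warning("%s: dropped %d self-interactions", path, int(selfpairs.sum()))
        df = df[~selfpairs]
    # canonical unordered orientation, then max-confidence collapse
    flip = df["rna_a"] > df["rna_b"]
    df.loc[flip, ["rna_a", "rna_b", "type_a", "type_b"]] = df.loc[
        flip, ["rna_b", "rna_a", "type_b", "type_a"]
    ].to_numpy()
    df = (
        df.sort_values("confidence", ascending=False)
        .drop_duplicates(subset=["rna_a", "rna_b"], keep="first")
        .sort_values(["rna_a", "rna_b"])
        .reset_index(drop=True)
    )
    return RnaInteractionTable(rows=df)


def write_interactions(table: RnaInteractionTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_site_gene_map(path) -> SiteGeneMap:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["site_id", "gene"]:
        raise FormatError(f"{path}: expected columns site_id, gene")
    pairs = {(normalize_site_id(s), str(g)) for s, g in zip(df["site_id"], df["gene"])}
    return SiteGeneMap(pairs=pairs)


def write_site_gene_map(sgmap: SiteGeneMap, path) -> None:
    df = pd.DataFrame(sorted(sgmap.pairs), columns=["site_id", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_expression(path, label_path) -> ExpressionMatrix:
    df = _read_tsv(path, index_col=0)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty or headerless expression matrix")
    df = df.apply(pd.to_numeric, errors="raise")
    labels = read_labels(label_path)
    return ExpressionMatrix(values=df, group_labels=labels)


def write_expression(expr: ExpressionMatrix, path, label_path=None) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    if label_path is not None:
        write_labels(expr.group_labels, label_path)


def read_clinical(path) -> ClinicalTable:
    df = _read_tsv(path)
    required = ["sample_id", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {missing}")
    df = df[required].copy()
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    return ClinicalTable(rows=df.reset_index(drop=True))


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_sets(path, background=None) -> GeneSetCollection:
    """Read a 2-column pathway TSV (``id:name``, comma-separated genes)."""
    path = Path(path)
    bg_from_file: set[str] = set()
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["pathway", "genes"]:
            raise FormatError(f"{path}: expected columns pathway, genes")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#background:"):
                bg_from_file |= {g for g in line[len("#background:"):].split(",") if g}
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed gene-set line {line!r}")
            rows.append((parts[0], parts[1]))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    for pathway, genes_csv in rows:
        pid, _, name = pathway.partition(":")
        genes = frozenset(g for g in genes_csv.split(",") if g)
        if pid in sets:
            raise ValidationError(f"{path}: duplicate pathway id {pid!r}")
        sets[pid] = (name or pid, genes)
        union |= genes
    bg = frozenset(background) if background is not None else (frozenset(bg_from_file) or frozenset(union))
    return GeneSetCollection(sets=sets, background=bg | union)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pathway\tgenes\n")
        fh.write("#background:" + ",".join(sorted(collection.background)) + "\n")
        for pid in sorted(collection.sets):
            name, genes = collection.sets[pid]
            fh.write(f"{pid}:{name}\t{','.join(sorted(genes))}\n")
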