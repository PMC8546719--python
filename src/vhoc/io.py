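"""Readers and writers for every external format the pipeline touches.

All tables are TSV with ``#``-prefixed comment lines permitted, matching the
conventions of OTU-table tooling.  Trees are newick, handled through
dendropy; unnamed internal nodes receive deterministic post-order integer
ids so that enrichment output is reproducible across runs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    EDGE_COLUMNS,
    EDGE_MARKER_COLUMNS,
    HIT_COLUMNS,
    TAXONOMY_COLUMNS,
    AbundanceMatrix,
    EdgeList,
    HitTable,
    MetaVariableTable,
    ReferenceHostTable,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "read_abundance", "write_abundance",
    "read_taxonomy", "write_taxonomy",
    "read_edges", "write_edges",
    "read_hits", "write_hits",
    "read_reference_hosts", "write_reference_hosts",
    "read_metavariables", "write_metavariables",
    "read_newick", "write_newick", "parse_newick",
    "leaf_labels", "internal_nodes", "leaf_set",
]

_TSV_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_TSV_KW)
    return df


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna() & (df[col] != "")]
        if len(bad):
            row = bad[0]
            raise ValidationError(
                f"{what}: malformed numeric cell {df.at[row, col]!r} "
                f"at row {row!r}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# abundance matrices

def read_abundance(path, marker: str, size_fraction: str = "",
                   unit: str = "counts", check_clr_sum: bool = True) -> AbundanceMatrix:
    """Read an OTU x sample TSV (OTU ids in the first column)."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected an id column plus >=1 sample")
    ids = raw.iloc[:, 0]
    values = _to_numeric(raw.iloc[:, 1:].set_axis(ids, axis=0), str(path))
    m = AbundanceMatrix(values, marker=marker, size_fraction=size_fraction, unit=unit)
    m.data.index.name = "otu_id"
    return m.validate(check_clr_sum=check_clr_sum)


def write_abundance(m: AbundanceMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "otu_id"
    with open(path, "w") as fh:
        fh.write(f"# marker={m.marker} size_fraction={m.size_fraction} unit={m.unit}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy

def read_taxonomy(path, vocabulary=None) -> TaxonomyTable:
    raw = _read_table(path)
    idcol = raw.columns[0]
    df = raw.set_index(idcol)
    for col in TAXONOMY_COLUMNS:
        if col in df.columns:
            df[col] = df[col].replace("", pd.NA)
    return TaxonomyTable(df, vocabulary=tuple(vocabulary) if vocabulary else None)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.df.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# edges

def write_edges(edges: EdgeList, path) -> None:
    """Write an edge TSV sorted by (|weight| desc, source, target)."""
    df = edges.df.copy()
    cols = EDGE_COLUMNS + [c for c in EDGE_MARKER_COLUMNS if c in df.columns]
    df = df[cols]
    df = df.iloc[np.lexsort((df["target"], df["source"], -df["weight"].abs()))]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_edges(path) -> EdgeList:
    raw = _read_table(path)
    missing = [c for c in EDGE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: edge table missing columns {missing}")
    df = raw.copy()
    df["weight"] = pd.to_numeric(df["weight"])
    df["p_value"] = pd.to_numeric(df["p_value"].replace("", np.nan))
    return EdgeList(df)


# ---------------------------------------------------------------------------
# homology hits

#: Default column mapping: our own 6-column layout.
DEFAULT_HIT_COLUMNS: Mapping[str, int] = {
    "query_id": 0, "subject_id": 1, "percent_identity": 2,
    "percent_query_coverage": 3, "e_value": 4, "bitscore": 5,
}

#: BLAST ``-outfmt '6 std qcovs'`` (13 columns, coverage last).
BLAST_QCOVS_COLUMNS: Mapping[str, int] = {
    "query_id": 0, "subject_id": 1, "percent_identity": 2,
    "e_value": 10, "bitscore": 11, "percent_query_coverage": 12,
}


def read_hits(path, columns: Mapping[str, int] | None = None) -> HitTable:
    """Read tabular homology hits; ``columns`` maps field -> column index."""
    columns = dict(columns or DEFAULT_HIT_COLUMNS)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                rows.append({
                    "query_id": parts[columns["query_id"]],
                    "subject_id": parts[columns["subject_id"]],
                    "percent_identity": float(parts[columns["percent_identity"]]),
                    "percent_query_coverage": float(parts[columns["percent_query_coverage"]]),
                    "e_value": float(parts[columns["e_value"]]),
                    "bitscore": float(parts[columns["bitscore"]]),
                })
            except (IndexError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed hit row ({exc})")
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(df)


def write_hits(hits: HitTable, path) -> None:
    hits.df[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# reference hosts and meta-variables

def read_reference_hosts(path) -> ReferenceHostTable:
    return ReferenceHostTable(_read_table(path))


def write_reference_hosts(ref: ReferenceHostTable, path) -> None:
    ref.df.to_csv(path, sep="\t", index=False)


def read_metavariables(path) -> MetaVariableTable:
    raw = _read_table(path)
    df = raw.set_index(raw.columns[0])
    df = df.replace("", np.nan).apply(pd.to_numeric)
    return MetaVariableTable(df)


def write_metavariables(env: MetaVariableTable, path) -> None:
    df = env.df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# trees

def _finalize_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check leaf uniqueness/arity and assign post-order ids to unnamed nodes."""
    tree.is_rooted = True
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValidationError("tree has an unlabeled leaf")
    dupes = pd.Index(labels)
    if dupes.has_duplicates:
        raise ValidationError(
            f"duplicate leaf label: {dupes[dupes.duplicated()][0]!r}")
    idx = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label
        else:
            if len(node.child_nodes()) < 2:
                raise ValidationError(
                    "internal node with a single child (unresolved unifurcation)")
            node.node_id = node.label if node.label else f"n{idx}"
        idx += not node.is_leaf()
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValidationError(f"newick parse error: {exc}") from exc
    return _finalize_tree(tree)


def read_newick(path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def leaf_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def internal_nodes(tree: dendropy.Tree, exclude_root: bool = True):
    """Internal nodes in post-order (optionally without the root)."""
    out = []
    for node in tree.postorder_internal_node_iter():
        if exclude_root and node is tree.seed_node:
            continue
        out.append(node)
    return out
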