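"""Phylogeny-guided filtering of virus-host associations (Taxon Interaction
Mapper).

The filter assumes that evolutionarily related viruses tend to infect
evolutionarily related hosts.  For every internal node of a viral marker
tree (root excluded) and every host taxon seen in the network, a one-sided
Fisher exact test asks whether the leaves under the node are enriched in
associations with that taxon relative to the rest of the tree.  P-values
are Benjamini-Hochberg adjusted over all (node, taxon) tests jointly, and
only edges covered by a significant (node, taxon) pair are retained.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping

import dendropy
import pandas as pd

from .containers import (
    ContingencyTable2x2,
    EdgeList,
    EnrichmentResult,
    TaxonomyTable,
    ValidationError,
)
from .io import internal_nodes, leaf_labels, leaf_set
from .stats import bh_adjust, fisher_exact_greater

__all__ = [
    "build_associations", "node_taxon_enrichment",
    "filter_edges_by_enrichment", "tim_network",
]

logger = logging.getLogger(__name__)

RANKS = ("major_lineage", "ncbi_order", "ncbi_class", "ncbi_phylum")


def build_associations(edges: EdgeList, tax: TaxonomyTable,
                       ranks=("major_lineage",),
                       virus_marker: str = "polB") -> dict[str, set[tuple[str, str]]]:
    """Map each virus OTU to the (rank, label) taxa of its network partners.

    A virus is "associated" with a taxon when it has at least one retained
    edge to a eukaryotic OTU annotated with that taxon (presence/absence;
    edge weights and multiplicities are not used).
    """
    for rank in ranks:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
    assoc: dict[str, set[tuple[str, str]]] = {}
    for _, row in edges.df.iterrows():
        if row.get("target_marker") == virus_marker:
            v, e = row["target"], row["source"]
        else:
            v, e = row["source"], row["target"]
        for rank in ranks:
            label = tax.rank_label(e, rank)
            if label != "unclassified":
                assoc.setdefault(v, set()).add((rank, label))
    return assoc


def node_taxon_enrichment(tree: dendropy.Tree,
                          assoc: Mapping[str, set[tuple[str, str]]],
                          q_threshold: float = 0.05) -> list[EnrichmentResult]:
    """Per-node, per-taxon Fisher enrichment with joint BH adjustment.

    Every (internal node, taxon) combination enters the BH family; tests
    with an empty in-clade association count (a = 0, p = 1 by construction)
    are counted in the adjustment but not reported.  Leaves absent from
    ``assoc`` count as not associated.
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 3:
        raise ValidationError("tree must have at least 3 leaves")
    missing = set(assoc) - set(leaves)
    if missing:
        raise ValidationError(
            f"association keys absent from the tree: {sorted(missing)[:5]}")
    taxa = sorted({t for taxa_set in assoc.values() for t in taxa_set})
    n_total = len(leaves)
    taxon_members = {t: {v for v, ts in assoc.items() if t in ts} for t in taxa}

    tests = []   # (node_id, taxon, table) for a > 0
    pvals = []
    n_skipped = 0
    for node in internal_nodes(tree, exclude_root=True):
        clade = leaf_set(node)
        for taxon in taxa:
            members = taxon_members[taxon]
            a = len(clade & members)
            if a == 0:
                n_skipped += 1
                pvals.append(1.0)
                tests.append(None)
                continue
            b = len(clade) - a
            c = len(members) - a
            d = n_total - len(clade) - c
            table = ContingencyTable2x2(a, b, c, d)
            pvals.append(fisher_exact_greater(table))
            tests.append((node.node_id, taxon, table))
    qvals = bh_adjust(pvals)
    results = []
    for test, p, q in zip(tests, pvals, qvals):
        if test is None:
            continue
        node_id, taxon, table = test
        results.append(EnrichmentResult(
            unit_id=node_id, taxon=taxon, table=table,
            p=float(p), q=float(q), significant=bool(q < q_threshold)))
    logger.info("enrichment: %d tests (%d with a=0 kept in the BH family), "
                "%d significant at q<%g", len(pvals), n_skipped,
                sum(r.significant for r in results), q_threshold)
    return results


def _node_index(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {node.node_id: node for node in tree.preorder_node_iter()}


def filter_edges_by_enrichment(edges: EdgeList, results, tree: dendropy.Tree,
                               tax: TaxonomyTable,
                               virus_marker: str = "polB") -> EdgeList:
    """Retain only edges covered by a significant (node, taxon) pair.

    Edge (v, e) survives iff some significant enrichment has v among the
    node's leaves and e annotated with the enriched taxon at its rank.
    Edges whose virus endpoint is missing from the tree are dropped (the
    tree is typically built from a length-filtered subset of sequences).
    """
    nodes = _node_index(tree)
    tree_leaves = set(leaf_labels(tree))
    significant = [r for r in results if r.significant]
    covered: list[tuple[frozenset[str], str, str]] = []
    for r in significant:
        node = nodes.get(r.unit_id)
        if node is None:
            raise ValidationError(f"enrichment node {r.unit_id!r} not in tree")
        rank, label = r.taxon
        covered.append((leaf_set(node), rank, label))

    keep = []
    n_missing = 0
    for _, row in edges.df.iterrows():
        if row.get("target_marker") == virus_marker:
            v, e = row["target"], row["source"]
        else:
            v, e = row["source"], row["target"]
        if v not in tree_leaves:
            n_missing += 1
            keep.append(False)
            continue
        ok = any(v in leaves and tax.rank_label(e, rank) == label
                 for leaves, rank, label in covered)
        keep.append(ok)
    if n_missing:
        logger.info("dropped %d edges whose virus endpoint is absent from the tree",
                    n_missing)
    return EdgeList(edges.df[pd.Series(keep, index=edges.df.index)]
                    .reset_index(drop=True))


def tim_network(results, tree: dendropy.Tree,
                viral_families: Mapping[str, str],
                lineage_map: Mapping[str, str] | None = None,
                purity: float = 1.0) -> pd.DataFrame:
    """Family x lineage summary: number of enriched nodes per pair.

    Each significant (node, taxon) is attributed to the viral family that
    labels at least ``purity`` of the node's leaves (default: pure clades
    only; impure nodes go to "mixed").  Rank-level taxa are converted to
    major lineages through ``lineage_map`` (labels absent from the map pass
    through unchanged).
    """
    nodes = _node_index(tree)
    lineage_map = dict(lineage_map or {})
    weights: Counter[tuple[str, str]] = Counter()
    for r in results:
        if not r.significant:
            continue
        node = nodes[r.unit_id]
        fams = Counter(viral_families.get(lf, "unclassified")
                       for lf in leaf_set(node))
        family, count = fams.most_common(1)[0]
        if count / sum(fams.values()) < purity:
            logger.info("node %s below family purity %.2f; attributed to 'mixed'",
                        r.unit_id, purity)
            family = "mixed"
        lineage = lineage_map.get(r.taxon[1], r.taxon[1])
        weights[(family, lineage)] += 1
    df = pd.DataFrame(
        [(f, l, w) for (f, l), w in sorted(weights.items())],
        columns=["viral_family", "major_lineage", "weight"])
    return df
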