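"""Virophage-giant-virus partner analysis.

Virophages (marker: major capsid protein, MCP) parasitize the replication
factories of giant viruses, so co-occurrence edges between MCP and polB
OTUs carry a signal of partner specificity.  This module assigns MCP OTUs
to tree-defined clades, tests clade x viral-family enrichment of the edges
(Fisher exact + BH), and classifies horizontal-gene-transfer candidates
from homology hit tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .containers import (
    ContingencyTable2x2,
    EdgeList,
    EnrichmentResult,
    HitTable,
    ValidationError,
)
from .io import leaf_labels, leaf_set
from .stats import bh_adjust, fisher_exact_greater

__all__ = ["HgtConfig", "assign_clades", "clade_family_enrichment",
           "hgt_candidates", "group_families"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HgtConfig:
    """Hit-filtering thresholds for the HGT-candidate scan."""

    max_evalue: float = 1e-10
    min_coverage: float = 50.0
    min_identity: float = 50.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        for v in (self.min_coverage, self.min_identity):
            if not 0 <= v <= 100:
                raise ValueError("coverage/identity thresholds must lie in [0, 100]")


def assign_clades(tree: dendropy.Tree,
                  spec: Mapping[str, list[str]]) -> dict[str, str]:
    """Leaf -> clade label, with each clade the full MRCA of its seed leaves.

    Clades must be disjoint after MRCA expansion; leaves under no clade map
    to ``"unassigned"``.
    """
    leaves = set(leaf_labels(tree))
    taxon_ns = tree.taxon_namespace
    expanded: dict[str, frozenset[str]] = {}
    for label, seeds in spec.items():
        missing = [s for s in seeds if s not in leaves]
        if missing:
            raise ValidationError(
                f"clade {label!r}: defining leaf {missing[0]!r} not in tree")
        taxa = [taxon_ns.get_taxon(s) for s in seeds]
        mrca = tree.mrca(taxa=taxa)
        expanded[label] = leaf_set(mrca)
    labels = sorted(expanded)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            if expanded[x] & expanded[y]:
                raise ValidationError(
                    f"clades {x!r} and {y!r} overlap after MRCA expansion")
    out = {leaf: "unassigned" for leaf in leaves}
    for label, members in expanded.items():
        for leaf in members:
            out[leaf] = label
    return out


def group_families(families: Mapping[str, str],
                   keep=("Mimiviridae", "Phycodnaviridae"),
                   other_label: str = "Other NCLDVs") -> dict[str, str]:
    """Pool all viral families except ``keep`` into one group."""
    return {otu: fam if fam in keep else other_label
            for otu, fam in families.items()}


def clade_family_enrichment(edges: EdgeList, clades: Mapping[str, str],
                            families: Mapping[str, str],
                            weight_cutoff: float = 0.0,
                            q_threshold: float = 0.05,
                            mcp_marker: str = "MCP") -> list[EnrichmentResult]:
    """Clade x family Fisher enrichment over association edges.

    For each (clade, family group): a = edges from the clade to the group,
    b = edges from the clade to other groups, c/d = the same for the other
    clades; one-sided Fisher with BH over all tests.  Edges below the
    |weight| cutoff or with an unassigned-clade MCP endpoint are excluded.
    The counting unit is the edge (not the OTU).
    """
    pairs = []
    n_unassigned = 0
    for _, row in edges.df.iterrows():
        if abs(float(row["weight"])) <= weight_cutoff:
            continue
        if row.get("source_marker") == mcp_marker:
            mcp, virus = row["source"], row["target"]
        else:
            mcp, virus = row["target"], row["source"]
        clade = clades.get(mcp, "unassigned")
        if clade == "unassigned":
            n_unassigned += 1
            continue
        family = families.get(virus, "unclassified")
        pairs.append((clade, family))
    if n_unassigned:
        logger.info("excluded %d edges with unassigned-clade MCP endpoints",
                    n_unassigned)
    if not pairs:
        logger.warning("no edges above the weight cutoff; empty enrichment result")
        return []
    clade_labels = sorted({c for c, _ in pairs})
    family_labels = sorted({f for _, f in pairs})
    total = len(pairs)
    tests = []
    pvals = []
    for clade in clade_labels:
        n_clade = sum(1 for c, _ in pairs if c == clade)
        for family in family_labels:
            a = sum(1 for c, f in pairs if c == clade and f == family)
            b = n_clade - a
            c = sum(1 for cc, f in pairs if cc != clade and f == family)
            d = total - n_clade - c
            tests.append((clade, family, ContingencyTable2x2(a, b, c, d)))
            pvals.append(fisher_exact_greater(tests[-1][2]))
    qvals = bh_adjust(pvals)
    return [EnrichmentResult(unit_id=clade, taxon=("viral_family", family),
                             table=table, p=float(p), q=float(q),
                             significant=bool(q < q_threshold))
            for (clade, family, table), p, q in zip(tests, pvals, qvals)]


def hgt_candidates(mcp_vs_ncldv: HitTable, mcp_vs_mcp: HitTable,
                   cfg: HgtConfig = HgtConfig()) -> list[tuple[str, str]]:
    """Virophage capsid genes whose best giant-virus-genome hit outscores
    every non-self hit in the virophage database.

    Giant-virus hits must pass the e-value/coverage/identity thresholds.
    A query with no non-self virophage-database hit is a candidate whenever
    it has any passing giant-virus hit (logged as unguarded).
    """
    ncldv = mcp_vs_ncldv.df
    passing = ncldv[(ncldv["e_value"] <= cfg.max_evalue)
                    & (ncldv["percent_query_coverage"] >= cfg.min_coverage)
                    & (ncldv["percent_identity"] >= cfg.min_identity)]
    self_db = mcp_vs_mcp.df
    non_self = self_db[self_db["query_id"] != self_db["subject_id"]]
    best_self = non_self.groupby("query_id")["e_value"].min()
    out = []
    for query, sub in passing.groupby("query_id", sort=True):
        best = sub.sort_values(["e_value", "subject_id"]).iloc[0]
        if query not in best_self.index:
            logger.info("query %s has no non-self virophage hit; "
                        "unguarded HGT candidate", query)
            out.append((query, best["subject_id"]))
        elif best["e_value"] < best_self.loc[query]:
            out.append((query, best["subject_id"]))
    return sorted(out)
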