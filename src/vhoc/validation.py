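"""Quantitative assessment of network-based host predictions.

Environmental virus OTUs are grouped to reference viruses by best homology
hit at a sequence-identity threshold (default 65%); a (virus OTU, host
lineage) pair is condition-positive when the assigned reference has a known
host in that lineage.  Predictions are the best (highest |weight|) network
edge per (virus, lineage, sign).  The diagnostic metrics are the positive
likelihood ratio LR+ = sensitivity / (1 - specificity) — LR+ = 1 means the
prediction does not change the odds — and the false discovery rate
FP / (FP + TP), swept over edge-weight cutoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ConfusionMatrix,
    EdgeList,
    HitTable,
    ReferenceHostTable,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "GroupingConfig", "UNDEFINED",
    "assign_reference_groups", "condition_positive_pairs",
    "reduce_best_edges", "confusion", "lr_plus", "fdr",
    "sweep_cutoffs", "average_lr_plus",
]

logger = logging.getLogger(__name__)

#: Sentinel for diagnostics that are undefined on the given counts.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class GroupingConfig:
    """Best-hit grouping rule for recruiting OTUs into the validation."""

    identity_threshold: float = 65.0
    rank_by: str = "bitscore"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must lie in (0, 100]")
        if self.rank_by not in ("bitscore", "evalue"):
            raise ValueError("rank_by must be 'bitscore' or 'evalue'")


def assign_reference_groups(hits: HitTable,
                            cfg: GroupingConfig = GroupingConfig()) -> dict[str, str]:
    """Best reference hit per query, kept only at/above the identity threshold.

    The best hit is the highest bitscore (or lowest e-value); ties break by
    higher identity, then lexicographic subject id.  Queries whose best hit
    falls below the identity threshold are left unassigned and are excluded
    from the validation universe.
    """
    assignment: dict[str, str] = {}
    if not len(hits):
        return assignment
    if cfg.rank_by == "bitscore":
        def key(row):
            return (-row["bitscore"], -row["percent_identity"], row["subject_id"])
    else:
        def key(row):
            return (row["e_value"], -row["percent_identity"], row["subject_id"])
    for query, sub in hits.df.groupby("query_id", sort=True):
        best = min((row for _, row in sub.iterrows()), key=key)
        if best["percent_identity"] >= cfg.identity_threshold:
            assignment[query] = best["subject_id"]
    return assignment


def condition_positive_pairs(assignment: dict[str, str],
                             ref: ReferenceHostTable) -> set[tuple[str, str]]:
    """(virus OTU, host lineage) pairs implied by the reference table."""
    positives = set()
    for otu, reference in assignment.items():
        if reference not in ref.reference_ids:
            raise ValidationError(
                f"assigned reference {reference!r} absent from the reference table")
        for lineage in ref.hosts_of(reference):
            positives.add((otu, lineage))
    return positives


def reduce_best_edges(edges: EdgeList, tax: TaxonomyTable,
                      virus_marker: str = "polB") -> pd.DataFrame:
    """Keep the single best edge per (virus OTU, host lineage, sign).

    Multi-fraction input is pooled: among all edges between a virus OTU and
    any V9 OTU of a given lineage and sign, only the one with the highest
    |weight| survives (ties: larger signed weight, then lexicographic
    eukaryote id).  Rows are oriented by the endpoint-marker columns when
    present (otherwise the source is taken to be the virus).  Returns a
    frame with columns source (virus), lineage, weight, sign, eukaryote.
    """
    df = edges.df
    if not len(df):
        return pd.DataFrame(columns=["source", "lineage", "weight", "sign", "eukaryote"])
    if "target_marker" in df.columns:
        flip = df["target_marker"] == virus_marker
        virus = df["source"].where(~flip, df["target"])
        euk = df["target"].where(~flip, df["source"])
    else:
        virus, euk = df["source"], df["target"]
    lineages = euk.map(tax.major_lineage)
    work = pd.DataFrame({
        "source": virus, "lineage": lineages,
        "weight": df["weight"].astype(float), "sign": df["sign"],
        "eukaryote": euk,
    })
    order = np.lexsort((work["eukaryote"], -work["weight"], -work["weight"].abs()))
    work = work.iloc[order]
    reduced = work.drop_duplicates(subset=["source", "lineage", "sign"], keep="first")
    return reduced.reset_index(drop=True)


def confusion(reduced: pd.DataFrame, positives: set[tuple[str, str]],
              universe_lineages, assigned_otus, sign: str = "positive",
              weight_cutoff: float = 0.0) -> ConfusionMatrix:
    """Confusion matrix over the (assigned OTU) x (lineage) candidate universe.

    Predicted-positive pairs are reduced edges of the requested sign with
    |weight| strictly above the cutoff, restricted to the universe; the
    remainder of the universe is split into FN (condition positive) and TN.
    """
    lineage_list = list(universe_lineages)
    otu_list = sorted(set(assigned_otus))
    if not lineage_list or not otu_list:
        raise ValidationError("empty candidate universe")
    universe_size = len(otu_list) * len(lineage_list)
    lineage_set = set(lineage_list)
    otu_set = set(otu_list)
    positives_in_universe = {(o, l) for (o, l) in positives
                             if o in otu_set and l in lineage_set}
    sel = reduced[(reduced["sign"] == sign)
                  & (reduced["weight"].abs() > weight_cutoff)]
    predicted = {(o, l) for o, l in zip(sel["source"], sel["lineage"])
                 if o in otu_set and l in lineage_set}
    tp = len(predicted & positives_in_universe)
    fp = len(predicted) - tp
    fn = len(positives_in_universe) - tp
    tn = universe_size - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def lr_plus(cm: ConfusionMatrix) -> float:
    """Positive likelihood ratio, with inf/undefined boundary sentinels."""
    if cm.tp + cm.fn == 0:
        logger.warning("no condition positives; LR+ undefined")
        return UNDEFINED
    sens = cm.sensitivity
    rate_fp = cm.fpr
    if rate_fp == 0:
        return math.inf if sens > 0 else UNDEFINED
    return sens / rate_fp


def fdr(cm: ConfusionMatrix) -> float:
    """False discovery rate FP / (FP + TP); undefined with no predictions."""
    if cm.tp + cm.fp == 0:
        return UNDEFINED
    return cm.fp / (cm.fp + cm.tp)


def sweep_cutoffs(reduced: pd.DataFrame, positives: set[tuple[str, str]],
                  universe_lineages, assigned_otus, cutoff_grid,
                  sign: str = "positive") -> pd.DataFrame:
    """One confusion-matrix row per weight cutoff (grid sorted ascending)."""
    grid = list(cutoff_grid)
    if grid != sorted(grid):
        raise ValidationError("cutoff grid must be sorted ascending")
    rows = []
    for cutoff in grid:
        cm = confusion(reduced, positives, universe_lineages, assigned_otus,
                       sign=sign, weight_cutoff=cutoff)
        sel = reduced[(reduced["sign"] == sign)
                      & (reduced["weight"].abs() > cutoff)]
        rows.append({
            "weight_cutoff": cutoff, "sign": sign, "n_edges": len(sel),
            "TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn,
            "sensitivity": cm.sensitivity, "fpr": cm.fpr,
            "lr_plus": lr_plus(cm), "fdr": fdr(cm),
        })
    return pd.DataFrame(rows)


def average_lr_plus(sweep: pd.DataFrame) -> float:
    """Unweighted mean of the defined (finite) LR+ values across a sweep."""
    vals = sweep["lr_plus"].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    skipped = len(vals) - len(finite)
    if skipped:
        logger.info("excluded %d undefined/infinite LR+ values from the average",
                    skipped)
    return float(finite.mean()) if len(finite) else UNDEFINED
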