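"""Signed co-occurrence network inference and its summaries.

The in-repo inference is a Spearman comparator: rank each OTU's abundance
profile across samples (average ties), correlate candidate pairs, and keep
edges whose two-sided p-value clears the significance level (default
alpha < 0.01, uncorrected).  Externally produced edge lists (e.g. from a
conditional-independence tool) can be loaded through :mod:`vhoc.io` and fed
to the same downstream machinery.  First-order partial rank correlation
against environmental meta-variables approximates the removal of indirect
(environmentally driven) associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    EDGE_COLUMNS,
    AbundanceMatrix,
    EdgeList,
    MetaVariableTable,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "NetworkConfig", "DegreeSummary", "AggregatedNetwork",
    "spearman_network", "metavar_condition", "detect_env_associations",
    "degree_stats", "aggregate_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    alpha: float = 0.01
    cross_group_only: bool = True
    condition_on_metavars: bool = False
    min_shared_nonzero_samples: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class DegreeSummary:
    """Per-node positive/negative degree plus network means (degree >= 1)."""

    df: pd.DataFrame  # index otu_id, columns positive_degree, negative_degree
    mean_positive: float
    mean_negative: float
    isolated: list[str] = field(default_factory=list)


@dataclass
class AggregatedNetwork:
    """Edge counts between group labels (viral family x eukaryotic group)."""

    df: pd.DataFrame  # columns family, group, count_positive, count_negative
    node_sizes: pd.Series  # group label -> member OTU count


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (n-2 df)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return p


def _exact_rho_pvalue(x_ranks: np.ndarray, y_ranks: np.ndarray,
                      observed: float) -> float:
    """Exact two-sided permutation p-value for small n (<= 10)."""
    from itertools import permutations
    xc = x_ranks - x_ranks.mean()
    n = len(xc)
    denom_x = np.sqrt((xc ** 2).sum())
    count = 0
    total = 0
    for perm in permutations(range(n)):
        yp = y_ranks[list(perm)]
        yc = yp - yp.mean()
        denom = denom_x * np.sqrt((yc ** 2).sum())
        rho = (xc * yc).sum() / denom
        if abs(rho) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_network(m: AbundanceMatrix, cfg: NetworkConfig = NetworkConfig(),
                     exact_small_n: bool = False) -> EdgeList:
    """Spearman co-occurrence network over a merged abundance matrix.

    With ``cross_group_only`` (the default) only pairs whose endpoints carry
    different markers are tested — for a merged polB + V9 matrix those are
    the virus-eukaryote candidate pairs.  Constant profiles are skipped
    (rho undefined) and logged.
    """
    n = m.data.shape[1]
    if n < 5:
        raise ValidationError("need at least 5 samples for network inference")
    X = m.data.to_numpy(dtype=float)
    otus = np.asarray(m.data.index)
    markers = m.otu_markers.loc[m.data.index].to_numpy() \
        if m.otu_markers is not None else np.array([m.marker] * len(otus))

    constant = np.all(X == X[:, :1], axis=1)
    for otu in otus[constant]:
        logger.info("skipping constant OTU %s (Spearman undefined)", otu)

    ranks = sps.rankdata(X, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    norms[norms == 0] = np.nan

    rows = []
    marker_values = sorted(set(markers))
    if cfg.cross_group_only and len(marker_values) > 1:
        pair_blocks = []
        for mi in range(len(marker_values)):
            for mj in range(mi + 1, len(marker_values)):
                pair_blocks.append((np.flatnonzero(markers == marker_values[mi]),
                                    np.flatnonzero(markers == marker_values[mj])))
    else:
        idx = np.arange(len(otus))
        pair_blocks = [(idx, idx)]

    for left, right in pair_blocks:
        corr = (centered[left] @ centered[right].T) / np.outer(norms[left], norms[right])
        pmat = _rho_pvalues(corr, n)
        for ii, i in enumerate(left):
            for jj, j in enumerate(right):
                if left is right and j <= i:
                    continue
                if constant[i] or constant[j]:
                    continue
                if cfg.min_shared_nonzero_samples > 0:
                    shared = int(((X[i] > 0) & (X[j] > 0)).sum())
                    if shared < cfg.min_shared_nonzero_samples:
                        continue
                rho = float(corr[ii, jj])
                if exact_small_n and n <= 10:
                    p = _exact_rho_pvalue(ranks[i], ranks[j], rho)
                else:
                    p = float(pmat[ii, jj])
                if p < cfg.alpha and rho != 0.0:
                    rows.append((otus[i], otus[j], rho, p,
                                 "positive" if rho > 0 else "negative",
                                 m.size_fraction, markers[i], markers[j]))
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS + ["source_marker", "target_marker"])
    return EdgeList(df)


def _partial_rank_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, int]:
    """First-order partial Spearman: Pearson partial correlation on ranks."""
    mask = np.isfinite(z)
    x, y, z = x[mask], y[mask], z[mask]
    n = len(x)
    if n < 4:
        return np.nan, n
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    cm = np.corrcoef(np.vstack([rx, ry, rz]))
    r_xy, r_xz, r_yz = cm[0, 1], cm[0, 2], cm[1, 2]
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0 or not np.isfinite(denom):
        # one profile is a perfect monotone function of z: the pair's
        # association is fully attributable to the covariate
        return 0.0, n
    return float((r_xy - r_xz * r_yz) / denom), n


def metavar_condition(edges: EdgeList, m: AbundanceMatrix,
                      env: MetaVariableTable, alpha: float = 0.01) -> EdgeList:
    """Drop edges explainable by a single environmental covariate.

    An edge survives iff, for every meta-variable z, the first-order
    partial Spearman correlation of the pair given z is still significant
    at ``alpha`` (t approximation, n-3 df).  Removed edges are logged with
    the variable responsible.  Constant meta-variables are skipped.
    """
    if not len(edges) or not env.variables:
        return edges
    envdf = env.aligned(m.data.columns)
    usable = []
    for var in envdf.columns:
        col = envdf[var].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.all(finite == finite[0]):
            logger.warning("meta-variable %s is constant/empty; skipped", var)
            continue
        usable.append(var)
    if not usable:
        return edges

    keep = []
    for _, row in edges.df.iterrows():
        x = m.data.loc[row["source"]].to_numpy(dtype=float)
        y = m.data.loc[row["target"]].to_numpy(dtype=float)
        survives = True
        for var in usable:
            z = envdf[var].to_numpy(dtype=float)
            r, n = _partial_rank_corr(x, y, z)
            if not np.isfinite(r):
                continue
            r = min(1.0, max(-1.0, r))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 3) / (1.0 - r ** 2))
                p = 2.0 * sps.t.sf(abs(t), df=n - 3)
            if p >= alpha:
                logger.info("edge %s--%s removed: not significant given %s "
                            "(partial rho=%.3f, p=%.3g)",
                            row["source"], row["target"], var, r, p)
                survives = False
                break
        if survives:
            keep.append(True)
        else:
            keep.append(False)
    return EdgeList(edges.df[np.asarray(keep, dtype=bool)].reset_index(drop=True))


def detect_env_associations(m: AbundanceMatrix, env: MetaVariableTable,
                            alpha: float = 0.01,
                            marker: str = "polB") -> pd.DataFrame:
    """Spearman tests of each focal-marker OTU against each meta-variable.

    Returns a frame (otu_id, variable, rho, p) for pairs with p < alpha.
    """
    rows = []
    if not env.variables:
        return pd.DataFrame(rows, columns=["otu_id", "variable", "rho", "p"])
    envdf = env.aligned(m.data.columns)
    markers = m.otu_markers if m.otu_markers is not None else \
        pd.Series(m.marker, index=m.data.index)
    for otu in m.data.index:
        if markers.loc[otu] != marker:
            continue
        x = m.data.loc[otu].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.info("skipping constant OTU %s", otu)
            continue
        for var in envdf.columns:
            z = envdf[var].to_numpy(dtype=float)
            mask = np.isfinite(z)
            if mask.sum() < 5 or np.all(z[mask] == z[mask][0]):
                continue
            rho, p = sps.spearmanr(x[mask], z[mask])
            if np.isfinite(rho) and p < alpha:
                rows.append((otu, var, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["otu_id", "variable", "rho", "p"])


def degree_stats(edges: EdgeList, focal_marker: str = "polB") -> DegreeSummary:
    """Cross-marker degree of each focal node, split by edge sign.

    Means are taken over focal nodes with at least one edge of the given
    sign, matching how per-network average degrees are usually reported.
    """
    df = edges.df
    counts: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        sm = row.get("source_marker")
        tm = row.get("target_marker")
        if sm == tm:
            continue  # within-marker edge: not a virus-eukaryote association
        for node, mk in ((row["source"], sm), (row["target"], tm)):
            if mk != focal_marker:
                continue
            rec = counts.setdefault(node, [0, 0])
            rec[0 if row["sign"] == "positive" else 1] += 1
    out = pd.DataFrame(
        [(otu, pos, neg) for otu, (pos, neg) in sorted(counts.items())],
        columns=["otu_id", "positive_degree", "negative_degree"]).set_index("otu_id")
    pos = out["positive_degree"][out["positive_degree"] >= 1]
    neg = out["negative_degree"][out["negative_degree"] >= 1]
    return DegreeSummary(
        df=out,
        mean_positive=float(pos.mean()) if len(pos) else float("nan"),
        mean_negative=float(neg.mean()) if len(neg) else float("nan"),
        isolated=[],
    )


def aggregate_network(edges: EdgeList, tax: TaxonomyTable,
                      virus_marker: str = "polB") -> AggregatedNetwork:
    """Collapse the OTU network to (viral family, eukaryotic group) counts.

    Unannotated endpoints are pooled under ``"unclassified"``; the total of
    pair counts equals the number of input edges.
    """
    counter: dict[tuple[str, str], list[int]] = {}
    members: dict[str, set[str]] = {}
    for _, row in edges.df.iterrows():
        if row.get("source_marker") == virus_marker:
            v, e = row["source"], row["target"]
        elif row.get("target_marker") == virus_marker:
            v, e = row["target"], row["source"]
        else:
            v, e = row["source"], row["target"]
        family = tax.viral_family(v)
        group = tax.major_lineage(e)
        rec = counter.setdefault((family, group), [0, 0])
        rec[0 if row["sign"] == "positive" else 1] += 1
        members.setdefault(family, set()).add(v)
        members.setdefault(group, set()).add(e)
    df = pd.DataFrame(
        [(f, g, pos, neg) for (f, g), (pos, neg) in sorted(counter.items())],
        columns=["family", "group", "count_positive", "count_negative"])
    sizes = pd.Series({k: len(v) for k, v in members.items()}, dtype=int).sort_index()
    return AggregatedNetwork(df, sizes)
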