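"""Abundance-table preparation ahead of network inference.

Stages: reconstruct read counts from relative abundances, add a pseudocount
and apply the centred log-ratio (clr) transform per sample, drop
low-abundance OTUs by a quartile rule, intersect sample sets across marker
matrices, and compute per-sample diversity indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, ValidationError

__all__ = [
    "FilterConfig", "GeneLengthTable", "DiversityResult",
    "relabund_to_counts", "clr_transform", "quartile_filter",
    "apply_retention", "intersect_and_merge", "diversity",
]

_QUANTILES = {"Q1": 0.25, "Q2": 0.50, "Q3": 0.75}


@dataclass(frozen=True)
class FilterConfig:
    """Low-abundance filtering rule: clr value above the chosen quartile of
    originally non-zero cells, in at least ``min_samples`` samples."""

    quantile: str = "Q1"
    min_samples: int = 5
    pseudocount: float = 1.0
    per_otu: bool = False  # compute the quantile per OTU instead of globally

    def __post_init__(self) -> None:
        if self.quantile not in _QUANTILES:
            raise ValueError(f"quantile must be one of {sorted(_QUANTILES)}")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class GeneLengthTable:
    """Per-OTU marker gene length (nt) plus the assumed sequencing read length."""

    lengths: pd.Series
    read_length: int = 100

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValidationError(f"non-positive gene length for otu {bad!r}")
        if self.read_length <= 0:
            raise ValidationError("read_length must be positive")


@dataclass
class DiversityResult:
    """Per-sample Shannon diversity (nats) and OTU richness."""

    df: pd.DataFrame  # index sample_id, columns shannon, richness
    empty_samples: list[str] = field(default_factory=list)


def relabund_to_counts(rel: AbundanceMatrix, lengths: GeneLengthTable,
                       per_sample_scale: float | pd.Series = 1e6) -> AbundanceMatrix:
    """Convert relative abundances back to approximate read counts.

    ``count = round(rel * gene_length / read_length * scale)``; the scale is
    per sample (scalar broadcast allowed).  Exact zeros stay zero.
    """
    if rel.unit != "relative":
        raise ValidationError(f"expected unit 'relative', got {rel.unit!r}")
    missing = [o for o in rel.data.index if o not in lengths.lengths.index]
    if missing:
        raise ValidationError(f"no gene length for otu {missing[0]!r}")
    lens = lengths.lengths.loc[rel.data.index].to_numpy(dtype=float)
    if np.isscalar(per_sample_scale):
        scale = np.full(rel.data.shape[1], float(per_sample_scale))
    else:
        scale = pd.Series(per_sample_scale).loc[rel.data.columns].to_numpy(dtype=float)
    counts = np.rint(rel.data.to_numpy(dtype=float)
                     * lens[:, None] / lengths.read_length * scale[None, :])
    out = AbundanceMatrix(
        pd.DataFrame(counts, index=rel.data.index, columns=rel.data.columns),
        marker=rel.marker, size_fraction=rel.size_fraction, unit="counts",
        otu_markers=rel.otu_markers)
    return out.validate()


def clr_transform(m: AbundanceMatrix, pseudocount: float = 1.0) -> AbundanceMatrix:
    """Centred log-ratio transform per sample after adding a pseudocount.

    For each sample column x: ``clr_i = ln(x_i + pc) - mean_k ln(x_k + pc)``.
    The composition is the full set of OTUs in the matrix.
    """
    if m.unit == "clr":
        raise ValidationError("matrix is already clr-transformed")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if m.data.size == 0:
        raise ValidationError("cannot clr-transform an empty matrix")
    logs = np.log(m.data.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    out = AbundanceMatrix(
        pd.DataFrame(clr, index=m.data.index, columns=m.data.columns),
        marker=m.marker, size_fraction=m.size_fraction, unit="clr",
        otu_markers=m.otu_markers)
    return out.validate()


def quartile_filter(counts: AbundanceMatrix, clr_m: AbundanceMatrix,
                    cfg: FilterConfig = FilterConfig()) -> set[str]:
    """OTUs whose clr abundance exceeds the chosen quartile often enough.

    The threshold is the ``cfg.quantile`` (linear-interpolation definition)
    of the clr values at cells that were non-zero in the original count
    matrix; by default it is computed globally over the whole matrix.  An
    OTU is retained when its clr value exceeds the threshold in at least
    ``cfg.min_samples`` samples.
    """
    if counts.data.shape != clr_m.data.shape or \
            list(counts.data.index) != list(clr_m.data.index) or \
            list(counts.data.columns) != list(clr_m.data.columns):
        raise ValidationError("count and clr matrices must share shape and ids")
    cvals = counts.data.to_numpy(dtype=float)
    zvals = clr_m.data.to_numpy(dtype=float)
    nonzero = cvals > 0
    if not nonzero.any():
        raise ValidationError("no non-zero counts; cannot set a filter threshold")
    q = _QUANTILES[cfg.quantile]
    if cfg.per_otu:
        retained = set()
        for i, otu in enumerate(counts.data.index):
            mask = nonzero[i]
            if not mask.any():
                continue
            thr = float(np.quantile(zvals[i][mask], q))
            if int((zvals[i] > thr).sum()) >= cfg.min_samples:
                retained.add(otu)
        return retained
    threshold = float(np.quantile(zvals[nonzero], q))
    above = (zvals > threshold).sum(axis=1)
    return {otu for otu, n in zip(counts.data.index, above)
            if n >= cfg.min_samples}


def apply_retention(m: AbundanceMatrix, retained: set[str]) -> AbundanceMatrix:
    """Row-subset a matrix to the retained OTUs (order preserved)."""
    keep = [o for o in m.data.index if o in retained]
    markers = m.otu_markers.loc[keep] if m.otu_markers is not None else None
    return AbundanceMatrix(m.data.loc[keep], marker=m.marker,
                           size_fraction=m.size_fraction, unit=m.unit,
                           otu_markers=markers)


def intersect_and_merge(a: AbundanceMatrix, b: AbundanceMatrix) -> AbundanceMatrix:
    """Stack two marker matrices over their shared samples.

    Sample set = intersection (sorted); rows = rows(a) followed by rows(b).
    OTU id spaces must be disjoint.  Units must match.
    """
    if a.unit != b.unit:
        raise ValidationError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
    overlap = set(a.data.index) & set(b.data.index)
    if overlap:
        raise ValidationError(f"otu id spaces overlap: {sorted(overlap)[:5]}")
    shared = sorted(set(a.data.columns) & set(b.data.columns))
    if not shared:
        raise ValidationError("no shared samples between the two matrices")
    data = pd.concat([a.data[shared], b.data[shared]], axis=0)
    markers = pd.concat([
        a.otu_markers if a.otu_markers is not None else pd.Series(a.marker, index=a.data.index),
        b.otu_markers if b.otu_markers is not None else pd.Series(b.marker, index=b.data.index),
    ])
    frac = a.size_fraction if a.size_fraction == b.size_fraction else \
        f"{a.size_fraction}+{b.size_fraction}"
    return AbundanceMatrix(data, marker="merged", size_fraction=frac,
                           unit=a.unit, otu_markers=markers.loc[data.index])


def diversity(counts: AbundanceMatrix) -> DiversityResult:
    """Shannon diversity (natural log) and richness per sample."""
    if counts.unit != "counts":
        raise ValidationError(f"expected unit 'counts', got {counts.unit!r}")
    vals = counts.data.to_numpy(dtype=float)
    rows = []
    empty = []
    for j, sample in enumerate(counts.data.columns):
        x = vals[:, j]
        total = x.sum()
        richness = int((x > 0).sum())
        if total == 0:
            shannon = 0.0
            empty.append(sample)
        else:
            p = x[x > 0] / total
            shannon = float(-(p * np.log(p)).sum())
        rows.append((sample, shannon, richness))
    df = pd.DataFrame(rows, columns=["sample_id", "shannon", "richness"])
    df = df.set_index("sample_id")
    return DiversityResult(df, empty_samples=empty)
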