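"""Shared domain containers for the co-occurrence pipeline.

All tabular containers are thin dataclass wrappers around pandas objects so
that downstream modules can rely on validated invariants (no duplicate ids,
weights within [-1, 1], signs consistent with weights, ...) instead of
re-checking raw frames everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MARKERS = ("polB", "V9", "MCP", "merged")
UNITS = ("counts", "relative", "clr")

#: Column layout of an edge table on disk and in memory.
EDGE_COLUMNS = ["source", "target", "weight", "p_value", "sign", "size_fraction"]

#: Optional endpoint annotation used by degree/aggregation summaries.
EDGE_MARKER_COLUMNS = ["source_marker", "target_marker"]

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity",
               "percent_query_coverage", "e_value", "bitscore"]

TAXONOMY_COLUMNS = ["major_lineage", "ncbi_order", "ncbi_class",
                    "ncbi_phylum", "viral_family"]


class ValidationError(ValueError):
    """An input violated a container invariant."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class AbundanceMatrix:
    """OTU x sample abundance table with marker and size-fraction metadata.

    ``data`` has OTU ids as the index and sample ids as columns.  ``unit``
    records whether cells are raw/reconstructed read counts, relative
    abundances, or clr-transformed values.  ``otu_markers`` maps each OTU to
    its marker gene; it is filled automatically for single-marker matrices
    and is required for merged (polB + V9) matrices.
    """

    data: pd.DataFrame
    marker: str
    size_fraction: str = ""
    unit: str = "counts"
    otu_markers: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        _check_unique(self.data.index, "otu_ids")
        _check_unique(self.data.columns, "sample_ids")
        if self.otu_markers is None and self.marker != "merged":
            self.otu_markers = pd.Series(self.marker, index=self.data.index)
        if self.marker == "merged" and self.otu_markers is None:
            raise ValidationError("merged matrix requires otu_markers")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self, check_clr_sum: bool = True) -> "AbundanceMatrix":
        """Enforce value invariants.

        ``check_clr_sum`` is disabled when validating a clr matrix that has
        been row-subset after transformation (the per-sample zero-sum
        identity only holds for a full composition).
        """
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at otu {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}")
        if self.unit != "clr" and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at otu {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}")
        if self.unit == "clr" and check_clr_sum and values.size:
            sums = values.sum(axis=0)
            if np.abs(sums).max() > 1e-9 * max(1.0, np.abs(values).max()):
                j = int(np.abs(sums).argmax())
                raise ValidationError(
                    f"clr column {self.data.columns[j]!r} sums to "
                    f"{sums[j]:.3g}, expected 0")
        return self


@dataclass
class EdgeList:
    """Weighted signed associations between OTUs (the network).

    Wraps a frame with columns ``source, target, weight, p_value, sign,
    size_fraction`` (plus optional ``source_marker``/``target_marker``).
    Weights lie in [-1, 1], the sign column matches the weight sign, there
    are no self-edges, and each unordered pair occurs at most once per size
    fraction.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in EDGE_COLUMNS:
            if col not in df.columns:
                if col == "p_value":
                    df[col] = np.nan
                elif col == "size_fraction":
                    df[col] = ""
                elif col == "sign" and len(df):
                    df[col] = np.where(df["weight"] > 0, "positive", "negative")
                elif col == "sign":
                    df[col] = pd.Series(dtype=object)
                else:
                    raise ValidationError(f"edge table missing column {col!r}")
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if not len(df):
            return
        w = df["weight"].to_numpy(dtype=float)
        if np.abs(w).max() > 1.0 + 1e-12:
            bad = df.iloc[int(np.abs(w).argmax())]
            raise ValidationError(
                f"edge {bad['source']}--{bad['target']} weight {bad['weight']} "
                "outside [-1, 1]")
        expected = np.where(w > 0, "positive", "negative")
        mism = df.index[expected != df["sign"].to_numpy()]
        if len(mism):
            bad = df.loc[mism[0]]
            raise ValidationError(
                f"edge {bad['source']}--{bad['target']}: sign {bad['sign']!r} "
                f"inconsistent with weight {bad['weight']}")
        selfs = df.index[df["source"] == df["target"]]
        if len(selfs):
            raise ValidationError(f"self-edge on {df.loc[selfs[0], 'source']!r}")
        key = [tuple(sorted((s, t))) + (f,) for s, t, f in
               zip(df["source"], df["target"], df["size_fraction"])]
        _check_unique(key, "edges (unordered pair within size fraction)")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records, size_fraction: str = "") -> "EdgeList":
        """Build from (source, target, weight[, p_value]) tuples."""
        rows = []
        for rec in records:
            src, tgt, w = rec[0], rec[1], float(rec[2])
            p = float(rec[3]) if len(rec) > 3 else np.nan
            rows.append((src, tgt, w, p,
                         "positive" if w > 0 else "negative", size_fraction))
        return cls(pd.DataFrame(rows, columns=EDGE_COLUMNS))


@dataclass
class TaxonomyTable:
    """OTU -> taxonomy lookup (major lineage, NCBI ranks, viral family)."""

    df: pd.DataFrame
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "taxonomy otu_ids")
        for col in TAXONOMY_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = pd.NA
        if self.vocabulary is not None:
            vocab = set(self.vocabulary) | {"unclassified"}
            lineages = self.df["major_lineage"].dropna()
            bad = lineages[~lineages.isin(vocab)]
            if len(bad):
                raise ValidationError(
                    f"major lineage {bad.iloc[0]!r} of otu {bad.index[0]!r} "
                    "not in the supplied vocabulary")

    def major_lineage(self, otu: str) -> str:
        if otu in self.df.index:
            val = self.df.at[otu, "major_lineage"]
            if pd.notna(val):
                return str(val)
        return "unclassified"

    def viral_family(self, otu: str) -> str:
        if otu in self.df.index:
            val = self.df.at[otu, "viral_family"]
            if pd.notna(val):
                return str(val)
        return "unclassified"

    def rank_label(self, otu: str, rank: str) -> str:
        if rank not in ("major_lineage", "ncbi_order", "ncbi_class", "ncbi_phylum"):
            raise ValueError(f"unknown rank {rank!r}")
        if otu in self.df.index:
            val = self.df.at[otu, rank]
            if pd.notna(val):
                return str(val)
        return "unclassified"


@dataclass
class HitTable:
    """Tabular homology-search hits (query, subject, identity, coverage, ...)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HIT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in HIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"hit table missing columns {missing}")
        for col in ("percent_identity", "percent_query_coverage"):
            vals = df[col].to_numpy(dtype=float)
            if len(vals) and (vals.min() < 0 or vals.max() > 100):
                i = int(np.argmax((vals < 0) | (vals > 100)))
                raise ValidationError(
                    f"hit {df.iloc[i]['query_id']}->{df.iloc[i]['subject_id']}: "
                    f"{col} = {vals[i]} outside [0, 100]")
        for col in ("e_value", "bitscore"):
            vals = df[col].to_numpy(dtype=float)
            if len(vals) and vals.min() < 0:
                i = int(np.argmin(vals))
                raise ValidationError(
                    f"hit {df.iloc[i]['query_id']}->{df.iloc[i]['subject_id']}: "
                    f"negative {col}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ReferenceHostTable:
    """Known virus-host pairs: (reference virus, viral family, host lineage)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["reference_virus_id", "viral_family", "host_major_lineage"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"reference table missing columns {missing}")
        key = list(zip(self.df["reference_virus_id"], self.df["host_major_lineage"]))
        _check_unique(key, "(reference virus, host lineage) pairs")

    def hosts_of(self, reference_virus_id: str) -> list[str]:
        sel = self.df[self.df["reference_virus_id"] == reference_virus_id]
        return sorted(sel["host_major_lineage"])

    @property
    def reference_ids(self) -> set[str]:
        return set(self.df["reference_virus_id"])


@dataclass
class MetaVariableTable:
    """Per-sample environmental covariates; missing values stay as NaN."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "meta-variable sample_ids")

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    def aligned(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise ValidationError(
                f"meta-variable table lacks samples {missing[:5]}")
        return self.df.loc[list(sample_ids)]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN over the (virus OTU, major lineage) candidate universe.

    Derived diagnostics follow the standard definitions: sensitivity
    TP/(TP+FN), specificity TN/(TN+FP), and the positive likelihood ratio
    LR+ = sensitivity / (1 - specificity).  Boundary cases return the
    sentinels ``inf`` (perfect specificity with nonzero sensitivity) or
    ``nan`` (undefined).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def lr_plus(self) -> float:
        from .validation import lr_plus
        return lr_plus(self)

    @property
    def fdr(self) -> float:
        from .validation import fdr
        return fdr(self)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a/b/c/d counts for a one-sided enrichment test.

    ``a`` = in-group associated, ``b`` = in-group not associated,
    ``c`` = out-group associated, ``d`` = out-group not associated.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """One (unit, taxon) enrichment test with raw and BH-adjusted p-values."""

    unit_id: str
    taxon: tuple[str, str]  # (rank, label)
    table: ContingencyTable2x2
    p: float
    q: float
    significant: bool
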