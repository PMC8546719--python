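import math

import numpy as np
import pandas as pd
import pytest

from vhoc.containers import (
    ConfusionMatrix,
    HitTable,
    ReferenceHostTable,
    TaxonomyTable,
    ValidationError,
)
from vhoc.validation import (
    GroupingConfig,
    assign_reference_groups,
    condition_positive_pairs,
    confusion,
    fdr,
    lr_plus,
    reduce_best_edges,
    sweep_cutoffs,
)
from conftest import make_edges


def hits_table(rows):
    return HitTable(pd.DataFrame(rows, columns=[
        "query_id", "subject_id", "percent_identity",
        "percent_query_coverage", "e_value", "bitscore"]))


REF = ReferenceHostTable(pd.DataFrame(
    [("r1", "Mimiviridae", "Haptophyta"),
     ("r2", "Phycodnaviridae", "Mamiellophyceae"),
     ("r2", "Phycodnaviridae", "Chlorarachnea"),
     ("r3", "Iridoviridae", "Metazoa")],
    columns=["reference_virus_id", "viral_family", "host_major_lineage"]))


class TestReferenceGrouping:
    def test_best_hit_by_bitscore(self):
        hits = hits_table([("q1", "r1", 70.0, 90.0, 1e-50, 200),
                           ("q1", "r2", 68.0, 90.0, 1e-40, 150)])
        assert assign_reference_groups(hits) == {"q1": "r1"}

    def test_below_identity_threshold_unassigned(self):
        hits = hits_table([("q1", "r1", 60.0, 90.0, 1e-50, 200)])
        assert assign_reference_groups(hits) == {}
        assert assign_reference_groups(
            hits, GroupingConfig(identity_threshold=55)) == {"q1": "r1"}

    def test_empty_hits(self):
        assert assign_reference_groups(hits_table([])) == {}

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(30)
        rows = [(f"q{rng.integers(3)}", f"r{i}", float(rng.uniform(50, 95)),
                 90.0, 1e-30, float(rng.uniform(100, 300))) for i in range(10)]
        got = assign_reference_groups(hits_table(rows))
        oracle = {}
        for q in {r[0] for r in rows}:
            cand = [r for r in rows if r[0] == q]
            best = max(cand, key=lambda r: (r[5], r[2],
                                            [-ord(ch) for ch in r[1]]))
            if best[2] >= 65.0:
                oracle[q] = best[1]
        assert got == oracle


class TestConditionPositives:
    def test_single_host(self):
        assert condition_positive_pairs({"q1": "r1"}, REF) == {("q1", "Haptophyta")}

    def test_reference_with_two_hosts_gives_two_pairs(self):
        assert condition_positive_pairs({"q1": "r2"}, REF) == {
            ("q1", "Mamiellophyceae"), ("q1", "Chlorarachnea")}

    def test_empty_assignment(self):
        assert condition_positive_pairs({}, REF) == set()

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValidationError, match="r99"):
            condition_positive_pairs({"q1": "r99"}, REF)


class TestReduceBestEdges:
    def test_keeps_highest_absolute_weight(self, toy_taxonomy):
        edges = make_edges([("v1", "e1", 0.3), ("v1", "e2", 0.7)])
        reduced = reduce_best_edges(edges, toy_taxonomy)
        assert len(reduced) == 1
        assert reduced.iloc[0]["weight"] == 0.7
        assert reduced.iloc[0]["lineage"] == "Haptophyta"

    def test_one_edge_per_sign(self, toy_taxonomy):
        edges = make_edges([("v1", "e1", 0.3), ("v1", "e2", -0.6)])
        reduced = reduce_best_edges(edges, toy_taxonomy)
        assert set(reduced["sign"]) == {"positive", "negative"}

    def test_matches_group_by_max_oracle(self, toy_taxonomy):
        rng = np.random.default_rng(31)
        euks, viruses = ["e1", "e2", "e3"], ["v1", "v2"]
        records, seen = [], set()
        while len(records) < 6:
            v, e = rng.choice(viruses), rng.choice(euks)
            if (v, e) in seen:
                continue
            seen.add((v, e))
            records.append((v, e, float(rng.uniform(-1, 1))))
        reduced = reduce_best_edges(make_edges(records), toy_taxonomy)
        oracle = {}
        for v, e, w in records:
            lin = toy_taxonomy.major_lineage(e)
            key = (v, lin, "positive" if w > 0 else "negative")
            cur = oracle.get(key)
            if cur is None or (abs(w), w, [-ord(c) for c in e]) > \
                    (abs(cur[1]), cur[1], [-ord(c) for c in cur[0]]):
                oracle[key] = (e, w)
        got = {(r["source"], r["lineage"], r["sign"]): (r["eukaryote"], r["weight"])
               for _, r in reduced.iterrows()}
        assert got == oracle


class TestConfusion:
    LINEAGES = ["Haptophyta", "Metazoa", "Dinophyceae"]

    def predicted(self):
        # v1 hosts Haptophyta; v2 hosts Metazoa
        return pd.DataFrame({
            "source": ["v1", "v1", "v2"],
            "lineage": ["Haptophyta", "Dinophyceae", "Haptophyta"],
            "weight": [0.8, 0.5, 0.6],
            "sign": ["positive"] * 3,
            "eukaryote": ["e1", "e2", "e3"],
        })

    POSITIVES = {("v1", "Haptophyta"), ("v2", "Metazoa")}

    def test_six_pair_universe_hand_enumeration(self):
        cm = confusion(self.predicted(), self.POSITIVES, self.LINEAGES,
                       ["v1", "v2"])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 2, 1, 2)
        assert cm.sensitivity == pytest.approx(0.5)
        assert cm.fpr == pytest.approx(0.5)
        assert lr_plus(cm) == pytest.approx(1.0)

    def test_no_predictions(self):
        empty = self.predicted().iloc[:0]
        cm = confusion(empty, self.POSITIVES, self.LINEAGES, ["v1", "v2"])
        assert (cm.tp, cm.fp, cm.fn) == (0, 0, 2)
        assert math.isnan(lr_plus(cm))

    def test_cutoff_above_max_weight_equals_no_predictions(self):
        cm = confusion(self.predicted(), self.POSITIVES, self.LINEAGES,
                       ["v1", "v2"], weight_cutoff=0.9)
        assert (cm.tp, cm.fp) == (0, 0)

    def test_universe_total_conserved(self):
        cm = confusion(self.predicted(), self.POSITIVES, self.LINEAGES,
                       ["v1", "v2"])
        assert cm.total == 2 * 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            confusion(self.predicted(), self.POSITIVES, [], ["v1"])


class TestDiagnostics:
    def test_lr_plus_closed_form(self):
        assert lr_plus(ConfusionMatrix(1, 1, 1, 3)) == pytest.approx(2.0)

    def test_lr_plus_infinite_when_fpr_zero(self):
        assert lr_plus(ConfusionMatrix(1, 0, 0, 5)) == math.inf

    def test_lr_plus_undefined_without_positives(self):
        assert math.isnan(lr_plus(ConfusionMatrix(0, 2, 0, 4)))

    def test_fdr_values(self):
        assert fdr(ConfusionMatrix(1, 11, 0, 0)) == pytest.approx(11 / 12)
        assert fdr(ConfusionMatrix(5, 0, 0, 0)) == 0.0
        assert fdr(ConfusionMatrix(1, 3, 0, 0)) == pytest.approx(0.75)

    def test_fdr_undefined_without_predictions(self):
        assert math.isnan(fdr(ConfusionMatrix(0, 0, 3, 4)))


class TestSweep:
    def test_single_cutoff_matches_confusion(self):
        tc = TestConfusion()
        sweep = sweep_cutoffs(tc.predicted(), tc.POSITIVES, tc.LINEAGES,
                              ["v1", "v2"], [0.0])
        cm = confusion(tc.predicted(), tc.POSITIVES, tc.LINEAGES, ["v1", "v2"])
        row = sweep.iloc[0]
        assert (row["TP"], row["FP"], row["FN"], row["TN"]) == \
            (cm.tp, cm.fp, cm.fn, cm.tn)

    def test_rows_match_independent_confusion_calls(self):
        tc = TestConfusion()
        sweep = sweep_cutoffs(tc.predicted(), tc.POSITIVES, tc.LINEAGES,
                              ["v1", "v2"], [0.0, 0.55])
        for _, row in sweep.iterrows():
            cm = confusion(tc.predicted(), tc.POSITIVES, tc.LINEAGES,
                           ["v1", "v2"], weight_cutoff=row["weight_cutoff"])
            assert row["TP"] == cm.tp and row["FP"] == cm.fp

    def test_n_edges_non_increasing(self):
        rng = np.random.default_rng(32)
        tax = TaxonomyTable(pd.DataFrame(
            {"major_lineage": ["Haptophyta", "Metazoa"]},
            index=pd.Index(["e1", "e2"], name="otu_id")))
        records = [(f"v{i}", e, float(rng.uniform(-1, 1)))
                   for i in range(10) for e in ("e1", "e2")]
        reduced = reduce_best_edges(make_edges(records), tax)
        sweep = sweep_cutoffs(reduced, set(), ["Haptophyta", "Metazoa"],
                              [f"v{i}" for i in range(10)],
                              list(np.linspace(0, 1, 11)))
        assert (np.diff(sweep["n_edges"]) <= 0).all()

    def test_unsorted_grid_rejected(self):
        tc = TestConfusion()
        with pytest.raises(ValidationError):
            sweep_cutoffs(tc.predicted(), tc.POSITIVES, tc.LINEAGES,
                          ["v1"], [0.5, 0.0])
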