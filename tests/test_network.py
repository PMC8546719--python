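import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vhoc.containers import AbundanceMatrix, MetaVariableTable
from vhoc.network import (
    NetworkConfig,
    aggregate_network,
    degree_stats,
    detect_env_associations,
    metavar_condition,
    spearman_network,
)
from conftest import make_edges, make_matrix


def merged_matrix(polb_rows, v9_rows, n=None):
    polb = np.atleast_2d(np.asarray(polb_rows, dtype=float))
    v9 = np.atleast_2d(np.asarray(v9_rows, dtype=float))
    data = np.vstack([polb, v9])
    otus = [f"p{i}" for i in range(len(polb))] + [f"v{i}" for i in range(len(v9))]
    samples = [f"s{j}" for j in range(data.shape[1])]
    markers = pd.Series(["polB"] * len(polb) + ["V9"] * len(v9), index=otus)
    return AbundanceMatrix(pd.DataFrame(data, index=otus, columns=samples),
                           marker="merged", otu_markers=markers)


def rank_rho_oracle(x, y):
    """Explicit rank-statistic formula with average ties."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestSpearmanNetwork:
    def test_perfect_monotone_retained(self):
        x = np.arange(10)
        edges = spearman_network(merged_matrix([x], [x ** 2 + 1]))
        assert len(edges) == 1
        row = edges.df.iloc[0]
        assert row["weight"] == pytest.approx(1.0)
        assert row["sign"] == "positive"
        assert row["p_value"] == 0.0

    def test_decreasing_is_negative(self):
        x = np.arange(10, dtype=float)
        edges = spearman_network(merged_matrix([x], [-x]))
        assert edges.df.iloc[0]["weight"] == pytest.approx(-1.0)
        assert edges.df.iloc[0]["sign"] == "negative"

    def test_rho_matches_rank_formula_with_ties(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([5, 6, 7, 8, 7], dtype=float)
        edges = spearman_network(merged_matrix([x], [y]),
                                 NetworkConfig(alpha=0.999))
        assert edges.df.iloc[0]["weight"] == pytest.approx(
            rank_rho_oracle(x, y), abs=1e-12)

    def test_oracle_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            x = rng.integers(0, 8, 20).astype(float)
            y = rng.integers(0, 8, 20).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            edges = spearman_network(merged_matrix([x], [y]),
                                     NetworkConfig(alpha=0.999999))
            assert edges.df.iloc[0]["weight"] == pytest.approx(
                rank_rho_oracle(x, y), abs=1e-12)

    def test_constant_profile_skipped(self):
        edges = spearman_network(
            merged_matrix([np.ones(8)], [np.arange(8)]),
            NetworkConfig(alpha=0.999))
        assert len(edges) == 0

    def test_cross_group_only_excludes_within_marker(self):
        rng = np.random.default_rng(21)
        m = merged_matrix(rng.normal(size=(3, 12)), rng.normal(size=(3, 12)))
        edges = spearman_network(m, NetworkConfig(alpha=0.9999))
        pairs = set(zip(edges.df["source_marker"], edges.df["target_marker"]))
        assert all(a != b for a, b in pairs)

    def test_invariant_to_sample_and_otu_order(self):
        rng = np.random.default_rng(22)
        m = merged_matrix(rng.normal(size=(4, 15)), rng.normal(size=(4, 15)))
        base = spearman_network(m, NetworkConfig(alpha=0.2))
        perm_s = rng.permutation(m.data.columns)
        perm_o = rng.permutation(m.data.index)
        m2 = AbundanceMatrix(m.data.loc[perm_o, perm_s], marker="merged",
                             otu_markers=m.otu_markers.loc[perm_o])
        other = spearman_network(m2, NetworkConfig(alpha=0.2))
        key = lambda e: sorted(
            (tuple(sorted((r["source"], r["target"]))), round(r["weight"], 12))
            for _, r in e.df.iterrows())
        assert key(base) == key(other)

    def test_too_few_samples_rejected(self):
        with pytest.raises(Exception):
            spearman_network(merged_matrix([[1, 2, 3]], [[3, 2, 1]]))


class TestMetavarCondition:
    def _env(self, samples, **cols):
        return MetaVariableTable(pd.DataFrame(cols, index=list(samples)))

    def test_confounded_edge_removed(self):
        n = 40
        rng = np.random.default_rng(23)
        z = rng.normal(size=n)
        x, y = np.exp(z), 2 * z + 5  # exact monotone functions of z
        m = merged_matrix([x - x.min()], [y - y.min()])
        edges = spearman_network(m, NetworkConfig(alpha=0.01))
        assert len(edges) == 1
        out = metavar_condition(edges, m, self._env(m.sample_ids, depth=z))
        assert len(out) == 0

    def test_independent_metavar_keeps_edge(self):
        n = 100
        rng = np.random.default_rng(24)
        x = rng.normal(size=n)
        y = x + 0.3 * rng.normal(size=n)
        z = rng.normal(size=n)
        m = merged_matrix([x - x.min()], [y - y.min()])
        edges = spearman_network(m, NetworkConfig(alpha=0.01))
        out = metavar_condition(edges, m, self._env(m.sample_ids, noise=z))
        assert len(out) == 1

    def test_empty_table_is_identity(self):
        m = merged_matrix([np.arange(10)], [np.arange(10) ** 2])
        edges = spearman_network(m, NetworkConfig(alpha=0.05))
        env = MetaVariableTable(pd.DataFrame(index=list(m.sample_ids)))
        assert metavar_condition(edges, m, env).df.equals(edges.df)


class TestEnvAssociations:
    def test_copy_of_temperature_reported(self):
        rng = np.random.default_rng(25)
        temp = rng.uniform(0, 30, 20)
        m = merged_matrix([temp], [rng.normal(size=20)])
        env = MetaVariableTable(
            pd.DataFrame({"temperature": temp}, index=list(m.sample_ids)))
        out = detect_env_associations(m, env, alpha=0.01)
        assert len(out) == 1
        assert out.iloc[0]["otu_id"] == "p0"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_empty_env_table(self):
        m = merged_matrix([np.arange(10)], [np.arange(10)])
        env = MetaVariableTable(pd.DataFrame(index=list(m.sample_ids)))
        assert len(detect_env_associations(m, env)) == 0

    def test_null_false_report_rate(self):
        # 20 OTUs x 5 variables at alpha 0.01: about one false report expected
        rng = np.random.default_rng(26)
        reports = 0
        for _ in range(20):
            m = merged_matrix(rng.normal(size=(20, 30)), rng.normal(size=(1, 30)))
            env = MetaVariableTable(pd.DataFrame(
                rng.normal(size=(30, 5)), index=list(m.sample_ids),
                columns=list("abcde")))
            reports += len(detect_env_associations(m, env, alpha=0.01))
        assert 0 < reports < 60  # mean 1 per replicate, generous band


MARKERS = {"p1": "polB", "p2": "polB", "p3": "polB",
           "v1": "V9", "v2": "V9", "v3": "V9"}


class TestDegreeStats:
    def test_sign_split(self):
        edges = make_edges([("p1", "v1", 0.5), ("p1", "v2", 0.2),
                            ("p1", "v3", -0.1)], markers=MARKERS)
        summary = degree_stats(edges)
        assert summary.df.loc["p1", "positive_degree"] == 2
        assert summary.df.loc["p1", "negative_degree"] == 1

    def test_mean_over_connected_nodes(self):
        edges = make_edges(
            [("p1", "v1", 0.5),
             ("p2", "v1", 0.5), ("p2", "v2", 0.5),
             ("p3", "v1", 0.5), ("p3", "v2", 0.5), ("p3", "v3", 0.5)],
            markers=MARKERS)
        assert degree_stats(edges).mean_positive == pytest.approx(2.0)

    def test_isolated_node_absent(self):
        edges = make_edges([("p1", "v1", 0.5)], markers=MARKERS)
        assert "p2" not in degree_stats(edges).df.index


class TestAggregateNetwork:
    def test_counts_and_conservation(self, toy_taxonomy):
        markers = {"v1": "polB", "v2": "polB", "e1": "V9", "e2": "V9", "e3": "V9"}
        edges = make_edges([("v1", "e1", 0.5), ("v1", "e2", 0.4),
                            ("v2", "e3", -0.2)], markers=markers)
        agg = aggregate_network(edges, toy_taxonomy)
        row = agg.df[(agg.df["family"] == "Mimiviridae")
                     & (agg.df["group"] == "Haptophyta")].iloc[0]
        assert row["count_positive"] == 2
        assert (agg.df["count_positive"].sum() + agg.df["count_negative"].sum()
                == len(edges))

    def test_unannotated_pooled_as_unclassified(self, toy_taxonomy):
        markers = {"v1": "polB", "x9": "V9"}
        edges = make_edges([("v1", "x9", 0.3)], markers=markers)
        agg = aggregate_network(edges, toy_taxonomy)
        assert agg.df.iloc[0]["group"] == "unclassified"
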