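import numpy as np
import pandas as pd
import pytest

from vhoc.containers import AbundanceMatrix, EdgeList, TaxonomyTable


@pytest.fixture
def toy_taxonomy():
    """Three eukaryotes in two lineages, two viruses in two families."""
    df = pd.DataFrame(
        {
            "major_lineage": ["Haptophyta", "Haptophyta", "Metazoa",
                              None, None],
            "viral_family": [None, None, None, "Mimiviridae", "Iridoviridae"],
        },
        index=pd.Index(["e1", "e2", "e3", "v1", "v2"], name="otu_id"))
    return TaxonomyTable(df)


def make_edges(records, size_fraction="", markers=None):
    """EdgeList from (source, target, weight) tuples, optional marker map."""
    edges = EdgeList.from_records(records, size_fraction=size_fraction)
    if markers is not None:
        edges.df["source_marker"] = edges.df["source"].map(markers)
        edges.df["target_marker"] = edges.df["target"].map(markers)
    return edges


def make_matrix(values, otus=None, samples=None, marker="polB", unit="counts"):
    arr = np.asarray(values, dtype=float)
    otus = otus or [f"o{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=otus, columns=samples),
                          marker=marker, unit=unit)
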