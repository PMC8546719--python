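"""Synthetic paired virus/eukaryote communities with planted interactions.

The generator emulates the statistical structure the pipeline assumes in
ocean survey data: zero-inflated lognormal OTU abundances, a subset of
viruses positively coupled to one host each (Gaussian copula with a target
rank correlation), host-lineage preference inherited along a random viral
tree (related viruses infect related hosts), homology hits that place
coupled viruses above the reference-grouping identity threshold with
decoys below it, and environmental covariates with an optional confounder.
Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    ConfusionMatrix,
    HitTable,
    MetaVariableTable,
    ReferenceHostTable,
    TaxonomyTable,
)
from .io import _finalize_tree

__all__ = ["SynthParams", "SyntheticTruth", "SyntheticDataset", "generate",
           "truth_confusion", "DEFAULT_LINEAGES", "DEFAULT_FAMILIES"]

#: Eukaryotic "major lineage" vocabulary used for synthetic host labels.
DEFAULT_LINEAGES = (
    "Haptophyta", "Dinophyceae", "Bacillariophyta", "Mamiellophyceae",
    "Metazoa", "Ciliophora", "Cryptophyta", "Pelagophyceae",
    "Chlorarachnea", "Collodaria", "MAST-3", "Foraminifera",
)

DEFAULT_FAMILIES = (
    "Mimiviridae", "Phycodnaviridae", "Iridoviridae", "Asfarviridae",
    "Marseilleviridae", "Ascoviridae", "Poxviridae",
)


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults define the standard benchmark conditions."""

    n_samples: int = 88
    n_hosts: int = 150
    n_viruses: int = 100
    n_lineages: int = 12
    n_families: int = 4
    frac_coupled: float = 0.4
    coupling_strength: float = 0.8
    occupancy: float = 0.5
    clade_host_fidelity: float = 0.9
    identity_true: tuple[float, float] = (66.0, 95.0)
    identity_decoy: tuple[float, float] = (30.0, 60.0)
    log_mean: float = 2.0
    log_sd: float = 1.0
    n_confounded: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_coupled", "coupling_strength", "occupancy",
                     "clade_host_fidelity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for rng_name in ("identity_true", "identity_decoy"):
            lo, hi = getattr(self, rng_name)
            if not 0 <= lo <= hi <= 100:
                raise ValueError(f"{rng_name} must be an ordered range in [0, 100]")
        if self.n_lineages > len(DEFAULT_LINEAGES):
            raise ValueError(f"at most {len(DEFAULT_LINEAGES)} lineages supported")
        if self.n_families > len(DEFAULT_FAMILIES):
            raise ValueError(f"at most {len(DEFAULT_FAMILIES)} families supported")
        if round(self.frac_coupled * self.n_viruses) < 1:
            raise ValueError("infeasible: frac_coupled * n_viruses < 1")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure."""

    pairs: list[tuple[str, str, str]]  # (virus_otu, host_otu, host_lineage)
    reference_assignment: dict[str, str]  # virus_otu -> reference id
    families: dict[str, str]  # virus_otu -> viral family
    host_lineages: dict[str, str]  # host_otu -> major lineage
    virus_preferences: dict[str, str]  # virus leaf -> preferred lineage


@dataclass
class SyntheticDataset:
    polb: AbundanceMatrix
    v9: AbundanceMatrix
    taxonomy: TaxonomyTable
    reference_hosts: ReferenceHostTable
    hits: HitTable
    tree: dendropy.Tree
    metavariables: MetaVariableTable
    truth: SyntheticTruth


def _random_tree(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random bifurcating topology by iterative random joining."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        node.edge.length = float(rng.exponential(0.1))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(0.1))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.pop(j)
        nodes.pop(i)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    return _finalize_tree(tree)


def _inherit_preferences(tree: dendropy.Tree, lineages: list[str],
                         fidelity: float, rng: np.random.Generator) -> dict[str, str]:
    """Assign a preferred host lineage to every leaf by descent with switching.

    Each child clade keeps its parent's lineage with probability
    ``fidelity``; a switch jumps to a lineage drawn without replacement
    from those not yet used in the tree (refilling when exhausted), so a
    host lineage occupies one contiguous region rather than recurring in
    distant subtrees — the phylogenetically clustered host preference the
    tree filter exploits.
    """
    prefs: dict[str, str] = {}
    bag: list[str] = []

    def draw(exclude: str | None) -> str:
        nonlocal bag
        for _ in range(2):
            while bag:
                candidate = bag.pop()
                if candidate != exclude:
                    return candidate
            bag = list(rng.permutation(lineages))
        others = [l for l in lineages if l != exclude] or list(lineages)
        return str(rng.choice(others))

    root = tree.seed_node
    root._lineage = draw(None)
    for node in tree.preorder_node_iter():
        if node is not root:
            parent_lineage = node.parent_node._lineage
            if rng.random() < fidelity or len(lineages) == 1:
                node._lineage = parent_lineage
            else:
                node._lineage = draw(parent_lineage)
        if node.is_leaf():
            prefs[node.taxon.label] = node._lineage
    return prefs


def _family_partition(tree: dendropy.Tree, n_families: int,
                      families: tuple[str, ...]) -> dict[str, str]:
    """Split the tree into ``n_families`` disjoint clades, one per family."""
    frontier = [tree.seed_node]
    while len(frontier) < n_families:
        splittable = [n for n in frontier if not n.is_leaf()]
        if not splittable:
            break
        biggest = max(splittable, key=lambda n: len(n.leaf_nodes()))
        frontier.remove(biggest)
        frontier.extend(biggest.child_nodes())
    frontier.sort(key=lambda n: -len(n.leaf_nodes()))
    out: dict[str, str] = {}
    for fam, node in zip(families, frontier):
        for leaf in node.leaf_iter():
            out[leaf.taxon.label] = fam
    return out


def _select_coupled(tree: dendropy.Tree, prefs: dict[str, str], n_coupled: int,
                    rng: np.random.Generator) -> list[str]:
    """Choose the coupled viruses as phylogenetically coherent blocks.

    Host-known viruses are not spread uniformly over a marker-gene tree:
    they are the OTUs similar enough to cultured references to be grouped,
    and such OTUs form clades.  Coupled viruses are therefore drawn as
    disjoint preference-pure subtrees, largest first with a seeded random
    tie-break and at most one block per host lineage, until the requested
    count is reached; only whole blocks are taken, so each coupled group
    stays a contiguous clade.  Any remainder is filled with single leaves.
    """
    cap = max(2, n_coupled // 2)
    blocks: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) <= cap and len({prefs[l] for l in leaves}) == 1:
            blocks.append(leaves)
    shuffled = list(rng.permutation(len(blocks)))
    ordered = sorted(shuffled, key=lambda i: -len(blocks[i]))
    chosen: set[str] = set()
    used_lineages: set[str] = set()
    for idx in ordered:
        block = blocks[idx]
        lineage = prefs[next(iter(block))]
        if len(chosen) >= n_coupled:
            break
        if chosen & block or lineage in used_lineages:
            continue
        if len(chosen) + len(block) <= n_coupled:
            chosen |= block
            used_lineages.add(lineage)
    if len(chosen) < n_coupled:  # remainder: uniformly drawn single leaves
        rest = sorted(set(prefs) - chosen)
        extra = rng.choice(rest, size=n_coupled - len(chosen), replace=False)
        chosen |= set(extra)
    return sorted(chosen)


def _zil_counts(z: np.ndarray, occupancy: float, log_mean: float,
                log_sd: float) -> np.ndarray:
    """Zero-inflated lognormal counts from latent normals.

    Presence is determined by thresholding the same latent variable that
    sets the magnitude, so the copula dependence carries through both the
    presence/absence and the more/less signal.
    """
    from scipy.stats import norm
    threshold = norm.ppf(1.0 - occupancy) if occupancy < 1.0 else -np.inf
    counts = np.rint(np.exp(log_mean + log_sd * z))
    counts[z < threshold] = 0.0
    return counts


def generate(params: SynthParams = SynthParams()) -> SyntheticDataset:
    """Generate the full paired synthetic data set for one seed."""
    rng = np.random.default_rng(params.seed)
    samples = [f"S{i + 1:03d}" for i in range(params.n_samples)]
    hosts = [f"euk_{i + 1:04d}" for i in range(params.n_hosts)]
    viruses = [f"polB_{i + 1:04d}" for i in range(params.n_viruses)]
    lineages = list(DEFAULT_LINEAGES[:params.n_lineages])

    # hosts: round-robin lineage assignment over a shuffled order, so every
    # lineage has members
    shuffled = list(hosts)
    rng.shuffle(shuffled)
    host_lineage = {h: lineages[i % len(lineages)] for i, h in enumerate(shuffled)}

    z_host = rng.standard_normal((params.n_hosts, params.n_samples))
    host_counts = _zil_counts(z_host.copy(), params.occupancy,
                              params.log_mean, params.log_sd)

    tree = _random_tree(viruses, rng)
    prefs = _inherit_preferences(tree, lineages, params.clade_host_fidelity, rng)
    families = _family_partition(tree, params.n_families,
                                 DEFAULT_FAMILIES[:params.n_families])

    n_coupled = int(round(params.frac_coupled * params.n_viruses))
    coupled = _select_coupled(tree, prefs, n_coupled, rng)
    hosts_by_lineage: dict[str, list[str]] = {}
    for h in hosts:
        hosts_by_lineage.setdefault(host_lineage[h], []).append(h)

    # Gaussian copula: latent Pearson r chosen so the rank correlation of
    # the latent pair equals the requested coupling strength
    r_latent = 1.0 if params.coupling_strength == 1.0 else \
        2.0 * math.sin(math.pi * params.coupling_strength / 6.0)
    host_index = {h: i for i, h in enumerate(hosts)}
    pairs: list[tuple[str, str, str]] = []
    z_virus = np.empty((params.n_viruses, params.n_samples))
    coupled_set = set(coupled)
    for vi, virus in enumerate(viruses):
        if virus in coupled_set:
            lineage = prefs[virus]
            host = str(rng.choice(hosts_by_lineage[lineage]))
            zh = z_host[host_index[host]]
            eps = rng.standard_normal(params.n_samples)
            z_virus[vi] = r_latent * zh + math.sqrt(1.0 - r_latent ** 2) * eps
            pairs.append((virus, host, lineage))
        else:
            z_virus[vi] = rng.standard_normal(params.n_samples)
    virus_counts = _zil_counts(z_virus, params.occupancy,
                               params.log_mean, params.log_sd)

    # environmental covariates; optionally a confounder driving extra
    # (virus, host) pairs that are NOT planted interactions
    temp = rng.uniform(-2.0, 30.0, params.n_samples)
    env = pd.DataFrame({
        "temperature": temp,
        "salinity": rng.normal(35.0, 1.0, params.n_samples),
        "nitrate": np.abs(rng.normal(5.0, 2.0, params.n_samples)),
        "phosphate": np.abs(rng.normal(0.5, 0.2, params.n_samples)),
        "silicate": np.abs(rng.normal(3.0, 1.5, params.n_samples)),
    }, index=pd.Index(samples, name="sample_id"))
    if params.n_confounded:
        z_temp = (temp - temp.mean()) / temp.std()
        uncoupled = [v for v in viruses if v not in coupled_set]
        free_hosts = [h for h in hosts
                      if h not in {p[1] for p in pairs}]
        a = 0.9
        for k in range(params.n_confounded):
            virus = uncoupled[k % len(uncoupled)]
            host = free_hosts[k % len(free_hosts)]
            for arr, idx in ((z_virus, viruses.index(virus)),
                             (z_host, host_index[host])):
                eps = rng.standard_normal(params.n_samples)
                arr[idx] = a * z_temp + math.sqrt(1 - a * a) * eps
        virus_counts = _zil_counts(z_virus, params.occupancy,
                                   params.log_mean, params.log_sd)
        host_counts = _zil_counts(z_host, params.occupancy,
                                  params.log_mean, params.log_sd)

    polb = AbundanceMatrix(
        pd.DataFrame(virus_counts, index=pd.Index(viruses, name="otu_id"),
                     columns=samples),
        marker="polB", size_fraction="0.8-inf", unit="counts").validate()
    v9 = AbundanceMatrix(
        pd.DataFrame(host_counts, index=pd.Index(hosts, name="otu_id"),
                     columns=samples),
        marker="V9", size_fraction="0.8-inf", unit="counts").validate()

    tax_rows = []
    for h in hosts:
        tax_rows.append((h, host_lineage[h], pd.NA, pd.NA, pd.NA, pd.NA))
    for v in viruses:
        tax_rows.append((v, pd.NA, pd.NA, pd.NA, pd.NA, families[v]))
    taxonomy = TaxonomyTable(
        pd.DataFrame(tax_rows, columns=["otu_id", "major_lineage", "ncbi_order",
                                        "ncbi_class", "ncbi_phylum",
                                        "viral_family"]).set_index("otu_id"),
        vocabulary=tuple(lineages))

    # one reference virus per coupled OTU, hosting the planted lineage
    ref_rows = []
    reference_assignment: dict[str, str] = {}
    for virus, _host, lineage in pairs:
        ref_id = f"ref_{virus}"
        ref_rows.append((ref_id, families[virus], lineage))
        reference_assignment[virus] = ref_id
    reference_hosts = ReferenceHostTable(
        pd.DataFrame(ref_rows, columns=["reference_virus_id", "viral_family",
                                        "host_major_lineage"]))
    ref_ids = [r[0] for r in ref_rows]

    hit_rows = []
    lo_t, hi_t = params.identity_true
    lo_d, hi_d = params.identity_decoy
    for virus in viruses:
        if virus in reference_assignment:
            ident = float(rng.uniform(lo_t, hi_t))
            hit_rows.append((virus, reference_assignment[virus], ident,
                             float(rng.uniform(80.0, 100.0)),
                             10.0 ** -float(rng.uniform(50, 120)),
                             3.0 * ident + float(rng.uniform(0.0, 5.0))))
        own_ref = reference_assignment.get(virus)
        decoy_refs = [r for r in ref_ids if r != own_ref]
        for _ in range(int(rng.integers(1, 4))):
            ident = float(rng.uniform(lo_d, hi_d))
            hit_rows.append((virus, str(rng.choice(decoy_refs)), ident,
                             float(rng.uniform(30.0, 90.0)),
                             10.0 ** -float(rng.uniform(5, 40)),
                             2.0 * ident + float(rng.uniform(0.0, 5.0))))
    hits = HitTable(pd.DataFrame(hit_rows, columns=[
        "query_id", "subject_id", "percent_identity",
        "percent_query_coverage", "e_value", "bitscore"]))

    truth = SyntheticTruth(pairs=pairs, reference_assignment=reference_assignment,
                           families=dict(families), host_lineages=dict(host_lineage),
                           virus_preferences=dict(prefs))
    return SyntheticDataset(polb=polb, v9=v9, taxonomy=taxonomy,
                            reference_hosts=reference_hosts, hits=hits,
                            tree=tree, metavariables=MetaVariableTable(env),
                            truth=truth)


def truth_confusion(reduced: pd.DataFrame, truth: SyntheticTruth,
                    universe_lineages, universe_otus=None,
                    sign: str = "positive",
                    weight_cutoff: float = 0.0) -> ConfusionMatrix:
    """Confusion matrix against the planted (virus, lineage) pairs."""
    from .validation import confusion
    positives = {(v, lineage) for v, _h, lineage in truth.pairs}
    if universe_otus is None:
        universe_otus = sorted(truth.families)
    return confusion(reduced, positives, universe_lineages, universe_otus,
                     sign=sign, weight_cutoff=weight_cutoff)
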