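# Methods

This note documents the models, defaults and numerical choices behind
`vhoc`, and what the synthetic benchmark does and does not demonstrate.

## Data model and preprocessing

Abundance tables are OTU × sample matrices tagged with a marker gene
(*polB* for giant viruses, 18S V9 for eukaryotes, MCP for virophages), a
plankton size fraction, and a unit (`counts`, `relative`, `clr`).
Relative abundances can be mapped back to approximate read counts as
`round(rel × gene_length / read_length × scale)` with a default read
length of 100 nt; when true library sizes are unknown the per-sample
scale defaults to 10⁶ — only relative magnitudes matter downstream of the
clr transform, so the constant is immaterial.

The clr transform is taken per sample over all OTUs of a marker matrix
(`ln(x+pc) − mean ln(x+pc)`, natural log, pseudocount 1 by default);
compositional closure acts within a sample, which is why the composition
axis is the OTU axis. A full clr column sums to zero (±1e-9, enforced);
row-subset clr matrices keep the `clr` unit but are exempt from the
zero-sum check, since the identity only holds for complete compositions.

Low-abundance filtering: the threshold is the chosen quartile (Q1 by
default, linear-interpolation quantile definition) of clr values at cells
that were non-zero in the original count matrix, computed globally over
the matrix; an OTU survives if it exceeds the threshold in at least
`min_samples` (default 5) samples. A per-OTU threshold variant exists
behind a flag, because the global/per-OTU choice is a genuine ambiguity
in common practice and quartile filtering is sensitive to it. Filtering
and normalization run separately per marker; matrices are merged (sample
intersection, sorted) afterwards, subsetting the already-computed clr
values without recomputation (a flag could recompute; the default keeps
the filtered values comparable to the full-matrix threshold).

## Network inference

The in-package inference is a Spearman comparator: ranks per OTU across
samples (average ties), Pearson correlation of rank vectors for each
virus–eukaryote candidate pair, two-sided p-value via the t
approximation with n−2 degrees of freedom (an exact permutation p-value
is available for n ≤ 10), and an edge when p < α (default 0.01, raw —
multiple-testing correction across pairs is deliberately off by default
to match the thresholding convention of co-occurrence studies; a BH flag
exists). Constant profiles are skipped and logged. Edge lists from
external conditional-independence tools (e.g. Markov-blanket learners)
can be read from TSV and fed to all downstream stages; reimplementing
such tools is out of scope.

Meta-variable conditioning approximates indirect-edge removal: an edge
survives only if, for every environmental covariate z, the first-order
partial Spearman correlation (Pearson partial correlation on ranks)
stays significant at α with n−3 degrees of freedom. When a profile is a
perfect monotone function of z the partial correlation is degenerate and
the edge is treated as fully explained (removed). This is a one-variable
approximation, not a full conditional-independence search.

## Validation

Virus OTUs are grouped to reference viruses by best homology hit
(ranked by bitscore, ties broken by identity then subject id) and kept
only at ≥65 % sequence identity — below that, marker similarity no
longer predicts a shared host lineage. Only grouped OTUs enter the
validation universe, which is (assigned OTUs) × (all major lineages in
the supplied vocabulary); restricting the universe to lineages present
in the network is available, and the most inclusive reading is the
default. Host labels live at the "major lineage" rank because reference
knowledge is too sparse for lower ranks.

Prediction reduction keeps, per (virus, lineage, sign), the single edge
of maximal |weight| (ties: larger signed weight, then lexicographic
eukaryote id); pooled multi-fraction input is deduplicated by the same
rule before reduction. Positive and negative signs are assessed
separately. LR+ boundary cases return sentinels: `inf` when FPR = 0 with
nonzero sensitivity, `nan` (undefined) when there are no condition
positives, no predictions (for FDR), or a degenerate denominator.
Averages over a cutoff sweep are unweighted means of the defined finite
LR+ values, with excluded infinities logged and counted.

## Phylogeny-guided filtering

A leaf is associated with taxon T iff it has ≥1 network edge to an OTU
annotated T at T's rank — presence/absence, not edge counts or weights,
so the filter acts on topology only. For every internal node (root
excluded; its complement is empty) × every observed taxon, the 2×2 table
(in-clade associated / in-clade not / out-clade associated / out-clade
not) is tested one-sided for enrichment. Fisher p-values use exact
rational arithmetic up to table total 64 and a log-space hypergeometric
tail sum (lgamma terms, peak-factored fsum) above, giving ≤1e-10 relative
error against exact enumeration across the tested range.

BH adjustment runs over all (node × taxon) tests jointly; tests with an
empty in-clade count (a = 0, p = 1 by construction) are not reported but
remain in the adjustment family, so the number of tests honestly reflects
the search space. The significance threshold is q < 0.05 (configurable).
Edges survive iff covered by some significant (node, taxon) pair; edges
whose virus endpoint is missing from the tree are dropped with a logged
count (marker trees are typically built from a length-filtered subset of
sequences). The family × lineage summary network attributes each
significant node to a viral family only when the node's leaves are
family-pure (purity threshold 1.0 by default; impure nodes are reported
as "mixed").

## Virophage analyses

Virophage clades are defined by MRCA expansion of seed leaf sets and
must be disjoint. Clade × family enrichment counts association *edges*
(OTU-level counting is available behind a flag, since either unit is
defensible); one-sided Fisher with joint BH, matching the tree filter.
Families other than the two majors can be pooled into "Other NCLDVs".
Size fractions are analysed as separate networks with their own weight
cutoffs. HGT candidates: a capsid query passes if its best giant-virus
genome hit (filtered at E ≤ 1e-10, coverage ≥ 50 %, identity ≥ 50 %) has
a lower E-value than every non-self hit in the virophage database;
queries with no non-self guard hit are accepted but logged as unguarded.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes in
survey data, at desk scale: 88 samples, 150 eukaryotic OTUs over 12
major lineages, 100 viral OTUs in 4 family clades, 40 % of viruses
coupled to one host each, rank-correlation target 0.8, occupancy 0.5.
Abundances are zero-inflated lognormal (log-mean 2, log-sd 1); presence
is thresholded on the same latent normal that sets magnitude, so copula
dependence flows through both the presence pattern and the quantitative
signal. The latent correlation is `2·sin(π·ρ/6)` so the latent rank
correlation equals the target; censoring at 50 % occupancy drags the
realized mean Spearman of planted pairs to ≈0.75, within the intended
±0.1 band, and the ρ = 1, occupancy = 1 limit yields bitwise-identical
planted vectors.

Host-lineage preference is inherited along a random bifurcating tree:
each child clade keeps its parent's lineage with probability 0.9
(`clade_host_fidelity`); a switch jumps to a lineage drawn without
replacement from those not yet used, so each lineage occupies a
contiguous region of the tree rather than recurring in distant subtrees.
Coupled viruses are drawn as whole preference-pure subtrees (largest
first, at most one block per lineage, remainder as single leaves) rather
than uniformly: host-known viruses in real data are exactly the OTUs
similar enough to cultured references to be grouped, and such OTUs form
clades. Both choices implement the "related viruses infect related
hosts" premise the tree filter is designed to exploit; with uniform
scatter the premise is false by construction and the filter has nothing
to find. Reference tables contain one entry per coupled virus; true
homology hits fall at 66–95 % identity with dominating bitscores, decoys
at 30–60 % (never to the query's own reference). Environmental
covariates are independent by default; a configurable number of
virus–host pairs can be driven by temperature to exercise the
conditioning step.

What passing the benchmark shows: the chain recovers planted couplings
far better than a volume-matched random predictor, and the tree filter
removes noise edges while keeping clade-concentrated signal. What it
does not show: robustness to compositional artefacts beyond clr, to
lagged or negative virus–host dynamics (couplings are positive-only by
default, with flags to explore alternatives), to spatial/temporal
autocorrelation between samples, or to taxonomy errors — real survey
data have all of these.

## Problem sizes and determinism

Default benchmark runs (5 seeds × generate + ~15,000 pair tests + 1000
random-predictor replicates + tree enrichment) finish in a few seconds
on one CPU; sizes were chosen so the whole suite iterates comfortably on
a laptop while keeping ≥4 planted couplings per lineage block, the
minimum at which clade enrichment is detectable at q < 0.05 under the
joint BH family. All randomness flows from a single integer seed through
`numpy.random.default_rng`; same seed, same outputs, bit for bit.
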