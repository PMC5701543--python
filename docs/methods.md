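# Methods

## The analysis model

The pipeline operates on a heterogeneous interaction network. Protein
nodes are the union of (a) putative targets — proteins predicted to be
bound or modulated by any compound of the intervention — and (b) known
therapeutic targets of the diseases under study, deduplicated by plain
set union after symbol normalization (uppercase, whitespace-stripped; no
alias resolution, so the mapping is deterministic and dataset-agnostic).
PPI edges are kept only when *both* endpoints are in that target set: the
network is target-anchored, and interactions among non-target proteins are
out of scope. Compound and disease-source nodes can be attached for
visualization export (`include_source_nodes`), but all topology is
computed on the protein–protein subnetwork; mixing star-shaped annotation
nodes into the centrality computation would distort every feature median.

### Key-target filter

Stage A removes nodes of degree < m × median(degree) over the whole
protein network (m = 2 by default) and rebuilds the network on the
survivors as an induced subgraph. Ties at exactly the threshold are kept —
only values *less than* the cutoff are deleted. Stage B recomputes degree,
betweenness, closeness and core number from scratch on the rebuilt
network (no caching across stages) and retains nodes strictly greater
than all four feature medians. Strict inequality is deliberate: on any
vertex-transitive graph all features tie their medians and the key set is
empty, which is the correct degenerate answer for a network with no
privileged nodes.

Feature conventions (all verified against exhaustive enumeration in the
test suite):

* **betweenness** — unnormalized, each unordered pair {s, t} counted
  once: b(v) = Σ σ_st(v)/σ_st. Unnormalized values are what a median
  threshold of tens-of-units magnitude implies; normalizing to [0, 1]
  would change nothing about the ranking but everything about the
  printed thresholds.
* **closeness** — 1 / Σ d(v, u) over *reachable* u, isolated node → 0.
  This is the plain inverse-distance-sum convention (as in igraph)
  rather than the (n−1)/Σd rescaling; on a ~100-node network it yields
  medians of magnitude 10⁻³, consistent with thresholds this filter is
  typically quoted with. The convention is a single place in
  `topology.closeness_map` and trivially swappable.
* **core number** — iterative peeling; equals the largest k such that
  the node survives in the k-core.
* **median** — linear interpolation (mean of the two middle order
  statistics for even n), applied uniformly to features, filter
  thresholds and docking scores. Non-integer published thresholds for
  integer-valued features are only possible under this rule, which is
  why it is the package-wide default (`median_method: interpolate`, the
  only supported value).

### Over-representation analysis

Hypergeometric upper tail computed in log-space (gammaln + logsumexp), so
p-values far below double-precision underflow of individual factorials
remain accurate; the test suite pins it to exhaustive draw enumeration at
1e-12 and to `scipy.stats.hypergeom.sf`. The universe defaults to the
union of all genes annotated in the GMT collection (the convention of the
standard ORA tools), overridable with an explicit background. Sets with
zero query overlap are omitted — they carry no network edges. The
significance filter is raw p < α (α = 0.05 by default), matching the
common practice of ORA pipelines that publish a p-value cutoff; BH
q-values are computed (statsmodels step-up) over all tested sets and
reported alongside so users can filter on FDR instead. Ties in p are
ordered by set id for deterministic output.

### Docking filter

Duplicate (compound, target) rows collapse to their maximum score
*before* the median is computed — docking scores are best-pose scores, so
the maximum is the natural representative. The median is taken over all
parsed finite scores and retention is strict (>): for n distinct scores
with n odd, exactly (n−1)/2 pairs survive, and the retained set is
invariant under positive rescaling of all scores. The median is always
data-derived, never hard-coded.

## Synthetic data: what it emulates, what it does not

`generate_bundle(seed)` produces a complete input bundle under fixed
default conditions: 20 compounds, 97 putative targets, disease lists of
59 (T2D), 279 (HT) and 20 (HL) targets, with planted Venn regions
PT∩HT = 8, PT∩HL = 1, one symbol in each of PT∩T2D∩HT, PT∩T2D∩HL,
PT∩HT∩HL and PT∩T2D∩HT∩HL (13 putative targets disease-linked in total),
plus small disease–disease overlaps for realism. Gene symbols are
synthesized `G0001`-style and compounds `CPD01`-style — deliberately not
real identifiers, so no accidental biological claim is embedded.

The PPI generator used in bundles plants recoverable structure. Three
node blocks:

* **hubs** (10) — a clique, wired to every decoy and to each background
  node with probability 0.05;
* **decoys** (60) — each linked to exactly 8 of the 10 hubs and to
  nothing else. Their degree is constant and their neighborhoods are
  near-interchangeable, so after stage A they form the median block of
  every feature: degree 8 each, betweenness 0 (their neighbors are
  clique members), core number 8, tightly clustered closeness. Strict
  inequality at stage B therefore excludes all of them;
* **background** (~357) — sparse Erdős–Rényi, mean degree 3. The
  network-wide median degree lands in this block, so the stage-A
  threshold (2 × median ≈ 6–8) removes almost all of it; the few
  high-degree stragglers that survive have small *induced* degree in the
  rebuilt network and fail the stage-B degree median.

The regime was designed (and is verified across ≥ 20 seeds) so that the
two-stage filter returns exactly the planted hubs, while the cascade
sizes (~427 nodes → ~80 → 10) echo what the filter does on real
compound–disease networks of this scale. A separate Barabási–Albert
generator (`generate_ppi`) provides heavy-tailed degree distributions for
tests that only need realism, not planted truth.

Docking scores are Gaussian(86, 25) per compound × planted-hub pair: the
location makes the data-derived median come out near the mid-80s and the
spread puts the best scores in the 150–170 range, the magnitudes typical
of rigid-docking pose scores; the synthetic scores carry no chemistry.

What the generator does **not** emulate: real PPI noise structure
(false-positive edges correlated with study bias), overlapping pathway
hierarchies (decoy sets are uniform draws), compound–target prediction
scores, or any correlation between docking score and network position.
Passing tests therefore demonstrate correctness of the *procedures* —
exact Venn arithmetic, faithful median thresholds, calibrated ORA — not
that the procedures recover biology from real databases. Results on real
data remain snapshot-dependent: the same pipeline on a different PPI or
pathway release will give different node counts, medians and key-target
sets; that sensitivity is inherent to the method, not to this
implementation.

## Numerical and design choices

* Master seed fans out to per-table child seeds by fixed affine offsets
  (mod 2³¹), so each table is individually reproducible.
* All writers sort nodes, edges, rows and JSON keys: identical inputs
  produce byte-identical outputs, which the CLI tests hash-compare.
* Stage A/B on an emptied network: a warning flag on the report, not an
  exception — an empty result is a legitimate outcome (e.g. regular
  graphs), and the pipeline continues with the stages that remain
  runnable.
* SIF export carries structure plus relation tags (`pp`, `ct`, `dt`,
  `pw`); roles are recovered from typed relations on read. GraphML and
  the TSV-pair form (edge table + `.nodes.tsv` attribute table) round-trip
  node annotations exactly. Compound ids and gene symbols live in
  disjoint namespaces via node roles, so a compound named like a gene
  cannot collide.
* Bipartite pathway–target and compound–target networks have one edge
  per overlap gene / retained docking pair, so the edge count always
  equals the summed overlap (an invariant the tests enforce).
* Degenerate inputs: empty medians, empty collections, self-loop pairs,
  malformed GMT lines and unknown config keys raise immediately with the
  offending item named; duplicate table rows collapse silently but are
  counted in the log.

## Problem sizes used in the shipped checks

The oracle-equivalence tests run ~200 random graphs with n ≤ 8 against
all-simple-paths and all-subsets enumeration, and the hypergeometric tail
against full draw enumeration up to N = 12; type-I calibration uses 1,000
null ORA replicates (20 sets, 300-gene universe); hub recovery runs 20+
full bundles. These sizes keep the whole suite under a minute on one core
while leaving every check exhaustive where exhaustiveness is the point.

## Known limitations

* No identifier mapping: symbols that differ by alias are distinct nodes.
* ORA assumes the universe is exchangeable (plain hypergeometric); no
  gene-length or annotation-bias correction.
* Betweenness is exact Brandes in pure Python — fine into the low
  thousands of nodes, not meant for proteome-scale graphs.
* The docking filter consumes scores as given; it has no notion of pose
  quality, chemistry or redundancy among crystal structures.
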