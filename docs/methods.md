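# Methods

## The network-of-interacting-pathways model

For one taxon with pathway annotation `P → M(P)` (each pathway a set of
metabolite identifiers, after exclusion filtering), the NIP is the
undirected graph with vertex set `{P}` and an edge `{a, b}` whenever
`M(a) ∩ M(b) ≠ ∅`, weighted `w(a,b) = |M(a) ∩ M(b)|`. Directionality of
metabolite production/consumption is not represented: the NIP captures
*potential* cross-talk, not flux. Isolated pathways stay in the vertex set —
they carry information about network size and enter the information-theoretic
descriptors. Currency metabolites are handled by an explicit exclusion list
that by default contains only the identifier configured as water; other
ubiquitous metabolites are kept deliberately, since pathway overlap through
common cofactors is part of the signal at this organizational level.

### Annotation-consistency filter

Pathway counts grow roughly linearly with the logarithm of genome size. The
filter fits OLS `n_pathways ~ ln(orf_count)` across taxa and removes the
`floor(q·n)` taxa with the most negative residuals (default `q = 0.05`),
i.e. genomes annotated with far fewer pathways than their size predicts.
Choices made where the procedure was open:

* signed residuals (under-annotation only), not absolute residuals;
* the cut is global, not per-group;
* residual ties break by taxon id, so the removal set is deterministic;
* natural log (the base only rescales the slope; r² is invariant).

### Strain merging

Strains mapped to the same taxon have their pathway sets and per-pathway
metabolite sets unioned, and `orf_count = max` over strains: a merged
taxon's metabolic capability is at least that of each strain. The logged
alternative (keep the strain with the most pathways) discards capability
present in other strains. Conflicting group labels within a merge group are
an error rather than silently resolved.

## The 52 descriptors

25 basic descriptors and 27 derivatives; ids and order are fixed in
`nipevo.descriptors.REGISTRY`.

**Degree/adjacency (9):** vertex count, edge count, total adjacency (Σ deg),
average degree, degree range, connectedness `2E/(V(V−1))`, total edge
weight, average strength, strength range.

**Distance (6):** radius and diameter (eccentricities within connected
components), total and average distance over unordered reachable pairs,
vertex distance-sum range, and the weighted average distance.

**Centrality (6):** mean degree centrality `deg/(V−1)`; mean harmonic
closeness; mean vertex and edge betweenness, unweighted and weighted.

**Cliques/clustering (4):** mean clustering coefficient, mean Barrat
weighted clustering, number of maximal cliques, maximum clique size.

**Derivatives (27):** `{AI, NI, TI} ×` nine equivalence distributions —
vertex degrees, vertex strengths, edge weights, vertex distance sums,
vertex eccentricities, pairwise finite distances, maximal-clique sizes,
per-vertex maximal-clique membership counts, per-vertex triangle counts.
For class sizes `n₁..n_k` over `N` elements:
`AI = −Σ (nᵢ/N) log₂(nᵢ/N)`, `TI = N log₂N − Σ nᵢ log₂nᵢ`,
`NI = AI/log₂N` (0 when `N = 1`).

### Conventions and numerical choices

* **Weighted path length is 1/weight.** More metabolites exchanged means a
  shorter effective distance; weight is treated as cross-talk intensity.
  Multiplying all weights by `c > 0` divides weighted distances by `c` and
  leaves every unweighted descriptor unchanged.
* **Disconnected graphs are first-class.** Distances are summed/averaged
  over reachable pairs only; eccentricity is within-component; closeness is
  harmonic (`1/∞ = 0`), which is why it stays well defined.
* **Betweenness normalization** divides by the pair count excluding the
  element's endpoints: `(n−1)(n−2)/2` for vertices, `n(n−1)/2` for edges.
  Equal-length shortest paths split contributions evenly.
* **Barrat weighted clustering**
  `C_w(i) = 1/(s_i(k_i−1)) Σ_{(j,h)} (w_ij+w_ih)/2` over ordered neighbour
  pairs closing a triangle; with unit weights it reduces exactly to the
  unweighted coefficient. Degree < 2 gives 0.
* **Information distributions use exact-value classes of integer-valued
  quantities only** (no binning of continuous values); an empty
  distribution (e.g. edge weights of an edgeless graph) yields NaN, as does
  any quantity undefined on the graph. An empty graph yields an all-NaN
  vector with a warning.
* **Shortest-path tie handling.** Path-length ties under reciprocal
  weights are decided in floating point. The dual-route equivalence tests
  therefore use power-of-two weights, for which `1/w` and all path sums are
  exact dyadic floats, making tie detection algorithm-independent. On
  arbitrary integer weights, tie misclassification can perturb betweenness
  in the last few ulps; no descriptor decision in the pipeline depends on
  such ties.
* Heavy traversals (all-pairs distances, betweenness, maximal-clique
  enumeration) run on a C-backed igraph view of the graph; every descriptor
  is checked against an independent naive implementation (Floyd–Warshall,
  pair-by-pair path counting, pivotless Bron–Kerbosch / subset enumeration)
  to 1e-9 in the test suite.

## Group classification

The training table pairs each taxon's 52 descriptor values with its group
label for one contrast. Models: logistic regression, a small MLP (one
hidden layer of 16 units), a depth-5 decision tree standing in for a rule
learner, a directly implemented OneR baseline (best single-feature
threshold rule), 1-nearest-neighbour, a 100-tree random forest, and an RBF
SVM — all behind a per-fold pipeline of median imputation and
standardization fit on training folds only (no leakage). Evaluation is
stratified k-fold CV (default 10; reduced with a warning when the smallest
class is smaller) with a fixed seed recorded in all outputs; predictions
are pooled across folds into one confusion matrix from which accuracy and
Cohen's kappa are computed; resubstitution scores are reported alongside.
Models are ranked by CV accuracy, then CV kappa, then roster order; the top
model is the reported classifier for the contrast — note this best-of-roster
selection inflates the reported kappa under a null by roughly the roster
maximum of k mean-zero noise terms (sd ≈ 0.1 per model at n = 100).

Feature selection is greedy forward selection maximizing CV kappa, stopping
as soon as the subset is within `tolerance = 0.01` kappa of the full-set
value (ties break by registry order; stalling without reaching tolerance is
flagged). Greedy forward search is a heuristic: it returns *a* minimal-ish
subset, not the global minimum.

## Pathway-importance statistics

Six per-pathway scores: frequency (fraction of group taxa possessing the
pathway), degree, strength, harmonic closeness, betweenness and weighted
betweenness. Frequency differences are tested with the two-sided Fisher
exact test on presence/absence counts; the other scores with the two-sided
Mann–Whitney U on per-taxon values **restricted to taxa possessing the
pathway** — absence is already captured by frequency, so zeros for missing
pathways are not imputed. The Mann–Whitney implementation uses the exact
null distribution when there are no ties and `n_x·n_y ≤ 400`, otherwise the
tie-corrected normal approximation (no continuity correction, so identical
samples give exactly p = 1; zero-variance pooled samples return p = 1 by
convention). All (pathway × score) tests of a contrast form a single
Benjamini–Hochberg family; the per-descriptor tests (Mann–Whitney for two
groups, Kruskal–Wallis for three or more) form a Bonferroni family of 52.
"Amplitude" is the difference of group medians (for frequency, the
difference of frequencies), signed second group minus first; category
summaries take per-category medians of amplitude and FDR, with direction
the sign of the median amplitude.

## Synthetic data generator

The generator emulates the *shape* of KEGG-style annotation data, not its
biochemistry. A universe of 150 pathways (default) draws ~10 metabolites
each from a pool of 400, of which 4 % are hub metabolites sampled with
9-fold higher probability. These defaults were set so that a full-retention
NIP lands in the regime observed for real pathway networks — dense
(connectedness ≈ 0.45), clustered (mean clustering ≈ 0.6), small diameter —
while keeping maximal-clique counts tractable (tens of thousands per NIP);
much stronger hub concentration drives the NIP toward a complete graph
whose clique enumeration is combinatorially explosive.

Taxa retain each pathway independently with a group-specific retention
probability, optionally multiplied per functional category (11 fixed
categories mirroring KEGG top-level metabolism classes); ORF counts invert
the pathways ~ log(ORF) relation (`orf = round(exp((n_pathways + 75)/25 + ε))`,
`ε ~ N(0, 0.15)`). A single `effect_size` scales all between-group
differences; at 0 the groups are exchangeable by construction, providing
the matched null. `make_inconsistent` deflates a marked taxon fraction's
pathway sets while keeping ORF counts, creating known targets for the
consistency filter. All randomness flows through one seeded generator.

The default study scenario is two groups of 50 taxa: retention 0.9
("free_living") versus 0.5 ("host_associated"), with lipid and glycan
retention in the second group further multiplied by 0.6 — the planted
categories, whose expected direction is recorded in the ground truth.

**What the generator does not emulate:** phylogenetic correlation between
taxa (taxa are independent draws), reaction stoichiometry and enzyme
assignment, pathway-size heterogeneity beyond Poisson, database-specific
annotation biases. Passing tests on this generator therefore demonstrate
that the pipeline recovers planted effects of the stated kind and size
under independence — not that any particular biological contrast would be
detected in real annotation data.

## Problem sizes

Dual-route descriptor equivalence runs on 50 random graphs of up to 30
vertices (plus exhaustive path-enumeration checks up to 8 vertices and
2^n-subset clique checks up to 10). Null calibration of the corrected
false-positive rates uses 500 replicate families of 20 tests. The
planted/null scenario runs at the full default size (100 taxa, 150
pathways); the determinism check uses a reduced scenario (24 taxa, 40
pathways), which exercises every pipeline stage at lower cost.

## Known limitations

* The NIP is undirected and unsigned; producer/consumer roles are not kept.
* Greedy forward selection and the best-of-roster model choice are
  heuristics with optimistic bias under weak signal (see above).
* Exact Mann–Whitney is only used for small tie-free samples; elsewhere the
  normal approximation applies.
* Descriptors on very small graphs (< 3 vertices) contain several NaN/0
  conventions documented above; downstream imputation replaces NaN with the
  training-fold median.
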