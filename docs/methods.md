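# Methods

## Model and assumptions

`genoclust` treats species delimitation as a graph problem over genome
labels. The input is one or more square pairwise-value matrices — typically
ANI (percent identity), alignment coverage (fraction of each genome
aligned), or a distance such as 1 − dDDH — produced upstream by pyANI,
FastANI or GGDC. The method assumes only an order relation between each
pair's value and a user-chosen cutoff; nothing about the distribution of
the values themselves.

The pipeline is deterministic and purely combinatorial:

1. **Pair averaging.** Identity values are direction-dependent (query
   fragments mapped onto a reference), so each unordered pair is summarized
   by the mean of its two directed values. If only one direction was
   reported, that value is used; if neither, the pair stays missing. The
   diagonal is forced to the scale maximum for identity/coverage and to 0
   for distances.
2. **Binarization.** An inclusive threshold (≥ for identity/coverage, ≤ for
   distance) maps the symmetric matrix to a Boolean relation with a false
   diagonal. A missing value never satisfies a criterion: absence of
   evidence must not create an edge.
3. **Consensus.** Relations over the same label set are combined by
   element-wise AND (commutative, associative, monotone — adding a
   criterion can only remove edges). This is how a coverage floor guards
   the identity cutoff against high-ANI calls from short homologous
   stretches, e.g. after horizontal transfer.
4. **Cluster readout.** Maximal cliques are candidate genospecies under the
   strict reading (every pair above cutoff); connected components are the
   loose reading (each genome above cutoff with at least one member).
   Cliques may overlap — a genome near the species boundary legitimately
   belongs to several candidate species at once, which is precisely the
   signal tree-shaped clusterings cannot represent. We implement the
   components output as standard connected components (isolated nodes
   become singleton components); descriptions of this output elsewhere as
   "isolated nodes or groups formed of complete graphs" conflate it with
   the clique output.

## Clique enumeration

Bron–Kerbosch with pivoting, driven by a degeneracy ordering of the outer
vertex loop — the standard output-sensitive variant; pivoting prunes
non-maximal branches and degeneracy ordering bounds the recursion width on
sparse graphs (genospecies graphs are extremely sparse: almost all mass is
in small blocks). Singletons are emitted for isolated nodes so the clique
set always covers the node set. All cluster outputs are post-sorted
(descending size, then lexicographic member order) so repeated runs are
byte-identical; ties anywhere (pivot choice, degeneracy ties) cannot affect
the output set, only the traversal order. The implementation is
cross-checked in the test suite against exhaustive subset enumeration
(all 2^n subsets, n ≤ 12) and against an independent library
implementation.

## Name parsing and filters

Node labels are parsed as `Genus epithet <strain designation>` with three
complications handled explicitly: surrounding quotes (names not validly
published) and *Candidatus* prefixes, trailing type-strain markers
(`^T^`, `(T)`, a superscript-T glyph, or a digit-attached `T`), and the
`sp.` placeholder, which yields no species identity. The species key is
lowercase genus+epithet; subspecies epithets fall into the strain residual
on purpose — whether two subspecies are one species is the downstream
question the clustering answers, so the filters must not prejudge it.
Quoted names do carry a species key: effectively-published names are
taxonomic signal even without standing in nomenclature.

Four filters compose in user-given order:

* `remove-isolated` — drop degree-0 nodes;
* `remove-larger-component` / `only-larger-component` — drop or keep the
  component with most nodes (size ties go to the lexicographically
  smallest-membered component, with a warning);
* `different-names-connected` — keep components whose members carry ≥ 2
  distinct species keys (candidate heterotypic synonyms). Placeholder
  labels never trigger retention but ride along with a retained component;
* `same-names-not-connected` — keep the induced subgraph on all nodes of
  every species key that occurs in ≥ 2 components (misidentified or
  unauthentic assemblies, "false type strains"). "Unconnected" is resolved
  at component granularity: the interesting cases are genomes in entirely
  different clusters, not merely in different cliques of one component.

All filters only ever remove nodes/edges. All except
`remove-larger-component` are idempotent; removing "the" largest component
necessarily exposes a new largest one, so repeated application keeps
shrinking the graph — treat it as a one-shot operation.

## Scales and units

Matrices declare `percent` (0–100) or `fraction` (0–1); the reader
auto-detects (all finite off-diagonal values ≤ 1.0 ⇒ fraction), overridable.
Criteria default to percent. A criterion whose scale differs from its
matrix raises unless conversion is explicitly allowed (the CLI allows it),
in which case both are normalized to percent before comparison — mixing
0.95 and 95 silently is the classic way to cluster everything or nothing.
For FastANI-style long records, pairs the tool never reported are filled
with 0 by default (guaranteeing no edge under any ≥ criterion) or kept
missing under `absent-marker`.

## Quality and authenticity screening

* `qc_flag` flags genomes with weighted completeness ≤ `completeness_max`
  (default 0.9) **or** weighted redundancy ≥ `redundancy_min` (default
  1.1), both inclusive. It consumes the tabular output of a marker-gene
  completeness tool (e.g. miComplete's weighted Bact105 scores); it does
  not recompute completeness from markers.
* `length_filter` removes 16S sequences with ungapped length ≤ 400 nt
  (inclusive) — too short for a reliable identity comparison.
* `pairwise_identity` computes percent identity from a pre-built alignment.
  Default gap handling is **pairwise deletion**: each pair is compared over
  the columns where both rows are ungapped, which maximizes usable signal;
  a `complete_deletion` switch restricts all comparisons to globally
  gap-free columns instead (both conventions are in use for rRNA distance
  computation, and which a given study used is rarely stated — hence both
  are implemented and reported explicitly). U equals T; N and other
  ambiguity codes count as compared columns but never as matches
  (conservative identity). A pair with zero comparable columns is marked
  missing with a warning rather than silently 0 or 100.
* `confirm_same_otu` is the ≥ 99% 16S-identity rule for confirming that
  two sequences represent the same operational taxonomic unit; it is
  monotone and inclusive at the boundary.

## Synthetic data

The generator emulates the one property of real OGRI matrices the method
depends on: block structure relative to a cutoff. Species blocks get
within-block values drawn uniformly from one range (default 96–100%) and
between-block values from another (default 75–85%), with independent ±0.2
percentage-point directional jitter so raw matrices are asymmetric the way
query/reference ANI output is. Defaults keep the ranges separated around
the 95% cutoff even after jitter, so recovered components and cliques
provably equal the generating blocks; an `overlapping` flag permits
boundary-straddling scenarios for stress tests. Labels are generated in the
field's naming styles (plain binomial+strain, quoted, `sp.` placeholder)
from deliberately fictitious genus/epithet pools.

What the generator does **not** emulate: chaining between real sister
species (within/between ranges straddling the cutoff), correlated error
between ANI and coverage, missing-data patterns of real FastANI output, or
genome-quality covariates. Passing the recovery tests therefore shows the
machinery is correct in the separated regime, not that a 95% cutoff is the
right species boundary for any particular genus — near-threshold cases are
covered separately by hand-built chain fixtures.

## Numerical and design choices

* Comparisons at cutoffs are inclusive everywhere (≥/≤), matching how the
  thresholds are quoted in practice (e.g. a pair at exactly 95.0% ANI is an
  edge; completeness exactly 0.9 is flagged).
* Matrix writing uses 17 significant digits, so read∘write is exact to the
  bit; the round-trip tolerance asserted in tests (1e-12) is conservative.
* All randomness is seeded through `numpy.random.default_rng`; identical
  seeds yield byte-identical matrix files and outputs.
* Problem sizes in the test suite: exhaustive clique cross-checks on
  graphs of ≤ 12 nodes (brute force over 2^12 subsets), 100-seed block
  recovery at 4 species × 3 genomes, component oracles at ≤ 50 nodes —
  sizes at which the independent oracles are exact yet the full suite
  stays fast.

## Known limitations

* No weighted-graph community detection; the method is threshold-based by
  design, and a cutoff is a scientific commitment the user makes.
* Name parsing is heuristic on free-text labels; it is total (never raises)
  but unusual label formats can yield no species key, silently exempting a
  node from name-based retention triggers.
* ANI/dDDH computation, marker-based completeness, 16S gene prediction and
  multiple alignment are upstream tools' jobs; this package starts at their
  outputs.
* Clique enumeration is exponential in the worst case; genospecies graphs
  are far from it, but a near-complete graph over thousands of nodes would
  be slow.
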