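# genoclust

Graph-based genospecies clustering of whole-genome relatedness matrices,
with taxonomy-aware filters and genome quality screening.

## The problem

Prokaryotic species are delimited today with overall genome-related indices
(OGRI): two genomes are conspecific when their average nucleotide identity
(ANI) is at least ~95–96% and their digital DNA–DNA hybridization (dDDH) is
at least 70%. Tools such as pyANI, FastANI and GGDC produce the pairwise
values, but mining a large all-vs-all matrix by hand is impractical, and
hierarchical clustering hides exactly the interesting cases — clusters in
which not every pair exceeds the cutoff, and genomes that sit in two
overlapping candidate species at once. `genoclust` is for microbial
taxonomists who have those matrices and want the species hypotheses, the
candidate synonyms, and the misidentified assemblies out of them.

## The method

Given one or more labeled square matrices *M* (identity, coverage, or
distance semantics), each with an inclusive cutoff criterion *t*:

1. **Symmetrize** each matrix by pair averaging:
   *S*ᵢⱼ = (*M*ᵢⱼ + *M*ⱼᵢ) / 2 (ANI is asymmetric between query and
   reference; the pair mean is the canonical summary).
2. **Binarize**: *A*ᵢⱼ = [*S*ᵢⱼ ≥ *t*] for identity/coverage
   (≤ *t* for distances), with a false diagonal; missing values never
   satisfy a criterion.
3. **Consensus**: AND the Boolean relations element-wise, e.g.
   ANI ≥ 95% **and** alignment coverage ≥ 50%, so a high-identity call over
   a short homologous stretch never becomes an edge.
4. **Cluster** the resulting undirected graph at two granularities:
   * **maximal cliques** (Bron–Kerbosch with pivoting over a degeneracy
     ordering) — strict genospecies in which *every* pair exceeds the
     cutoff; cliques may overlap;
   * **connected components** — loose clusters in which every genome
     exceeds the cutoff with *at least one* other member.
5. **Filter** by parsed binomial names: keep connected genomes carrying
   different species names (candidate heterotypic synonyms), or same-named
   genomes that failed to connect (misidentified or unauthentic
   assemblies), or drop isolated nodes / the largest component.

A QC module implements the companion screening rules: flag genomes with
weighted completeness ≤ 0.9 or weighted redundancy ≥ 1.1, drop 16S rRNA
sequences of ≤ 400 nt, compute gap-aware pairwise 16S identities from an
alignment, and confirm same-OTU assignment at ≥ 99% identity.

## Worked example

```python
import numpy as np
from genoclust import (LabeledMatrix, Criterion, binarize, build_graph,
                       maximal_cliques, components)

labels = ("Rhizobium favelukesii LPU83^T^",
          "Rhizobium tibeticum CCBAU 85039^T^",
          "Rhizobium gallicum SEMIA 4085^T^")
ani = np.array([[100.0, 95.9, 80.3],
                [95.9, 100.0, 80.1],
                [80.3, 80.1, 100.0]])
m = LabeledMatrix(labels, ani, kind="identity", scale="percent")
g = build_graph(binarize(m, Criterion(95.0)))
print("cliques:", maximal_cliques(g))
print("components:", components(g))
```

prints

```
cliques: [('Rhizobium favelukesii LPU83^T^', 'Rhizobium tibeticum CCBAU 85039^T^'), ('Rhizobium gallicum SEMIA 4085^T^',)]
components: [('Rhizobium favelukesii LPU83^T^', 'Rhizobium tibeticum CCBAU 85039^T^'), ('Rhizobium gallicum SEMIA 4085^T^',)]
```

The two type strains at 95.9% ANI clear the inclusive ≥ 95% cutoff and form
a two-genome cluster — despite carrying different species names, which is
exactly what the `different-names-connected` filter surfaces as a candidate
synonymy — while the third genome at ~80% stays a singleton.

From the shell, the same pipeline with multiple matrices and filters:

```sh
genoclust cluster --ani ani.tsv --ani-cutoff 95 \
                  --coverage cov.tsv --coverage-cutoff 50 \
                  --different-names-connected --same-names-not-connected \
                  --granularity both --out results/
```

writes `max_cliques.tsv`, `components.tsv`, `graph.graphml` / `graph.dot` /
`edges.tsv`, a force-layout `graph.svg` colored by species name, and a JSON
run summary. `genoclust qc`, `genoclust rrna-identity` and
`genoclust simulate` expose the QC screen, the 16S identity computation,
and the synthetic block-matrix generator.

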