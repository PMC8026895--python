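"""Binomial-name parsing and taxonomy-aware graph filters.

Node labels in genome-relatedness graphs are organism names of the form
``Genus epithet STRAIN`` — possibly quoted (not validly published names),
carrying *Candidatus* markers, type-strain superscripts (``^T^``), or an
``sp.`` placeholder instead of an epithet.  The filters here exploit those
names to surface the taxonomically interesting clusters: connected genomes
carrying *different* species names (candidate heterotypic synonyms) and
same-named genomes that ended up in *different* clusters (misidentified or
unauthentic assemblies).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable

from .graph import RelationGraph, components

__all__ = [
    "TaxonLabel",
    "parse_binomial",
    "filter_remove_isolated",
    "filter_larger_component",
    "filter_different_names_connected",
    "filter_same_names_not_connected",
    "FILTERS",
]

_QUOTES = "\"'“”‘’"
# trailing type-strain superscript variants: ^T^, (T), superscript T glyph
_TYPE_MARKER = re.compile(r"(\^T\^|\(T\)|ᵀ|(?<=\d)T)\s*$")


@dataclass(frozen=True)
class TaxonLabel:
    """Genus/epithet/strain decomposition of a node label.

    ``species_key`` is the lowercase ``"genus epithet"`` when the label's
    first two tokens form a binomial, else ``None`` (single-token labels,
    ``sp.`` placeholders).  Subspecies are ignored on purpose: whether two
    subspecies are one species is exactly the downstream question the
    clustering answers.
    """

    raw: str
    genus: str | None
    epithet: str | None
    qualifier: str  # 'none' | 'candidatus-or-quoted' | 'sp-placeholder'
    strain: str

    @property
    def species_key(self) -> str | None:
        if self.genus and self.epithet:
            return f"{self.genus.lower()} {self.epithet.lower()}"
        return None


def parse_binomial(label: str) -> TaxonLabel:
    """Parse an organism-name label; total — never raises on any string."""
    raw = label
    s = label.strip()
    qualifier = "none"
    if s and (s[0] in _QUOTES or s[-1] in _QUOTES):
        qualifier = "candidatus-or-quoted"
        s = s.strip(_QUOTES).strip()
    if s.lower().startswith("candidatus "):
        qualifier = "candidatus-or-quoted"
        s = s[len("candidatus "):].strip()
    s = _TYPE_MARKER.sub("", s).strip()
    # a quote may sit mid-label: "Genus epithet" STRAIN
    s = s.replace('"', " ").replace("“", " ").replace("”", " ")
    tokens = s.split()
    if not tokens:
        return TaxonLabel(raw, None, None, qualifier, "")
    genus = tokens[0]
    if len(tokens) == 1:
        return TaxonLabel(raw, genus, None, qualifier, "")
    second = tokens[1]
    if second in ("sp.", "sp"):
        strain = " ".join(tokens[2:])
        return TaxonLabel(raw, genus, None, "sp-placeholder", strain)
    strain = " ".join(tokens[2:])
    return TaxonLabel(raw, genus, second, qualifier, strain)


def filter_remove_isolated(g: RelationGraph) -> RelationGraph:
    """Drop degree-0 nodes (genomes with no partner above the cutoff)."""
    adj = g.adjacency()
    return g.subgraph(v for v in g.nodes if adj[v])


def filter_larger_component(g: RelationGraph, mode: str = "only") -> RelationGraph:
    """Remove or keep only the component with the most nodes.

    On a size tie the lexicographically smallest-membered largest component
    is taken as "the" larger one and a warning is emitted.
    """
    if mode not in ("remove", "only"):
        raise ValueError(f"mode must be 'remove' or 'only', got {mode!r}")
    comps = components(g)
    if not comps:
        return g
    top_size = len(comps[0])
    ties = [c for c in comps if len(c) == top_size]
    if len(ties) > 1:
        warnings.warn(
            f"{len(ties)} components tie at the maximum size {top_size}; "
            f"taking the lexicographically smallest-membered one",
            stacklevel=2,
        )
    largest = set(min(ties))  # components() already sorts members
    if mode == "only":
        return g.subgraph(largest)
    return g.subgraph(set(g.nodes) - largest)


def filter_different_names_connected(g: RelationGraph) -> RelationGraph:
    """Keep components whose members carry >= 2 distinct binomial names.

    These are the candidate heterotypic-synonym clusters.  Undefined
    species keys (``sp.`` placeholders, single-token labels) never count
    as a distinct name but ride along with a retained component.
    """
    keep: set[str] = set()
    for comp in components(g):
        keys = {parse_binomial(v).species_key for v in comp}
        keys.discard(None)
        if len(keys) >= 2:
            keep.update(comp)
    return g.subgraph(keep)


def filter_same_names_not_connected(g: RelationGraph) -> RelationGraph:
    """Keep nodes of species whose genomes are split across components.

    A species key is *split* when its nodes occur in >= 2 distinct
    components — the signature of a misidentified assembly or a false type
    strain.  Returns the subgraph induced by all nodes of all split keys.
    """
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(components(g)):
        for v in comp:
            comp_of[v] = ci
    by_key: dict[str, set[int]] = {}
    nodes_of_key: dict[str, set[str]] = {}
    for v in g.nodes:
        key = parse_binomial(v).species_key
        if key is None:
            continue
        by_key.setdefault(key, set()).add(comp_of[v])
        nodes_of_key.setdefault(key, set()).add(v)
    keep: set[str] = set()
    for key, comps_seen in by_key.items():
        if len(comps_seen) >= 2:
            keep.update(nodes_of_key[key])
    return g.subgraph(keep)


#: CLI-facing registry; applied in the order the user gives the flags
FILTERS: dict[str, Callable[[RelationGraph], RelationGraph]] = {
    "remove-isolated": filter_remove_isolated,
    "remove-larger-component": lambda g: filter_larger_component(g, "remove"),
    "only-larger-component": lambda g: filter_larger_component(g, "only"),
    "different-names-connected": filter_different_names_connected,
    "same-names-not-connected": filter_same_names_not_connected,
}
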