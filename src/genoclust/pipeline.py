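"""End-to-end workflow: matrices -> consensus graph -> filters -> outputs.

Composes the library stages in the canonical order — read each input
matrix, symmetrize by pair averaging, binarize against its criterion, AND
the relations into a consensus, build the graph, apply the requested
filters in order — and writes the four standard outputs: a maximal-cliques
table, a components table, graph exports (GraphML, DOT, edge list), and a
static plot with nodes colored by species name, plus a JSON run summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from . import __version__
from .graph import (
    BooleanRelation,
    Criterion,
    RelationGraph,
    binarize,
    build_graph,
    components,
    consensus,
    maximal_cliques,
)
from .matrix import LabeledMatrix, read_square_matrix
from .taxa import FILTERS, parse_binomial

__all__ = ["MatrixInput", "RunConfig", "run_pipeline", "render_plot",
           "write_clusters_tsv", "write_graph_exports"]


@dataclass(frozen=True)
class MatrixInput:
    path: str
    kind: str  # 'identity' | 'coverage' | 'distance'
    criterion: Criterion


@dataclass
class RunConfig:
    """Configuration of one clustering run."""

    inputs: list[MatrixInput]
    filters: list[str] = field(default_factory=list)
    outputs: Path | str = "genoclust_out"
    cluster_granularity: str = "both"  # 'cliques' | 'components' | 'both'
    allow_scale_conversion: bool = True

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input matrix is required")
        if self.cluster_granularity not in ("cliques", "components", "both"):
            raise ValueError(
                f"cluster_granularity must be cliques/components/both, "
                f"got {self.cluster_granularity!r}"
            )
        unknown = [f for f in self.filters if f not in FILTERS]
        if unknown:
            raise ValueError(
                f"unknown filter(s) {unknown}; available: {sorted(FILTERS)}"
            )


def write_clusters_tsv(
    clusters: Sequence[tuple[str, ...]], cluster_type: str, path: Path
) -> None:
    """Cluster table: cluster_id, cluster_type, size, members (;-joined)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tcluster_type\tsize\tmembers\n")
        for i, members in enumerate(clusters, start=1):
            fh.write(
                f"{cluster_type}_{i}\t{cluster_type}\t{len(members)}\t"
                + ";".join(members)
                + "\n"
            )


def write_graph_exports(g: RelationGraph, outdir: Path) -> None:
    """GraphML, DOT and edge-list exports of the final graph."""
    nxg = g.to_networkx()
    nx.write_graphml(nxg, outdir / "graph.graphml")
    with open(outdir / "graph.dot", "w") as fh:
        fh.write("graph genoclust {\n")
        for v in g.nodes:
            fh.write(f'  "{v}";\n')
        for a, b in sorted(g.edges):
            fh.write(f'  "{a}" -- "{b}";\n')
        fh.write("}\n")
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(g.edges):
            fh.write(f"{a}\t{b}\n")


def render_plot(g: RelationGraph, path: str | Path, seed: int = 0) -> None:
    """Static force-layout rendering with nodes colored by species name.

    Distinct binomial species keys get distinct colors (cycled if the
    palette runs out); nodes without a defined species key are gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    nxg = g.to_networkx()
    keys = sorted(
        {k for k in (parse_binomial(v).species_key for v in g.nodes) if k}
    )
    cmap = colormaps["tab20"]
    color_of = {k: cmap(i % 20) for i, k in enumerate(keys)}
    node_colors = [
        color_of.get(parse_binomial(v).species_key, (0.6, 0.6, 0.6, 1.0))
        for v in g.nodes
    ]
    fig, ax = plt.subplots(figsize=(8, 8))
    if g.nodes:
        pos = nx.spring_layout(nxg, seed=seed)
        nx.draw_networkx_edges(nxg, pos, ax=ax, edge_color="#999999")
        nx.draw_networkx_nodes(
            nxg, pos, nodelist=list(g.nodes), node_color=node_colors, ax=ax,
            node_size=250, edgecolors="black", linewidths=0.5,
        )
        nx.draw_networkx_labels(nxg, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def _load_relation(inp: MatrixInput, allow_scale_conversion: bool) -> BooleanRelation:
    try:
        m = read_square_matrix(inp.path, kind=inp.kind)
    except Exception as e:
        raise type(e)(f"[input {inp.path}, stage read] {e}") from e
    return binarize(m, inp.criterion, allow_scale_conversion=allow_scale_conversion)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write outputs; returns the run summary.

    Deterministic given identical inputs: all cluster tables and graph
    exports are byte-identical across re-runs.
    """
    outdir = Path(cfg.outputs)
    outdir.mkdir(parents=True, exist_ok=True)

    relations: list[BooleanRelation] = []
    for inp in cfg.inputs:
        try:
            relations.append(_load_relation(inp, cfg.allow_scale_conversion))
        except Exception as e:
            if str(e).startswith("[input "):
                raise
            raise type(e)(f"[input {inp.path}, stage binarize] {e}") from e
    rel = consensus(relations)
    g = build_graph(rel)

    applied: list[str] = []
    for name in cfg.filters:
        g = FILTERS[name](g)
        applied.append(name)

    comps = components(g)
    cliqs = maximal_cliques(g)
    if cfg.cluster_granularity in ("cliques", "both"):
        write_clusters_tsv(cliqs, "clique", outdir / "max_cliques.tsv")
    if cfg.cluster_granularity in ("components", "both"):
        write_clusters_tsv(comps, "component", outdir / "components.tsv")
    write_graph_exports(g, outdir)
    render_plot(g, outdir / "graph.svg")

    summary = {
        "genoclust_version": __version__,
        "inputs": [
            {
                "path": str(inp.path),
                "kind": inp.kind,
                "criterion": {
                    "threshold": inp.criterion.threshold,
                    "direction": inp.criterion.direction,
                    "scale": inp.criterion.scale,
                },
            }
            for inp in cfg.inputs
        ],
        "filters_applied": applied,
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "n_components": len(comps),
        "n_cliques": len(cliqs),
        "component_sizes": [len(c) for c in comps],
        "clique_sizes": [len(c) for c in cliqs],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
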