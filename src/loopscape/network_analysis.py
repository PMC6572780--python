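"""Chromatin interaction networks (ChINs) and term enrichment.

Anchors are nodes, interactions are edges; a ChIN is a connected component
with at least three interactions.  Gene sets attached to a component's
proximal nodes can be tested for annotation-term enrichment with the same
hypergeometric tail + Benjamini-Hochberg machinery used for loop calling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .anchor_annotation import AnchorAnnotation
from .interaction_calling import bh_adjust, hypergeom_tail
from .io_formats import GenomicInterval, Interaction


@dataclass
class ChinComponent:
    """One connected component of the anchor-interaction graph."""

    id: str
    nodes: dict[str, str]  # peak id -> "P"/"D" (or "?" when unannotated)
    edges: list[Interaction]
    genes: tuple[str, ...] = ()

    @property
    def n_interactions(self) -> int:
        return len(self.edges)


def build_chins(
    interactions: Sequence[Interaction],
    min_interactions: int = 3,
    annotations: Mapping[str, AnchorAnnotation] | None = None,
) -> list[ChinComponent]:
    """Connected components with >= min_interactions edges, largest first.

    Nodes are peak ids; parallel interactions between the same anchor pair
    count as separate edges.
    """
    g = nx.MultiGraph()
    for idx, it in enumerate(interactions):
        g.add_edge(it.peak_a, it.peak_b, key=idx, interaction=it)
    components: list[ChinComponent] = []
    for nodes in nx.connected_components(g):
        edges = [
            data["interaction"]
            for _, _, data in g.subgraph(nodes).edges(data=True)
        ]
        if len(edges) < min_interactions:
            continue
        node_types = {}
        gene_ids: set[str] = set()
        for n in nodes:
            ann = annotations.get(n) if annotations else None
            node_types[n] = ann.type if ann else "?"
            if ann and ann.type == "P":
                gene_ids.update(ann.genes)
        components.append(
            ChinComponent(
                id="",
                nodes=node_types,
                edges=edges,
                genes=tuple(sorted(gene_ids)),
            )
        )
    components.sort(key=lambda c: (-c.n_interactions, sorted(c.nodes)[0]))
    for i, comp in enumerate(components, start=1):
        comp.id = f"chin_{i:04d}"
    return components


def degree_stats(component: ChinComponent) -> dict[str, int]:
    """Node degree = number of incident edges (sum = 2 * edge count)."""
    deg: dict[str, int] = {n: 0 for n in component.nodes}
    for it in component.edges:
        deg[it.peak_a] += 1
        deg[it.peak_b] += 1
    return deg


def component_span(component: ChinComponent) -> dict[str, GenomicInterval]:
    """Per-chromosome hull [min anchor start, max anchor end) of a component."""
    lo: dict[str, int] = {}
    hi: dict[str, int] = {}
    for it in component.edges:
        for iv in (it.anchor_a, it.anchor_b):
            lo[iv.chrom] = min(lo.get(iv.chrom, iv.start), iv.start)
            hi[iv.chrom] = max(hi.get(iv.chrom, iv.end), iv.end)
    return {c: GenomicInterval(c, lo[c], hi[c]) for c in lo}


@dataclass
class ComponentOverlap:
    component_id: str
    overlap_fraction: float
    conserved: bool


def pp_component_overlap(
    components_a: Sequence[ChinComponent],
    components_b: Sequence[ChinComponent],
    threshold: float = 0.65,
    metric: str = "edges",
) -> list[ComponentOverlap]:
    """Cross-tissue conservation of P-P network components.

    For each A component, the fraction of its P-P edges matched anywhere in
    B (both-anchor >= 1 bp overlap); a component is conserved when the
    fraction exceeds ``threshold``.  ``metric='nodes'`` uses instead the
    fraction of A nodes whose anchor interval overlaps some B node.
    """
    if metric not in ("edges", "nodes"):
        raise ValueError("metric must be 'edges' or 'nodes'")
    b_edges = [e for comp in components_b for e in comp.edges]
    from .interaction_calling import _anchor_tree, match_interaction

    trees = _anchor_tree(b_edges)
    b_anchor_ivs: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for e in b_edges:
        for iv in (e.anchor_a, e.anchor_b):
            b_anchor_ivs[iv.chrom].append((iv.start, iv.end))

    out = []
    for comp in components_a:
        if metric == "edges":
            if not comp.edges:
                frac = 0.0
            else:
                matched = sum(
                    1
                    for e in comp.edges
                    if match_interaction(e, b_edges, trees) is not None
                )
                frac = matched / len(comp.edges)
        else:
            anchor_of = {}
            for e in comp.edges:
                anchor_of[e.peak_a] = e.anchor_a
                anchor_of[e.peak_b] = e.anchor_b
            if not anchor_of:
                frac = 0.0
            else:
                hits = 0
                for iv in anchor_of.values():
                    if any(
                        s < iv.end and iv.start < e
                        for s, e in b_anchor_ivs.get(iv.chrom, ())
                    ):
                        hits += 1
                frac = hits / len(anchor_of)
        out.append(ComponentOverlap(comp.id, frac, frac > threshold))
    return out


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    hits_in_component: int
    component_genes: int
    hits_in_genome: int
    genome_genes: int
    p: float
    fdr: float
    significant: bool


def term_enrichment(
    component_genes: Sequence[str],
    gene_terms: Mapping[str, set],
    universe: Sequence[str],
    fdr_max: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric term enrichment of a component's gene set.

    Population = the gene universe, successes = genome-wide term carriers,
    draws = the component's genes; BH across the terms tested.
    """
    comp = set(component_genes)
    uni = set(universe)
    if not comp:
        return []
    if not comp <= uni:
        raise ValueError("component genes must be contained in the universe")
    genome_hits: dict[str, int] = defaultdict(int)
    comp_hits: dict[str, int] = defaultdict(int)
    for gene in uni:
        for term in gene_terms.get(gene, ()):
            genome_hits[term] += 1
            if gene in comp:
                comp_hits[term] += 1
    terms = sorted(genome_hits)
    if not terms:
        return []
    pvals = [
        hypergeom_tail(comp_hits[t], genome_hits[t], len(comp), len(uni))
        for t in terms
    ]
    fdrs = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term=t,
            hits_in_component=comp_hits[t],
            component_genes=len(comp),
            hits_in_genome=genome_hits[t],
            genome_genes=len(uni),
            p=float(p),
            fdr=float(q),
            significant=bool(q < fdr_max),
        )
        for t, p, q in zip(terms, pvals, fdrs)
    ]
    rows.sort(key=lambda r: r.p)
    return rows
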