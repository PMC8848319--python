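"""Network neighborhoods around significant gene pairs and hypergeometric
gene-set enrichment with a Bonferroni-corrected cutoff.

The neighborhood of a significant gene pair (A, B) contains A, B, and every
gene that (1) lies on any shortest path between A and B in the gene-model
graph after the direct A-B edge is removed, and (2) itself takes part in a
significant gene pair with another gene on those paths. Only neighborhoods
of >= 3 genes are tested for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
from scipy import stats

from .io_formats import GeneSetCollection, SnpGeneMap, ValidationError
from .model_building import GeneModel

__all__ = [
    "Neighborhood",
    "EnrichmentResult",
    "gene_model_graph",
    "build_neighborhood",
    "build_universe",
    "hypergeom_enrich",
]


@dataclass
class Neighborhood:
    gene_a: str
    gene_b: str
    members: set[str]
    tested: bool

    @property
    def label(self) -> str:
        return f"{self.gene_a}--{self.gene_b}"


@dataclass
class EnrichmentResult:
    neighborhood_id: str
    set_name: str
    overlap: int
    set_size: int
    neighborhood_size: int
    universe_size: int
    p: float
    threshold: float
    significant: bool


def gene_model_graph(gene_models: Iterable[GeneModel]) -> nx.Graph:
    """Unweighted undirected graph over the filtered gene models."""
    g = nx.Graph()
    for gm in gene_models:
        g.add_edge(gm.gene_a, gm.gene_b)
    return g


def build_neighborhood(
    gene_model: GeneModel,
    graph: nx.Graph,
    significant_gene_models: Iterable[GeneModel],
) -> Neighborhood:
    """Shortest-path neighborhood of one significant gene pair.

    With the direct edge removed, a node v is on a shortest A-B path iff
    d(A, v) + d(v, B) = d(A, B). Intermediate genes are kept only when they
    form a significant gene pair with >= 1 other gene on those paths (the
    partner may be an endpoint); the endpoints are always members. The
    neighborhood is tested downstream iff it has >= 3 members.
    """
    a, b = gene_model.gene_a, gene_model.gene_b
    if a not in graph or b not in graph:
        raise ValidationError(f"gene(s) of model ({a},{b}) absent from the gene-model graph")
    work = graph.copy()
    if work.has_edge(a, b):
        work.remove_edge(a, b)
    try:
        da = nx.single_source_shortest_path_length(work, a)
        if b not in da:
            raise nx.NetworkXNoPath
        db = nx.single_source_shortest_path_length(work, b)
        dist = da[b]
    except nx.NetworkXNoPath:
        return Neighborhood(a, b, {a, b}, tested=False)
    on_path = {v for v in da if v in db and da[v] + db[v] == dist}
    sig_partners: dict[str, set[str]] = {}
    for gm in significant_gene_models:
        sig_partners.setdefault(gm.gene_a, set()).add(gm.gene_b)
        sig_partners.setdefault(gm.gene_b, set()).add(gm.gene_a)
    members = {a, b}
    for v in on_path - {a, b}:
        if sig_partners.get(v, set()) & on_path:
            members.add(v)
    return Neighborhood(a, b, members, tested=len(members) >= 3)


def build_universe(
    gene_sets: GeneSetCollection,
    mapping: SnpGeneMap,
    gene_models: Sequence[GeneModel],
    mode: str = "biofiltered",
) -> set[str]:
    """Enrichment background: annotated genes mappable to a dataset SNP.

    ``standard``: genes in any set that the mapping assigns to >= 1 SNP.
    ``biofiltered``: additionally restricted to genes in >= 1 gene model.
    """
    if mode not in ("standard", "biofiltered"):
        raise ValidationError(f"unknown universe mode {mode!r}")
    universe = gene_sets.gene_universe() & mapping.genes()
    if mode == "biofiltered":
        in_models = {g for gm in gene_models for g in gm.pair}
        universe &= in_models
    if not universe:
        raise ValidationError("enrichment universe is empty")
    return universe


def hypergeom_enrich(
    neighborhoods: Sequence[Neighborhood],
    gene_sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    bonferroni_scope: str = "global",
    set_size_bounds: Optional[tuple[int, int]] = None,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Upper-tail hypergeometric enrichment of tested neighborhoods.

    For each tested neighborhood and each gene set sharing >= 1 gene with
    it, p = P(X >= k) with population |universe|, successes |set ∩ universe|
    and draws |neighborhood ∩ universe|. The Bonferroni denominator is
    (#pathways x #tested neighborhoods) where, under the default ``global``
    scope, #pathways counts the distinct sets touched by ANY tested
    neighborhood (one shared threshold); under ``per_neighborhood`` each
    neighborhood counts only its own touched sets. Significance is strict:
    p < alpha / denominator. Returns (results, skip log).
    """
    if bonferroni_scope not in ("global", "per_neighborhood"):
        raise ValidationError(f"unknown bonferroni_scope {bonferroni_scope!r}")
    tested = [nb for nb in neighborhoods if nb.tested]
    skipped: list[str] = []
    names = sorted(gene_sets.sets)
    if set_size_bounds is not None:
        lo, hi = set_size_bounds
        names = [nm for nm in names if lo <= len(gene_sets.sets[nm] & universe) <= hi]

    draws_by_nb: dict[str, set[str]] = {}
    touched_by_nb: dict[str, list[str]] = {}
    for nb in tested:
        draw = nb.members & universe
        if not draw:
            skipped.append(f"{nb.label}: no member in universe")
            continue
        draws_by_nb[nb.label] = draw
        touched_by_nb[nb.label] = [
            nm for nm in names if gene_sets.sets[nm] & draw
        ]
    n_tested = len(draws_by_nb)
    global_touched = {nm for lst in touched_by_nb.values() for nm in lst}

    results: list[EnrichmentResult] = []
    for label, draw in draws_by_nb.items():
        n_path = len(global_touched) if bonferroni_scope == "global" else len(touched_by_nb[label])
        denom = max(1, n_path * n_tested)
        threshold = alpha / denom
        for nm in touched_by_nb[label]:
            in_universe = gene_sets.sets[nm] & universe
            k = len(in_universe & draw)
            p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(draw)))
            p = min(max(p, 5e-324), 1.0)
            results.append(
                EnrichmentResult(
                    neighborhood_id=label, set_name=nm, overlap=k,
                    set_size=len(in_universe), neighborhood_size=len(draw),
                    universe_size=len(universe), p=p,
                    threshold=threshold, significant=p < threshold,
                )
            )
    results.sort(key=lambda r: (r.p, r.neighborhood_id, r.set_name))
    return results, skipped
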