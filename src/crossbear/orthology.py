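"""One-to-one ortholog reconciliation from many-to-many Biomart-style edges.

Biomart reports orthology candidates as scored cross-species gene pairs,
often many-to-many. We reduce them to one-to-one maps in two steps: a greedy
maximum-score matching between a hub species and every other species, then a
transitive "triangle" pass that links an apex-species gene A to an untouched
gene C in a third species whenever A-B is an accepted edge and B-C appears in
the independent one-to-one map of the (s(B), s(C)) pair. No attempt is made
to keep the result consistent with the species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrthologEdge", "PairwiseMap", "OrthologyGraph",
    "greedy_pairwise_map", "fill_transitive", "build_one_to_one",
    "translate_matrix", "read_edges", "write_table",
]


@dataclass(frozen=True)
class OrthologEdge:
    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    percent_identity: float

    def __post_init__(self):
        if self.species_a == self.species_b:
            raise ValueError("edges must connect two different species")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity must lie in [0, 100]")


@dataclass
class PairwiseMap:
    """Accepted one-to-one edges for one ordered species pair."""

    species_a: str
    species_b: str
    pairs: dict = field(default_factory=dict)    # gene_a -> gene_b
    scores: dict = field(default_factory=dict)   # (gene_a, gene_b) -> score

    def partner(self, gene_a: str):
        return self.pairs.get(gene_a)


@dataclass
class OrthologyGraph:
    """Reduced graph G': adjacency gene -> {species -> (gene, score)}."""

    species_of: dict                      # gene -> species
    adjacency: dict = field(default_factory=dict)

    def has_any_edge(self, gene: str) -> bool:
        return bool(self.adjacency.get(gene))

    def neighbor(self, gene: str, species: str):
        entry = self.adjacency.get(gene, {}).get(species)
        return entry[0] if entry else None

    def add_edge(self, g1: str, g2: str, score: float):
        s1, s2 = self.species_of[g1], self.species_of[g2]
        if s1 == s2:
            raise ValueError("within-species edge")
        for g, s, other in ((g1, s2, g2), (g2, s1, g1)):
            if self.neighbor(g, s) not in (None, other):
                raise ValueError(f"{g} already linked to a {s} gene")
        self.adjacency.setdefault(g1, {})[s2] = (g2, score)
        self.adjacency.setdefault(g2, {})[s1] = (g1, score)

    def edges(self):
        seen = set()
        for g, nbrs in self.adjacency.items():
            for sp, (h, score) in nbrs.items():
                key = tuple(sorted((g, h)))
                if key not in seen:
                    seen.add(key)
                    yield g, h, score


def _sorted_edges(edges):
    # decreasing score; ties broken lexicographically on gene ids
    return sorted(edges, key=lambda e: (-e.percent_identity, e.gene_a, e.gene_b))


def greedy_pairwise_map(edges) -> PairwiseMap:
    """Greedy one-to-one matching: accept edges in decreasing score order.

    An edge is accepted iff neither endpoint already carries an accepted
    edge. Equal scores are broken lexicographically on (gene_a, gene_b).
    """
    edges = list(edges)
    if not edges:
        raise ValueError("no edges supplied")
    pair = (edges[0].species_a, edges[0].species_b)
    if any((e.species_a, e.species_b) != pair for e in edges):
        raise ValueError("all edges must connect the same ordered species pair")
    out = PairwiseMap(*pair)
    used_b = set()
    for e in _sorted_edges(edges):
        if e.gene_a in out.pairs or e.gene_b in used_b:
            continue
        out.pairs[e.gene_a] = e.gene_b
        used_b.add(e.gene_b)
        out.scores[(e.gene_a, e.gene_b)] = e.percent_identity
    return out


def fill_transitive(gprime: OrthologyGraph, pair_maps: dict,
                    species_order, apex: str) -> OrthologyGraph:
    """Add transitive triangle edges to G' in place and return it.

    For each species pair (sB, sC) in `species_order`, candidate triangles
    (A, B, C) must satisfy: s(A) = apex; s(B), s(C) != apex; s(B) != s(C);
    A-B is an edge of G'; the one-to-one map of (sB, sC) links B to C; C has
    no apex-species neighbour in G'; and A has no s(C) neighbour in G'. The
    last two conditions operationalize "A has no ortholog in s(C) yet":
    requiring C to be completely untouched would be unsatisfiable whenever
    the B-C edge itself sits in G' through the hub maps. Within a pair,
    triangles are applied greedily by decreasing B-C score.
    """
    for sB, sC in species_order:
        if apex in (sB, sC):
            continue
        key = (sB, sC)
        if key not in pair_maps:
            raise KeyError(f"missing pairwise map for species pair {key}")
        pm = pair_maps[key]
        rev = {b: a for a, b in pm.pairs.items()}
        directions = (
            (sB, sC, pm.pairs, lambda b, c: pm.scores[(b, c)]),
            (sC, sB, rev, lambda b, c: pm.scores[(c, b)]),
        )
        candidates = []
        for a, nbrs in list(gprime.adjacency.items()):
            if gprime.species_of[a] != apex:
                continue
            for s_b, s_c, fwd, score_of in directions:
                b_entry = nbrs.get(s_b)
                if b_entry is None:
                    continue
                b = b_entry[0]
                c = fwd.get(b)
                if c is None or gprime.neighbor(c, apex) is not None:
                    continue
                if gprime.neighbor(a, s_c) is not None:
                    continue
                candidates.append((score_of(b, c), a, b, c))
        candidates.sort(key=lambda t: (-t[0], t[1], t[3]))
        for score, a, b, c in candidates:
            if (gprime.neighbor(c, apex) is not None
                    or gprime.neighbor(a, gprime.species_of[c]) is not None):
                continue
            gprime.add_edge(a, c, score)
    return gprime


def _split_by_pair(edges):
    by_pair = {}
    for e in edges:
        key = tuple(sorted((e.species_a, e.species_b)))
        if (e.species_a, e.species_b) != key:
            e = OrthologEdge(e.gene_b, e.species_b, e.gene_a, e.species_a,
                             e.percent_identity)
        by_pair.setdefault(key, []).append(e)
    return by_pair


def build_one_to_one(edges, hub: str, apex: str | None = None,
                     species_order=None, min_score: float | None = None
                     ) -> pd.DataFrame:
    """Full reconciliation: hub-vs-other greedy maps, then transitive filling.

    Parameters
    ----------
    edges
        Iterable of OrthologEdge across any number of species.
    hub
        Species matched one-to-one against every other species first.
    apex
        Species whose genes may gain transitive edges; default "human" if
        present, else the hub. Pass ``"none"`` to skip transitive filling.
    species_order
        Ordered (speciesB, speciesC) pairs scanned for triangles; default is
        all pairs sorted with hub pairs first.
    min_score
        Optional percent-identity threshold applied before matching.

    Returns
    -------
    DataFrame with one column per species; each row is an ortholog tuple,
    NaN where a species has no member.
    """
    edges = list(edges)
    if min_score is not None:
        edges = [e for e in edges if e.percent_identity >= min_score]
    species = sorted({e.species_a for e in edges} | {e.species_b for e in edges})
    if hub not in species:
        raise KeyError(f"hub species {hub!r} not present in the edge table")
    if apex is None:
        apex = "human" if "human" in species else hub
    if apex not in species and apex != "none":
        raise KeyError(f"apex species {apex!r} not present in the edge table")

    by_pair = _split_by_pair(edges)
    species_of = {}
    for es in by_pair.values():
        for e in es:
            species_of[e.gene_a] = e.species_a
            species_of[e.gene_b] = e.species_b

    graph = OrthologyGraph(species_of=species_of)
    pair_maps = {}
    for key, es in sorted(by_pair.items()):
        pm = greedy_pairwise_map(es)
        pair_maps[key] = pm
        pair_maps[key[::-1]] = PairwiseMap(
            key[1], key[0],
            pairs={b: a for a, b in pm.pairs.items()},
            scores={(b, a): s for (a, b), s in pm.scores.items()})
        if hub in key:
            for (ga, gb), score in pm.scores.items():
                graph.add_edge(ga, gb, score)

    if apex != "none":
        if species_order is None:
            others = [s for s in species if s != apex]
            species_order = [tuple(sorted((hub, s))) for s in others if s != hub]
            species_order += [p for p in sorted(by_pair) if hub not in p
                              and apex not in p]
        present = set(species)
        species_order = [p for p in species_order if set(p) <= present]
        for p in species_order:
            key = tuple(sorted(p))
            if key not in pair_maps and apex not in p:
                pair_maps[key] = PairwiseMap(*key)
                pair_maps[key[::-1]] = PairwiseMap(*key[::-1])
        fill_transitive(graph, pair_maps, species_order, apex)

    # emit tuples: breadth-first from each hub (or apex) anchor, filling one
    # slot per species first-come
    rows = []
    seen = set()
    for g in sorted(graph.adjacency):
        if graph.species_of[g] not in (hub, apex) or g in seen:
            continue
        component = {}
        queue = [g]
        while queue:
            v = queue.pop(0)
            sv = graph.species_of[v]
            if component.get(sv, v) != v:
                continue  # slot already taken by an earlier gene
            if sv in component:
                continue
            component[sv] = v
            seen.add(v)
            for sp, (h, _) in sorted(graph.adjacency.get(v, {}).items()):
                if sp not in component:
                    queue.append(h)
        rows.append({sp: component.get(sp) for sp in species})
    return pd.DataFrame(rows, columns=species)


def translate_matrix(counts: pd.DataFrame, table: pd.DataFrame,
                     source: str, target: str) -> pd.DataFrame:
    """Rename the gene axis (columns) of `counts` from source to target ids.

    Genes without a mapped target ortholog are dropped; values are unchanged.
    """
    sub = table[[source, target]].dropna()
    if sub[target].duplicated().any() or sub[source].duplicated().any():
        raise ValueError("translation table is not one-to-one")
    mapping = dict(zip(sub[source], sub[target]))
    keep = [g for g in counts.columns if g in mapping]
    out = counts[keep].copy()
    out.columns = [mapping[g] for g in keep]
    return out


def read_edges(path) -> list:
    """Read a TSV of gene_a, species_a, gene_b, species_b, percent_identity."""
    df = pd.read_csv(path, sep="\t")
    return [OrthologEdge(str(r.gene_a), str(r.species_a), str(r.gene_b),
                         str(r.species_b), float(r.percent_identity))
            for r in df.itertuples()]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
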