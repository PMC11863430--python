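"""Independent brute-force references shared by the test modules.

These deliberately re-derive results from first principles (plain dict/set
replay of the matching rules, exhaustive sign-assignment enumeration) so
they share no code with the package implementations they check.
"""

import itertools

import numpy as np
from scipy import stats

from crossbear.orthology import OrthologEdge


def ref_greedy(edges):
    """Replay of greedy one-to-one matching: decreasing score, tie on ids."""
    taken_a, taken_b, accepted = set(), set(), {}
    for e in sorted(edges, key=lambda e: (-e.percent_identity, e.gene_a,
                                          e.gene_b)):
        if e.gene_a in taken_a or e.gene_b in taken_b:
            continue
        taken_a.add(e.gene_a)
        taken_b.add(e.gene_b)
        accepted[e.gene_a] = e.gene_b
    return accepted


def ref_build(edges, hub, apex, order):
    """Replay of the full reconciliation: hub maps then transitive triangles.

    Returns the edge set of the reduced graph as frozen gene pairs.
    """
    species_of, by_pair = {}, {}
    for e in edges:
        key = tuple(sorted((e.species_a, e.species_b)))
        a, b = ((e.gene_a, e.gene_b) if (e.species_a, e.species_b) == key
                else (e.gene_b, e.gene_a))
        by_pair.setdefault(key, []).append(
            OrthologEdge(a, key[0], b, key[1], e.percent_identity))
        species_of[e.gene_a] = e.species_a
        species_of[e.gene_b] = e.species_b
    maps = {k: ref_greedy(v) for k, v in by_pair.items()}
    scores = {k: {(e.gene_a, e.gene_b): e.percent_identity for e in v}
              for k, v in by_pair.items()}
    gp = set()
    for k, m in maps.items():
        if hub in k:
            gp |= {frozenset((a, b)) for a, b in m.items()}

    def neighbor_in(g, sp):
        for p in gp:
            if g in p:
                (other,) = p - {g}
                if species_of[other] == sp:
                    return other
        return None

    for sB, sC in order:
        if apex in (sB, sC):
            continue
        key = tuple(sorted((sB, sC)))
        fwd = maps.get(key, {})
        rev = {v: k for k, v in fwd.items()}
        cands = []
        for p in list(gp):
            for a in p:
                if species_of[a] != apex:
                    continue
                (b,) = p - {a}
                for mapping, s_b in ((fwd, key[0]), (rev, key[1])):
                    if species_of[b] != s_b:
                        continue
                    c = mapping.get(b)
                    if c is None or neighbor_in(c, apex) is not None:
                        continue
                    if neighbor_in(a, species_of[c]) is not None:
                        continue
                    sc = scores[key][(b, c) if s_b == key[0] else (c, b)]
                    cands.append((sc, a, b, c))
        for sc, a, b, c in sorted(cands, key=lambda t: (-t[0], t[1], t[3])):
            if (neighbor_in(c, apex) is not None
                    or neighbor_in(a, species_of[c]) is not None):
                continue
            gp.add(frozenset((a, c)))
    return gp


def random_edges(rng, n_per_species=6, species=("mouse", "opossum", "chicken")):
    """Random scored many-to-many edge tables over up to 3 species."""
    edges = []
    for ai in range(len(species)):
        for bi in range(ai + 1, len(species)):
            sa, sb = species[ai], species[bi]
            n_edges = rng.integers(3, 2 * n_per_species)
            for _ in range(n_edges):
                i, j = rng.integers(n_per_species, size=2)
                edges.append(OrthologEdge(f"{sa}{i}", sa, f"{sb}{j}", sb,
                                          float(rng.integers(50, 101))))
    seen, uniq = set(), []
    for e in edges:
        key = (e.gene_a, e.gene_b)
        if key not in seen:
            seen.add(key)
            uniq.append(e)
    return uniq


def table_edge_set(table):
    """Flatten a per-species ortholog table into anchor-gene edge pairs."""
    got = set()
    for _, row in table.iterrows():
        genes = [g for g in row if isinstance(g, str)]
        anchor = next(g for g in genes if g.startswith("mouse"))
        for g in genes:
            if g != anchor:
                got.add(frozenset((anchor, g)))
    return got


def enumeration_signed_rank_pvalue(values, null_median, alternative):
    """One-sample signed-rank p by enumerating every sign assignment."""
    d = np.asarray(values, dtype=float) - null_median
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if alternative == "greater":
            hits += w >= w_obs - 1e-12
        else:
            hits += w <= w_obs + 1e-12
    return hits / total
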