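"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain
Python loops and scalar arithmetic only, so they can serve as
independent references for the library implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Windowed FST
# ---------------------------------------------------------------------------

def brute_windowed_fst(
    dosage, chroms, positions, group_rows_a, group_rows_b, extents, window_bp, step_bp
):
    """Ratio-of-sums windowed FST recomputed from raw dosages with
    scalar loops.  Returns {(chrom, start, end): value} for windows with
    >= 1 informative locus."""
    out = {}
    n_loci = len(positions)
    for chrom, extent in extents.items():
        start = 1
        while start <= extent:
            num = den = 0.0
            k = 0
            for j in range(n_loci):
                if chroms[j] != chrom or not (start <= positions[j] < start + window_bp):
                    continue
                stats = []
                ok = True
                for rows in (group_rows_a, group_rows_b):
                    n_called = 0
                    alt = 0
                    for i in rows:
                        d = dosage[i][j]
                        if d != MISSING:
                            n_called += 1
                            alt += d
                    if n_called == 0:
                        ok = False
                        break
                    stats.append((n_called, alt / (2.0 * n_called)))
                if not ok:
                    continue
                (n1, p1), (n2, p2) = stats
                p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
                msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2  # s-1 = 1
                msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 1)
                nc = (n1 + n2) / 2.0
                d_loc = msp + (nc - 1.0) * msg
                if d_loc == 0.0:
                    continue
                num += msp - msg
                den += d_loc
                k += 1
            if k > 0 and den != 0.0:
                out[(chrom, start, start + window_bp)] = num / den
            start += step_bp
    return out


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------

def brute_overlaps(regions, genes):
    """All-pairs overlap: {region_key: sorted gene ids} for half-open
    1-based intervals given as (chrom, start, end) tuples / objects."""
    out = {}
    for r in regions:
        hits = []
        for g in genes:
            if g.chrom == r.chrom and g.start_bp < r.end_bp and g.end_bp > r.start_bp:
                hits.append(g.gene_id)
        out[(r.chrom, r.start_bp, r.end_bp)] = sorted(hits)
    return out


# ---------------------------------------------------------------------------
# HWE by direct enumeration
# ---------------------------------------------------------------------------

def brute_hwe_exact(hom_ref, het, hom_alt):
    """Exact HWE p by direct factorial enumeration of heterozygote
    counts conditional on the allele counts."""
    n = hom_ref + het + hom_alt
    na = 2 * hom_ref + het  # copies of the first allele
    nb = 2 * hom_alt + het

    def prob(h):
        if (na - h) % 2 or h > min(na, nb) or h < 0:
            return 0.0
        a_hom = (na - h) // 2
        b_hom = (nb - h) // 2
        return (
            math.factorial(n)
            / (math.factorial(a_hom) * math.factorial(h) * math.factorial(b_hom))
            * 2**h
            * math.factorial(na)
            * math.factorial(nb)
            / math.factorial(2 * n)
        )

    hs = [h for h in range(min(na, nb) + 1) if (na - h) % 2 == 0]
    probs = {h: prob(h) for h in hs}
    total = sum(probs.values())
    p_obs = probs[het] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# Unrooted tree topology enumeration + least-squares fit (NJ oracle)
# ---------------------------------------------------------------------------

def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward.  Built by inserting each
    leaf on every edge of each smaller topology.
    """
    assert n >= 3
    base = [[(0, n), (1, n), (2, n)]]  # star on 3 leaves
    next_internal = n + 1
    trees = base
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal
                new = edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (w, leaf)]
                new_trees.append(new)
        next_internal += 1
        trees = new_trees
    return trees


def _paths(edges, n):
    """Edge-index sets on the path between every leaf pair."""
    adj = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    out = {}
    for a in range(n):
        # BFS from a
        prev = {a: (None, None)}
        queue = [a]
        while queue:
            x = queue.pop()
            for y, k in adj[x]:
                if y not in prev:
                    prev[y] = (x, k)
                    queue.append(y)
        for b in range(a + 1, n):
            path = []
            x = b
            while x != a:
                px, k = prev[x]
                path.append(k)
                x = px
            out[(a, b)] = path
    return out


def ls_fit(edges, n, dist):
    """Least-squares branch lengths for a topology; returns (lengths,
    residual sum of squares)."""
    paths = _paths(edges, n)
    pairs = sorted(paths)
    a = np.zeros((len(pairs), len(edges)))
    y = np.array([dist[i][j] for i, j in pairs])
    for r, pair in enumerate(pairs):
        for k in paths[pair]:
            a[r, k] = 1.0
    x, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = float(((a @ x - y) ** 2).sum())
    return x, resid


def topology_bipartitions(edges, n):
    """Non-trivial bipartitions (canonical smaller side) of a topology."""
    out = set()
    for k, (u, v) in enumerate(edges):
        adj = {}
        for k2, (a, b) in enumerate(edges):
            if k2 == k:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj.get(x, ()):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n - 1:
            other = frozenset(range(n)) - frozenset(side)
            out.add(min(frozenset(side), other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def random_additive_instance(n, rng):
    """Random binary topology with uniform branch lengths and its exact
    path-distance matrix."""
    topos = None
    # build one random topology by random insertion (not via enumeration)
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        w = next_internal
        next_internal += 1
        edges += [(u, w), (w, v), (w, leaf)]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _paths(edges, n)
    d = np.zeros((n, n))
    for (a, b), path in paths.items():
        d[a, b] = d[b, a] = sum(lengths[k] for k in path)
    del topos
    return edges, lengths, d


def brute_best_topology(n, dist):
    """Bipartition set of the topology with minimal least-squares
    residual over the full enumeration."""
    best = (np.inf, None)
    for edges in enumerate_topologies(n):
        _, resid = ls_fit(edges, n, dist)
        if resid < best[0] - 1e-12:
            best = (resid, edges)
    return topology_bipartitions(best[1], n), best[0]


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------

def brute_site_pi(alleles):
    """Proportion of mismatching pairs among a list of 0/1 alleles."""
    pairs = list(itertools.combinations(range(len(alleles)), 2))
    diff = sum(1 for i, j in pairs if alleles[i] != alleles[j])
    return diff / len(pairs)


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
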