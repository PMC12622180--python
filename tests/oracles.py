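"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written against different primitives than
the implementation under test (Biopython translation, explicit enumeration,
direct formula evaluation) so the two routes cannot share a bug.
"""
from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_sites_oracle(codon: str, R: float) -> tuple[float, float]:
    """Weighted synonymous site count by explicit per-change enumeration."""
    aa = translate(codon)
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    syn = 0.0
    for pos in range(3):
        weights = []
        syn_w = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = R if (codon[pos], alt) in transitions else 1.0
            weights.append(w)
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate(mutant) == aa:
                syn_w += w
        syn += syn_w / sum(weights)
    return syn, 3.0 - syn


def ng_differences_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Pathway averaging by brute-force permutation enumeration."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    clean, stopped = [], []
    for order in permutations(diff):
        cur = c1
        s = n = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate(nxt) == "*":
                through_stop = True
            if translate(nxt) == translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        (stopped if through_stop else clean).append((s, n))
    use = clean if clean else stopped
    syn = sum(x[0] for x in use) / len(use)
    return syn, len(diff) - syn


def tajima_d_oracle(seqs: list[str]) -> float | None:
    """Direct evaluation of Tajima's formula from scratch."""
    n = len(seqs)
    if n < 4:
        return None
    L = len(seqs[0])
    cols = [
        c
        for c in range(L)
        if all(s[c] in "ACGT" for s in seqs)
    ]
    S = sum(1 for c in cols if len({s[c] for s in seqs}) > 1)
    if S == 0:
        return None
    k_sum = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            k_sum += sum(1 for c in cols if seqs[i][c] != seqs[j][c])
    pi = k_sum / pairs
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose point
    probability does not exceed that of the observed table.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(x: int) -> float:
        return math.lgamma(x + 1)

    def log_p(x: int) -> float:
        # table (x, r1-x, c1-x, r2-c1+x)
        return (
            log_fact(r1)
            + log_fact(r2)
            + log_fact(c1)
            + log_fact(n - c1)
            - log_fact(n)
            - log_fact(x)
            - log_fact(r1 - x)
            - log_fact(c1 - x)
            - log_fact(r2 - (c1 - x))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def random_additive_matrix(n: int, rng: np.random.Generator):
    """A random unrooted binary tree and its exact leaf distance matrix."""
    import heapq

    labels = [f"T{i}" for i in range(n)]
    adj: dict[int, dict[int, float]] = {}
    nxt = n
    active = list(range(n))
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        new = nxt
        nxt += 1
        for x, l in ((a, rng.uniform(0.05, 1.0)), (b, rng.uniform(0.05, 1.0))):
            adj.setdefault(x, {})[new] = l
            adj.setdefault(new, {})[x] = l
        active = [x for x in active if x not in (a, b)] + [new]
    center = nxt
    for a in active:
        l = float(rng.uniform(0.05, 1.0))
        adj.setdefault(a, {})[center] = l
        adj.setdefault(center, {})[a] = l
    D = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        pq = [(0.0, s)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, 1e18):
                continue
            for v, w in adj.get(u, {}).items():
                if d + w < dist.get(v, 1e18):
                    dist[v] = d + w
                    heapq.heappush(pq, (d + w, v))
        for t in range(n):
            D[s, t] = dist[t]
    return labels, D


def tree_leaf_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a lucfam Tree, by graph search."""
    import collections
    import heapq

    adj = collections.defaultdict(dict)
    counter = [0]

    def walk(node, myid):
        for c in node.children:
            counter[0] += 1
            cid = c.name if c.is_leaf else f"__I{counter[0]}"
            adj[myid][cid] = c.length
            adj[cid][myid] = c.length
            walk(c, cid)

    walk(tree.root, "__ROOT")
    leaves = tree.leaf_names
    out = {}
    for s in leaves:
        dist = {s: 0.0}
        pq = [(0.0, s)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, 1e18):
                continue
            for v, w in adj[u].items():
                if d + w < dist.get(v, 1e18):
                    dist[v] = d + w
                    heapq.heappush(pq, (d + w, v))
        for t in leaves:
            out[(s, t)] = dist[t]
    return out
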