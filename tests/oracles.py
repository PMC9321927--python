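"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route from the library
implementation (naive slicing/counting, direct enumeration, numerical
integration) so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math
import random

from scipy import integrate


# ---------------------------------------------------------------------------
# CpG islands


def cgi_oracle(seq, min_length=200, min_gc=0.50, min_obs_exp=0.60):
    """Exhaustive interval evaluation via naive slice counting (N-free input).

    Evaluates every min-length window, merges overlapping/adjacent
    qualifying windows, and finds the longest (leftmost on ties) qualifying
    sub-interval of each merged region by checking every candidate slice.
    """

    def qualifies(sub):
        length = len(sub)
        c, g = sub.count("C"), sub.count("G")
        if c == 0 or g == 0:
            return False
        if (c + g) / length < min_gc:
            return False
        return sub.count("CG") * length / (c * g) >= min_obs_exp

    n = len(seq)
    starts = [i for i in range(n - min_length + 1) if qualifies(seq[i : i + min_length])]
    islands = []
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - starts[j] <= min_length:
            j += 1
        lo, hi = starts[i], starts[j] + min_length
        found = None
        for length in range(hi - lo, min_length - 1, -1):
            for s in range(lo, hi - length + 1):
                if qualifies(seq[s : s + length]):
                    found = (s, s + length)
                    break
            if found:
                break
        islands.append(found)
        i = j + 1
    return islands


# ---------------------------------------------------------------------------
# sequence tallies


def at_oracle(seq):
    counts = {b: 0 for b in "ACGT"}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    return (counts["A"] + counts["T"]) / sum(counts.values())


def obs_exp_oracle(seq):
    c = sum(1 for ch in seq if ch == "C")
    g = sum(1 for ch in seq if ch == "G")
    cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    if c == 0 or g == 0:
        return 0.0
    return cpg * len(seq) / (c * g)


def sequon_oracle(prot):
    """1-based Asn positions of valid N-X-S/T (X != P) via sliding triple."""
    return [
        i + 1
        for i in range(len(prot) - 2)
        if prot[i] == "N" and prot[i + 1] != "P" and prot[i + 2] in "ST"
    ]


def p_distance_oracle(a, b):
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    return sum(x != y for x, y in pairs) / len(pairs)


def intron_oracle(exon_intervals):
    """Gap lengths between genomically sorted (start, end) exon pairs."""
    srt = sorted(exon_intervals)
    return [b[0] - a[1] for a, b in zip(srt, srt[1:])]


# ---------------------------------------------------------------------------
# isoelectric point


def pi_grid_oracle(prot, charge_fn, step=0.001):
    """First sign change of the net charge on a fixed pH grid."""
    prev_ph, prev_q = 0.0, charge_fn(prot, 0.0)
    ph = step
    while ph <= 14.0:
        q = charge_fn(prot, ph)
        if prev_q >= 0 and q < 0:
            return (prev_ph + ph) / 2.0
        prev_ph, prev_q = ph, q
        ph += step
    return 14.0


# ---------------------------------------------------------------------------
# paired t-test


def paired_t_p_oracle(diffs):
    """Two-tailed p of a paired t-test via numerical integration of the
    t density (df = n-1), built from math.gamma rather than scipy.stats."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    df = n - 1

    def density(x):
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = integrate.quad(density, abs(t), math.inf)
    return 2 * tail, t


# ---------------------------------------------------------------------------
# random additive trees


class AdditiveTree:
    """Random binary unrooted tree with positive branch lengths.

    Built leaf-by-leaf by subdividing a random edge; exposes the exact
    path-length (additive) distance matrix and the non-trivial splits.
    """

    def __init__(self, names, rng: random.Random):
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_of: dict[int, str] = {}
        self._next = 0

        def new_node():
            nonlocal_id = self._next
            self._next += 1
            self.adj[nonlocal_id] = {}
            return nonlocal_id

        def connect(u, v, w):
            self.adj[u][v] = w
            self.adj[v][u] = w

        def blen():
            return rng.uniform(0.5, 2.0)

        center = new_node()
        for name in names[:3]:
            leaf = new_node()
            self.leaf_of[leaf] = name
            connect(center, leaf, blen())
        for name in names[3:]:
            edges = [
                (u, v) for u in self.adj for v in self.adj[u] if u < v
            ]
            u, v = edges[rng.randrange(len(edges))]
            w = self.adj[u][v]
            mid = new_node()
            split = rng.uniform(0.2, 0.8) * w
            del self.adj[u][v]
            del self.adj[v][u]
            connect(u, mid, split)
            connect(mid, v, w - split)
            leaf = new_node()
            self.leaf_of[leaf] = name
            connect(mid, leaf, blen())

    def distances(self):
        names = sorted(self.leaf_of.values())
        index = {n: i for i, n in enumerate(names)}
        import collections

        n = len(names)
        d = [[0.0] * n for _ in range(n)]
        for leaf, name in self.leaf_of.items():
            dist = {leaf: 0.0}
            queue = collections.deque([leaf])
            while queue:
                node = queue.popleft()
                for nb, w in self.adj[node].items():
                    if nb not in dist:
                        dist[nb] = dist[node] + w
                        queue.append(nb)
            for other, oname in self.leaf_of.items():
                d[index[name]][index[oname]] = dist[other]
        return d, names

    def splits(self):
        all_names = frozenset(self.leaf_of.values())
        out = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = self._side(u, v)
                    names = frozenset(
                        self.leaf_of[x] for x in side if x in self.leaf_of
                    )
                    if 1 < len(names) < len(all_names) - 1:
                        out.add(min(names, all_names - names, key=sorted))
        return out

    def _side(self, u, v):
        seen = {v, u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        seen.discard(v)
        return seen
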