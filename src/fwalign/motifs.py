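"""Motif-position role profiles and role similarity for directed webs.

The role of a species is the vector counting how many times it occupies
each automorphism-distinct position (orbit) of the connected 2- and
3-species directed motifs.  There are 2 two-node motifs (single link,
mutual link) with 3 position orbits, and 13 three-node motifs with 30
orbits, so the full role vector has 33 slots (or 30 when two-node
motifs are excluded).

Role similarity between two species is the Pearson correlation of their
role vectors: 1 for equivalent roles, 0 for uncorrelated, -1 for
opposite roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .webio import FoodWeb

__all__ = ["MotifCatalog", "build_motif_catalog", "count_roles", "role_similarity"]


def _edge_order(n: int):
    """Fixed bit order for encoding labeled n-node digraphs."""
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _code_edges(code: int, n: int):
    eo = _edge_order(n)
    return frozenset(e for k, e in enumerate(eo) if code >> k & 1)


def _edges_code(edges, n: int) -> int:
    eo = _edge_order(n)
    idx = {e: k for k, e in enumerate(eo)}
    return sum(1 << idx[e] for e in edges)


def _permute_code(code: int, perm, n: int) -> int:
    return _edges_code({(perm[u], perm[v]) for u, v in _code_edges(code, n)}, n)


def _weakly_connected(code: int, n: int) -> bool:
    edges = _code_edges(code, n)
    if not edges and n > 1:
        return False
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, stack = {0}, [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


@dataclass(frozen=True)
class Motif:
    """One canonical connected digraph on ``n`` nodes."""
    n: int
    code: int                 # canonical (minimal) labeled code
    edges: frozenset         # edges of the canonical representative
    orbits: tuple            # tuple of tuples of node indices

    def __repr__(self):
        es = ",".join(f"{u}>{v}" for u, v in sorted(self.edges))
        return f"Motif(n={self.n}, [{es}], orbits={len(self.orbits)})"


class MotifCatalog:
    """Catalog of motifs and their position orbits, with fast lookup.

    Positions are numbered 0..n_positions-1 in a stable order: motifs
    sorted by node count then canonical code, orbits within a motif by
    smallest member node.  ``position_names`` gives readable labels like
    ``"n3_m5_o1"``.
    """

    def __init__(self, max_n: int = 3, min_n: int = 2):
        if max_n not in (2, 3):
            raise ValueError("motif size must be 2 or 3")
        if min_n not in (2, 3) or min_n > max_n:
            raise ValueError("min_n must be 2 or 3 and <= max_n")
        self.max_n = max_n
        self.min_n = min_n
        self.motifs: list[Motif] = []
        self.position_names: list[str] = []
        # per-n lookup: labeled code -> tuple of global slot per node
        self._tables: dict[int, dict[int, tuple]] = {}
        slot = 0
        for n in range(min_n, max_n + 1):
            canon_of: dict[int, int] = {}
            classes: dict[int, list[int]] = {}
            perms = list(permutations(range(n)))
            for code in range(1, 1 << len(_edge_order(n))):
                if not _weakly_connected(code, n):
                    continue
                canon = min(_permute_code(code, p, n) for p in perms)
                canon_of[code] = canon
                classes.setdefault(canon, []).append(code)
            table: dict[int, tuple] = {}
            for mi, canon in enumerate(sorted(classes)):
                autos = [p for p in perms if _permute_code(canon, p, n) == canon]
                orbit_of = {}
                for v in range(n):
                    orbit_of[v] = min(p[v] for p in autos)
                reps = sorted(set(orbit_of.values()))
                orbits = tuple(tuple(v for v in range(n) if orbit_of[v] == r)
                               for r in reps)
                motif = Motif(n, canon, _code_edges(canon, n), orbits)
                self.motifs.append(motif)
                slot_of_rep = {}
                for oi, r in enumerate(reps):
                    slot_of_rep[r] = slot
                    self.position_names.append(f"n{n}_m{mi}_o{oi}")
                    slot += 1
                # map every labeled code in the class to per-node slots
                for code in classes[canon]:
                    # a permutation sending `code` onto `canon`
                    sigma = next(p for p in perms if _permute_code(code, p, n) == canon)
                    table[code] = tuple(slot_of_rep[orbit_of[sigma[v]]] for v in range(n))
            self._tables[n] = table
        self.n_positions = slot

    def motif_of_slot(self, slot: int) -> Motif:
        """The motif a position slot belongs to."""
        s = 0
        for m in self.motifs:
            if slot < s + len(m.orbits):
                return m
            s += len(m.orbits)
        raise IndexError(slot)

    def __repr__(self):
        return (f"MotifCatalog(n={self.min_n}..{self.max_n}, "
                f"{len(self.motifs)} motifs, {self.n_positions} positions)")


_CATALOG_CACHE: dict[tuple, MotifCatalog] = {}


def build_motif_catalog(max_n: int = 3, min_n: int = 2) -> MotifCatalog:
    """Build (and cache) the motif/position catalog for n in [min_n, max_n]."""
    key = (min_n, max_n)
    if key not in _CATALOG_CACHE:
        _CATALOG_CACHE[key] = MotifCatalog(max_n=max_n, min_n=min_n)
    return _CATALOG_CACHE[key]


def count_roles(web: FoodWeb, catalog: MotifCatalog | None = None) -> dict[str, np.ndarray]:
    """Count each species' occurrences at every catalog position.

    Every connected induced subgraph on 2 (and 3) species increments the
    count of each member at its position orbit.  Self-loops are ignored.
    Returns ``{species: integer vector of length catalog.n_positions}``.
    """
    if catalog is None:
        catalog = build_motif_catalog()
    web = web.without_self_loops()
    sp = list(web.species)
    idx = {s: i for i, s in enumerate(sp)}
    n = len(sp)
    out_adj = [set() for _ in range(n)]
    und = [set() for _ in range(n)]
    for r, c in web.links:
        i, j = idx[r], idx[c]
        out_adj[i].add(j)
        und[i].add(j)
        und[j].add(i)
    counts = {s: np.zeros(catalog.n_positions, dtype=np.int64) for s in sp}

    if 2 in catalog._tables:
        t2 = catalog._tables[2]
        for i in range(n):
            for j in und[i]:
                if j <= i:
                    continue
                code = (1 if j in out_adj[i] else 0) | (2 if i in out_adj[j] else 0)
                si, sj = t2[code]
                counts[sp[i]][si] += 1
                counts[sp[j]][sj] += 1

    if 3 in catalog._tables:
        t3 = catalog._tables[3]
        eo3 = _edge_order(3)
        bit = {e: 1 << k for k, e in enumerate(eo3)}
        # every connected triple has a node adjacent to the other two
        triples = set()
        for v in range(n):
            nb = sorted(und[v])
            for u, w in combinations(nb, 2):
                triples.add(tuple(sorted((u, v, w))))
        for x, y, z in triples:
            trio = (x, y, z)
            code = 0
            for a in range(3):
                for b in range(3):
                    if a != b and trio[b] in out_adj[trio[a]]:
                        code |= bit[(a, b)]
            slots = t3[code]
            for a in range(3):
                counts[sp[trio[a]]][slots[a]] += 1
    return counts


def role_similarity(ca: np.ndarray, cb: np.ndarray) -> float:
    """Pearson correlation between two role vectors.

    Equals 1 for equivalent roles and -1 for opposite roles.  When one
    or both vectors are constant the correlation is undefined; by
    convention the value is 1 if the vectors are elementwise equal
    (degenerate but identical roles) and 0 otherwise.
    """
    ca = np.asarray(ca, dtype=float)
    cb = np.asarray(cb, dtype=float)
    if ca.shape != cb.shape:
        raise ValueError(f"role vectors differ in length: {ca.shape} vs {cb.shape}")
    if np.array_equal(ca, cb):
        return 1.0
    sa = ca.std()
    sb = cb.std()
    if sa == 0.0 or sb == 0.0:
        return 1.0 if np.array_equal(ca, cb) else 0.0
    r = float(np.dot(ca - ca.mean(), cb - cb.mean()) / (len(ca) * sa * sb))
    return max(-1.0, min(1.0, r))


def role_matrix(roles: dict[str, np.ndarray], order: list[str] | None = None):
    """Stack role profiles into a (species x positions) array."""
    order = list(roles) if order is None else list(order)
    return order, np.array([roles[s] for s in order], dtype=float)


def similarity_matrix(roles_a: dict[str, np.ndarray], roles_b: dict[str, np.ndarray],
                      order_a: list[str] | None = None,
                      order_b: list[str] | None = None) -> np.ndarray:
    """Pairwise role similarity between the species of two webs.

    Vectorized Pearson with the same degenerate-vector convention as
    :func:`role_similarity`.
    """
    order_a, A = role_matrix(roles_a, order_a)
    order_b, B = role_matrix(roles_b, order_b)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.outer(sa, sb) * A.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, Ac @ Bc.T / np.where(denom == 0, 1.0, denom), 0.0)
    # degenerate rows/cols: 1 where the raw vectors are elementwise equal
    deg_a = np.flatnonzero(sa == 0)
    deg_b = np.flatnonzero(sb == 0)
    for i in deg_a:
        R[i, :] = [1.0 if np.array_equal(A[i], B[j]) else 0.0 for j in range(B.shape[0])]
    for j in deg_b:
        R[:, j] = [1.0 if np.array_equal(A[i], B[j]) else 0.0 for i in range(A.shape[0])]
    return np.clip(R, -1.0, 1.0)
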