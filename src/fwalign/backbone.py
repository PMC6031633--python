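"""Backbones of interactions: link overlap, extraction, clustering.

The link overlap of a web counts, for every link, the number of
alignments in which the two endpoint species' partners are also linked
(in the same energy-flow direction) in the partner web.  The k-link
backbone is the subgraph of the k most-overlapped links.  Backbones
from different webs are themselves aligned to build a dissimilarity
matrix E_k, which is clustered around medoids; overlaying each cluster
member on its medoid yields a consensus structure whose links carry a
likelihood l — the fraction of member backbones whose aligned image
contains the link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .alignment import AlignConfig, optimize_alignment
from .ensemble import DissimilarityMatrix, PairingStore
from .webio import FoodWeb

log = logging.getLogger(__name__)

__all__ = [
    "LinkOverlap", "Backbone", "ConsensusBackbone",
    "link_overlap", "extract_backbone", "backbone_matrix",
    "kmedoids", "choose_n_clusters", "cluster_and_consensus",
    "strength_test", "sweep_backbone_sizes",
]

#: Auxiliary-node label used in consensus structures for member nodes
#: that have no counterpart in the medoid.
AUX = "*aux*"


@dataclass
class LinkOverlap:
    """Per-link overlap counts of one web across all its alignments."""
    web_id: str
    weights: dict  # (resource, consumer) -> int
    n_partners: int

    def top_links(self, k: int) -> list:
        """The k most-overlapped links; ties broken lexicographically."""
        ranked = sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


@dataclass
class Backbone:
    """The k most-overlapped links of a web, as a subgraph."""
    web_id: str
    k: int
    links: list            # [(link, overlap weight)] in rank order
    species: tuple = ()

    def __post_init__(self):
        if len(self.links) != self.k:
            raise ValueError(f"backbone of {self.web_id}: {len(self.links)} links != k={self.k}")
        if not self.species:
            self.species = tuple(dict.fromkeys(
                s for (r, c), _ in self.links for s in (r, c)))

    def to_foodweb(self) -> FoodWeb:
        return FoodWeb(f"{self.web_id}|bb{self.k}", self.species,
                       [e for e, _ in self.links])


@dataclass
class ConsensusBackbone:
    """Representative structure of one cluster of backbones.

    Links live in the medoid's species space (with the pooled label
    ``*aux*`` standing in for member nodes unmatched in the medoid) and
    carry the likelihood l = fraction of within-cluster backbones whose
    aligned image contains the link.  Links below ``threshold`` are
    dropped.
    """
    cluster_id: int
    medoid_web_id: str
    nodes: tuple
    links: dict            # (u, v) -> likelihood l in (0, 1]
    threshold: float
    member_web_ids: tuple
    n_aux_nodes_mean: float = 0.0


def link_overlap(web: FoodWeb, store: PairingStore) -> LinkOverlap:
    """Count, per link of ``web``, the alignments that preserve it.

    A link (a, a') counts as shared with a partner web when both a and
    a' have real partners (b, b') there and b -> b' is a link of that
    web (same direction of energy flow).  The store must know the
    partner webs' link sets (it does when built by all_pairs_align).
    """
    others = sorted({w for pair in store.pairs() if web.id in pair
                     for w in pair if w != web.id})
    if not others:
        raise ValueError(f"web {web.id!r} has no alignments in the store")
    weights = {e: 0 for e in web.links}
    for other in others:
        aln = store.alignment(web.id, other)
        mates = aln.mapping()
        if aln.web_a != web.id:
            mates = {b: a for a, b in mates.items()}
        other_links = store.links_of(other)
        for (a, a2) in web.links:
            b, b2 = mates.get(a), mates.get(a2)
            if b is not None and b2 is not None and (b, b2) in other_links:
                weights[(a, a2)] += 1
    return LinkOverlap(web.id, weights, n_partners=len(others))


def extract_backbone(overlap: LinkOverlap, k: int) -> Backbone:
    """Top-k links by overlap weight (descending), ties lexicographic.

    Refuses when the web has fewer than k links, mirroring the upstream
    practice of dropping webs too small for the requested backbone size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(overlap.weights):
        raise ValueError(
            f"web {overlap.web_id!r} has only {len(overlap.weights)} links; "
            f"cannot extract a {k}-link backbone")
    return Backbone(overlap.web_id, k, overlap.top_links(k))


def backbone_matrix(backbones: list[Backbone],
                    config: AlignConfig | None = None,
                    use_quality: bool = False) -> DissimilarityMatrix:
    """Align all pairs of k-link backbones; entries are alignment costs.

    Backbones all share the same number of links k, so the raw optimal
    alignment cost is comparable without size normalization (set
    ``use_quality`` to use the normalized dissimilarity instead).
    """
    config = config or AlignConfig()
    ks = {b.k for b in backbones}
    if len(ks) != 1:
        raise ValueError(f"backbones must share k, got {sorted(ks)}")
    ids = [b.web_id for b in backbones]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate backbone web ids")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    webs = [backbones[i].to_foodweb() for i in order]
    n = len(webs)
    E = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        _, score = optimize_alignment(webs[i], webs[j], config)
        E[i, j] = E[j, i] = (score.quality if use_quality
                             else score.cost(config.cost_kind))
    return DissimilarityMatrix([ids[i] for i in order], E)


# ---------------------------------------------------------------------------
# clustering

def kmedoids(matrix: DissimilarityMatrix, n_clusters: int, seed: int = 0,
             n_init: int = 10, max_iter: int = 100):
    """Seeded alternating k-medoids on a precomputed dissimilarity matrix.

    Returns ``(labels, medoid_indices)``; the best of ``n_init``
    random initializations by total within-cluster distance to medoid.
    """
    D = matrix.values
    n = D.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        medoids = np.sort(rng.choice(n, size=n_clusters, replace=False))
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(n_clusters):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    # re-seed an empty cluster on the worst-fit point
                    far = np.argmax(D[np.arange(n), medoids[labels]])
                    new_medoids[c] = far
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if best is None or cost < best[0] - 1e-12:
            best = (cost, labels, medoids)
    _, labels, medoids = best
    return labels, medoids


def _dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    diam = max((D[np.ix_(m, m)].max() if m.size > 1 else 0.0)
               for m in clusters)
    sep = min(D[np.ix_(a, b)].min()
              for a, b in combinations(clusters, 2))
    if diam == 0.0:
        return np.inf if sep > 0 else 0.0
    return sep / diam


def choose_n_clusters(matrix: DissimilarityMatrix, k_range=None,
                      seed: int = 0) -> int:
    """Majority vote of three cluster-validity indices.

    Candidate counts (default 2..min(8, n-1)) are each clustered with
    k-medoids and scored by average silhouette width, Calinski-Harabasz
    (on the principal-coordinate embedding) and the Dunn index; each
    index votes for its best count and the majority wins, ties going to
    the smallest count.
    """
    from .distmat_stats import pcoa
    n = len(matrix.ids)
    if n < 4:
        raise ValueError("need at least 4 items to vote on a cluster count")
    candidates = list(k_range) if k_range is not None else list(range(2, min(8, n - 1) + 1))
    if not all(2 <= k <= n - 1 for k in candidates):
        raise ValueError(f"candidate counts must lie in [2, {n - 1}]")
    D = matrix.values
    if np.allclose(D[np.triu_indices(n, 1)], D[0, 1] if n > 1 else 0.0):
        log.warning("degenerate (all-equal) distances; returning smallest "
                    "candidate cluster count")
        return min(candidates)
    emb = pcoa(matrix).coordinates
    if emb.shape[1] == 0:
        emb = np.zeros((n, 1))
    scores = {"silhouette": {}, "calinski_harabasz": {}, "dunn": {}}
    for k in candidates:
        labels, _ = kmedoids(matrix, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        scores["silhouette"][k] = silhouette_score(D, labels, metric="precomputed")
        scores["calinski_harabasz"][k] = calinski_harabasz_score(emb, labels)
        scores["dunn"][k] = _dunn_index(D, labels)
    votes = []
    for index, by_k in scores.items():
        if by_k:
            best_k = min(by_k, key=lambda k: (-by_k[k], k))
            votes.append(best_k)
            log.info("index %s votes for %d clusters", index, best_k)
    counts = pd.Series(votes).value_counts()
    winners = counts[counts == counts.max()].index
    return int(min(winners))


def cluster_and_consensus(matrix: DissimilarityMatrix,
                          backbones: list[Backbone], n_clusters: int,
                          l_threshold: float = 0.01,
                          config: AlignConfig | None = None,
                          seed: int = 0) -> list[ConsensusBackbone]:
    """Cluster backbones and overlay each cluster on its medoid.

    Every member backbone is aligned to its cluster medoid; member
    links map through the pairing into the medoid's species space, and
    each mapped link's likelihood l is the fraction of members whose
    image contains it.  Member nodes with no medoid counterpart are
    pooled under the ``*aux*`` label.  Links with l < l_threshold are
    dropped.
    """
    config = config or AlignConfig()
    by_id = {b.web_id: b for b in backbones}
    if set(matrix.ids) != set(by_id):
        raise ValueError("matrix ids and backbones differ")
    labels, medoid_idx = kmedoids(matrix, n_clusters, seed=seed)
    out = []
    for c in range(n_clusters):
        members = [matrix.ids[i] for i in np.flatnonzero(labels == c)]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        medoid_id = matrix.ids[medoid_idx[c]]
        medoid_bb = by_id[medoid_id]
        medoid_web = medoid_bb.to_foodweb()
        link_counts: dict = {}
        aux_counts = []
        for mid in members:
            member_bb = by_id[mid]
            if mid == medoid_id:
                mapping = {s: s for s in member_bb.species}
            else:
                aln, _ = optimize_alignment(member_bb.to_foodweb(), medoid_web,
                                            config)
                mapping = aln.mapping()
            unmatched = [s for s in member_bb.species if s not in mapping]
            aux_counts.append(len(unmatched))
            seen = set()
            for (r, cns), _w in member_bb.links:
                u = mapping.get(r, AUX)
                v = mapping.get(cns, AUX)
                if u == AUX and v == AUX:
                    continue
                if (u, v) not in seen:        # one count per member
                    seen.add((u, v))
                    link_counts[(u, v)] = link_counts.get((u, v), 0) + 1
        m = len(members)
        links = {e: cnt / m for e, cnt in link_counts.items()
                 if cnt / m >= l_threshold}
        nodes = tuple(dict.fromkeys(
            [s for s in medoid_bb.species] +
            [s for e in links for s in e if s != AUX]))
        out.append(ConsensusBackbone(
            cluster_id=c, medoid_web_id=medoid_id, nodes=nodes, links=links,
            threshold=l_threshold, member_web_ids=tuple(members),
            n_aux_nodes_mean=float(np.mean(aux_counts))))
    return out


def strength_test(web: FoodWeb, backbone: Backbone, n_perm: int = 999,
                  seed: int = 0) -> dict:
    """Are backbone links heavier than random equal-size link sets?

    Statistic: mean interaction strength of the backbone's links.  Null:
    means of ``n_perm`` uniformly drawn k-link subsets of the web.
    One-sided p with +1 smoothing, plus the observed percentile.
    """
    if not web.weights:
        raise ValueError(f"web {web.id!r} has no interaction strengths")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bb_links = [e for e, _ in backbone.links]
    missing = [e for e in bb_links if e not in web.weights]
    if missing:
        raise ValueError(f"backbone links missing weights: {missing[:3]}")
    obs = float(np.mean([web.weights[e] for e in bb_links]))
    all_w = np.array([web.weights[e] for e in sorted(web.links)])
    rng = np.random.default_rng(seed)
    k = len(bb_links)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = all_w[rng.choice(len(all_w), size=k, replace=False)].mean()
    p = (1 + int((null >= obs - 1e-12).sum())) / (n_perm + 1)
    return {"observed_mean": obs, "p_value": p,
            "percentile": float((null < obs).mean()),
            "null_mean": float(null.mean()), "n_perm": n_perm}


def sweep_backbone_sizes(webs: list[FoodWeb], store: PairingStore,
                         k_range=range(6, 32),
                         config: AlignConfig | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Cluster-count sweep over backbone sizes k.

    For each k, webs with at least k links get their backbone
    extracted, the backbone dissimilarity matrix E_k is built, and the
    majority-rule cluster count recorded along with the fraction of
    webs retained.
    """
    overlaps = {w.id: link_overlap_with_webs(w, store, webs) for w in webs}
    rows = []
    for k in k_range:
        kept = [w for w in webs if w.n_links >= k]
        if len(kept) < 4:
            rows.append({"k": k, "n_webs": len(kept),
                         "retained_fraction": len(kept) / len(webs),
                         "n_clusters": np.nan})
            continue
        bbs = [extract_backbone(overlaps[w.id], k) for w in kept]
        Ek = backbone_matrix(bbs, config)
        nc = choose_n_clusters(Ek, seed=seed)
        rows.append({"k": k, "n_webs": len(kept),
                     "retained_fraction": len(kept) / len(webs),
                     "n_clusters": nc})
    return pd.DataFrame(rows)


def link_overlap_with_webs(web: FoodWeb, store: PairingStore,
                           webs: list[FoodWeb]) -> LinkOverlap:
    """Link overlap, registering explicit web objects with the store."""
    for w in webs:
        store.register_web(w)
    return link_overlap(web, store)
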