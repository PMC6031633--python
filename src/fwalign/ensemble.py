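"""Dataset-level alignment analyses.

Aligning every pair of webs in a collection yields (i) the symmetric
dissimilarity matrix of normalized alignment qualities, (ii) a store of
all species-species pairings from which species are ranked by their
average role similarity, (iii) alignment transitivity — how often the
two partners of a species are themselves paired — with a shuffled null,
and (iv) a connectedness (path-likelihood) test for whether the
best-aligned species of a web hang together as a subweb.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AlignConfig, Alignment, optimize_alignment
from .motifs import build_motif_catalog, count_roles, role_similarity
from .webio import FoodWeb

log = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix", "PairingStore", "plan_pairs", "all_pairs_align",
    "rank_species", "alignment_transitivity", "transitivity_null",
    "path_connectedness", "path_likelihood_test", "best_aligned_species",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal dissimilarities over a set of web ids."""

    ids: list
    values: np.ndarray
    groups: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def save(self, path):
        self.to_frame().to_csv(path)

    @classmethod
    def load(cls, path, groups=None) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), groups)

    def submatrix(self, keep_ids) -> "DissimilarityMatrix":
        pos = [self.ids.index(i) for i in keep_ids]
        g = {i: self.groups[i] for i in keep_ids} if self.groups else None
        return DissimilarityMatrix(list(keep_ids),
                                   self.values[np.ix_(pos, pos)], g)


class PairingStore:
    """All optimal alignments of a dataset, indexed for species lookups.

    One alignment is stored per unordered pair of web ids.  Role
    similarities of each real pairing are attached so that rankings and
    nulls never have to recompute roles.
    """

    def __init__(self):
        self._alignments: dict[tuple, Alignment] = {}
        self._rho: dict[tuple, dict] = {}       # pair -> {(a, b): rho}
        # (web, species) -> list of (other_web, partner-or-None, rho-or-None)
        self._index: dict[tuple, list] = {}
        self._links: dict[str, frozenset] = {}  # web id -> link set

    def register_web(self, web: FoodWeb):
        """Record a web's link set (needed for link-overlap queries)."""
        self._links[web.id] = frozenset(web.links)

    def links_of(self, web_id: str) -> frozenset:
        try:
            return self._links[web_id]
        except KeyError:
            raise KeyError(
                f"web {web_id!r} was not registered with the store; call "
                "store.register_web(web) or build the store via "
                "all_pairs_align") from None

    @staticmethod
    def _key(w1: str, w2: str) -> tuple:
        return (w1, w2) if w1 <= w2 else (w2, w1)

    def add(self, alignment: Alignment, rho_of_pair: dict):
        key = self._key(alignment.web_a, alignment.web_b)
        if key in self._alignments:
            raise ValueError(f"alignment for pair {key} already stored")
        if key != (alignment.web_a, alignment.web_b):
            alignment = alignment.flipped()
            rho_of_pair = {(b, a): r for (a, b), r in rho_of_pair.items()}
        self._alignments[key] = alignment
        self._rho[key] = dict(rho_of_pair)
        wa, wb = key
        for a, b in alignment.pairs:
            r = rho_of_pair.get((a, b))
            if a is not None:
                self._index.setdefault((wa, a), []).append((wb, b, r))
            if b is not None:
                self._index.setdefault((wb, b), []).append((wa, a, r))

    def __len__(self):
        return len(self._alignments)

    @property
    def web_ids(self) -> list:
        ids = set()
        for a, b in self._alignments:
            ids.update((a, b))
        return sorted(ids)

    def alignment(self, w1: str, w2: str) -> Alignment:
        return self._alignments[self._key(w1, w2)]

    def pairs(self):
        return list(self._alignments)

    def partner(self, web: str, species: str, other_web: str):
        """Partner of (web, species) in the alignment with other_web."""
        for ow, partner, _ in self._index.get((web, species), []):
            if ow == other_web:
                return partner
        return None

    def pairings_of(self, web: str, species: str) -> list:
        """All (other_web, partner-or-None, rho-or-None) of a species."""
        return list(self._index.get((web, species), []))

    def are_paired(self, w1: str, s1: str, w2: str, s2: str) -> bool:
        return self.partner(w1, s1, w2) == s2 and s2 is not None

    def species_of(self, web: str) -> list:
        return sorted(s for w, s in self._index if w == web)


def plan_pairs(ids: list) -> list[tuple]:
    """Unordered pairs of web ids scheduled by the all-pairs aligner."""
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate web ids")
    return [(a, b) for a, b in combinations(sorted(ids), 2)]


def _web_digest(web: FoodWeb) -> str:
    payload = json.dumps([list(web.species), sorted(web.links)])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _alignment_to_json(aln: Alignment, score, rho_of_pair) -> dict:
    return {
        "web_a": aln.web_a, "web_b": aln.web_b,
        "pairs": sorted(([a, b] for a, b in aln.pairs),
                        key=lambda p: (p[0] is None, p[0] or "", p[1] or "")),
        "rho": {f"{a}\t{b}": r for (a, b), r in rho_of_pair.items()},
        "cost_simple": score.cost_simple,
        "cost_neighborhood": score.cost_neighborhood,
        "quality": score.quality,
        "n_matched": score.n_matched,
        "seed": aln.seed,
    }


def all_pairs_align(webs: list[FoodWeb], config: AlignConfig | None = None,
                    cache_dir=None, progress: bool = False
                    ) -> tuple[DissimilarityMatrix, PairingStore]:
    """Align every pair of webs; return the quality matrix and the store.

    With ``cache_dir`` set, each pair's result is written as JSON keyed
    by the web contents and configuration, and completed pairs are
    skipped on rerun.
    """
    config = config or AlignConfig()
    if len(webs) < 2:
        raise ValueError("need at least 2 webs")
    ids = [w.id for w in webs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate web ids")
    by_id = {w.id: w for w in webs}
    order = sorted(ids)
    catalog = build_motif_catalog(max_n=config.max_n)
    roles = {w.id: count_roles(w, catalog) for w in webs}
    groups = {w.id: w.ecosystem for w in webs if w.ecosystem}
    n = len(order)
    E = np.zeros((n, n))
    store = PairingStore()
    for w in webs:
        store.register_web(w)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    cfg_tag = hashlib.sha256(config.key().encode()).hexdigest()[:8]
    for i, j in combinations(range(n), 2):
        wa, wb = by_id[order[i]], by_id[order[j]]
        cached = None
        if cache:
            name = f"{wa.id}__{wb.id}__{_web_digest(wa)}_{_web_digest(wb)}_{cfg_tag}.json"
            fp = cache / name
            if fp.exists():
                cached = json.loads(fp.read_text())
                log.info("cache hit for pair (%s, %s)", wa.id, wb.id)
        if cached is not None:
            pairs = frozenset((a, b) for a, b in cached["pairs"])
            aln = Alignment(cached["web_a"], cached["web_b"], pairs,
                            seed=cached.get("seed"))
            rho_of_pair = {tuple(k.split("\t")): v
                           for k, v in cached["rho"].items()}
            quality_ij = cached["quality"]
        else:
            aln, score = optimize_alignment(wa, wb, config,
                                            roles[wa.id], roles[wb.id])
            rho_of_pair = {
                (a, b): role_similarity(roles[wa.id][a], roles[wb.id][b])
                for a, b in aln.pairs if a is not None and b is not None}
            quality_ij = score.quality
            if cache:
                fp.write_text(json.dumps(
                    _alignment_to_json(aln, score, rho_of_pair)))
        store.add(aln, rho_of_pair)
        E[i, j] = E[j, i] = quality_ij
        if progress:
            print(f"aligned {wa.id} vs {wb.id}: quality {quality_ij:.4f}")
    return DissimilarityMatrix(order, E, groups or None), store


def rank_species(store: PairingStore, groups: dict | None = None
                 ) -> pd.DataFrame:
    """Rank every species by its average role similarity across pairings.

    Returns a DataFrame with mean rho over all real partners, split into
    same- and cross-ecosystem partner webs when ``groups`` is given,
    plus the number of real pairings and the alignment transitivity.
    Unpaired pairings are excluded from all means.
    """
    if len(store) == 0:
        raise ValueError("empty pairing store")
    rows = []
    for web in store.web_ids:
        g = groups.get(web) if groups else None
        for sp in store.species_of(web):
            rhos, same, cross = [], [], []
            for ow, partner, r in store.pairings_of(web, sp):
                if partner is None:
                    continue
                rhos.append(r)
                if groups:
                    (same if groups.get(ow) == g else cross).append(r)
            trans = alignment_transitivity(store, web, sp)
            rows.append({
                "web_id": web, "species": sp,
                "mean_rho_all": float(np.mean(rhos)) if rhos else np.nan,
                "mean_rho_same_ecosystem": float(np.mean(same)) if same else np.nan,
                "mean_rho_cross_ecosystem": float(np.mean(cross)) if cross else np.nan,
                "n_pairings": len(rhos),
                "transitivity": trans if trans is not None else np.nan,
            })
    df = pd.DataFrame(rows)
    return df.sort_values(["web_id", "mean_rho_all"],
                          ascending=[True, False]).reset_index(drop=True)


def alignment_transitivity(store: PairingStore, web: str, species: str
                           ) -> float | None:
    """Fraction of partner pairs of a species that are themselves paired.

    Over all unordered pairs of other webs (B, C) in which the species
    has real partners b and c, the fraction where (b, c) is a pairing
    of the B-C alignment.  None when fewer than one valid (B, C) pair
    exists (undefined rather than zero).
    """
    partners = [(ow, p) for ow, p, _ in store.pairings_of(web, species)
                if p is not None]
    stored = set(store.pairs())
    closed = total = 0
    for (wb, b), (wc, c) in combinations(sorted(partners), 2):
        if PairingStore._key(wb, wc) not in stored:
            continue
        total += 1
        if store.are_paired(wb, b, wc, c):
            closed += 1
    if total == 0:
        return None
    return closed / total


def _shuffled_store(store: PairingStore, rng) -> PairingStore:
    """Permute partners within each alignment, keeping pairing counts."""
    out = PairingStore()
    for w1, w2 in store.pairs():
        aln = store.alignment(w1, w2)
        matched = [(a, b) for a, b in aln.pairs if a is not None and b is not None]
        unmatched = [(a, b) for a, b in aln.pairs if a is None or b is None]
        a_side = [a for a, _ in matched]
        b_side = [b for _, b in matched]
        perm = rng.permutation(len(b_side))
        new_pairs = [(a_side[k], b_side[perm[k]]) for k in range(len(b_side))]
        out.add(Alignment(w1, w2, frozenset(new_pairs + unmatched)),
                {p: 0.0 for p in new_pairs})
    return out


def transitivity_null(store: PairingStore, n_shuffles: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Expected transitivity under partner-shuffled alignments.

    Within every alignment the matched partners are permuted uniformly
    at random (the number of real pairings is maintained).  Returns per
    (web, species) the mean shuffled transitivity and a Monte-Carlo
    95% interval over shuffles.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    samples: dict[tuple, list] = {}
    for _ in range(n_shuffles):
        sh = _shuffled_store(store, rng)
        for web in sh.web_ids:
            for sp in sh.species_of(web):
                t = alignment_transitivity(sh, web, sp)
                if t is not None:
                    samples.setdefault((web, sp), []).append(t)
    rows = []
    for (web, sp), vals in sorted(samples.items()):
        v = np.asarray(vals)
        rows.append({
            "web_id": web, "species": sp,
            "null_mean": float(v.mean()),
            "null_lo": float(np.quantile(v, 0.025)),
            "null_hi": float(np.quantile(v, 0.975)),
            "n_shuffles": len(vals),
        })
    return pd.DataFrame(rows)


def path_connectedness(web: FoodWeb, subset) -> float:
    """Fraction of species pairs in ``subset`` joined by an undirected
    path within the induced subweb (1 iff the subweb is connected)."""
    subset = set(subset)
    if not subset <= set(web.species):
        raise ValueError("subset contains species not in the web")
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 species")
    g = web.to_networkx().to_undirected()
    sub = g.subgraph(subset)
    k = len(subset)
    total = k * (k - 1) // 2
    connected = sum(len(cc) * (len(cc) - 1) // 2
                    for cc in nx.connected_components(sub))
    return connected / total


def path_likelihood_test(web: FoodWeb, subset, n_random: int = 999,
                         seed: int = 0) -> dict:
    """Is the subset more connected than equally sized random subsets?

    One-sided permutation p-value with +1 smoothing:
    p = (1 + #{random subsets with connectedness >= observed}) / (n + 1).
    """
    subset = set(subset)
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if len(subset) >= web.n_species:
        raise ValueError("subset must be a strict subset of the web's species")
    obs = path_connectedness(web, subset)
    rng = np.random.default_rng(seed)
    species = list(web.species)
    k = len(subset)
    null = np.empty(n_random)
    for i in range(n_random):
        pick = rng.choice(len(species), size=k, replace=False)
        null[i] = path_connectedness(web, [species[j] for j in pick])
    p = (1 + int((null >= obs - 1e-12).sum())) / (n_random + 1)
    return {"observed": obs, "p_value": p, "null_mean": float(null.mean()),
            "null_median": float(np.median(null)), "n_random": n_random}


def best_aligned_species(ranking: pd.DataFrame, web_id: str,
                         fraction: float = 0.25) -> list:
    """Top fraction of a web's species by mean role similarity (the
    candidate backbone membership for the path test)."""
    sub = ranking[ranking.web_id == web_id].dropna(subset=["mean_rho_all"])
    sub = sub.sort_values("mean_rho_all", ascending=False)
    k = max(2, int(round(fraction * len(sub))))
    return sub.species.head(k).tolist()
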