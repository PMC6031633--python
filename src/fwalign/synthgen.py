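"""Synthetic food-web generators used as test and study inputs.

The niche model is the standard stochastic generator of ecologically
plausible webs: each species gets a niche value n_i ~ U(0, 1) and eats
every species whose niche value falls in an interval of beta-distributed
width centered below n_i.  Ensembles with a planted backbone embed an
identical small subgraph in every web and surround it with independent
random periphery, giving ground truth for backbone-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .webio import FoodWeb

__all__ = [
    "NicheParams", "PlantedEnsembleParams", "niche_web", "er_web",
    "permuted_copy", "planted_backbone_ensemble", "fig_toy_triple",
    "star_backbone", "bipartite_backbone", "motif_rich_backbone",
]


@dataclass(frozen=True)
class NicheParams:
    """Niche-model parameters: ``n_species`` >= 2, directed connectance
    ``connectance`` in (0, 0.5) (expected links / S^2), and a seed."""
    n_species: int = 20
    connectance: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0.0 < self.connectance < 0.5:
            raise ValueError("connectance must be in (0, 0.5)")


@dataclass(frozen=True)
class PlantedEnsembleParams:
    """Planted-backbone ensemble: every web contains an exact copy of
    ``backbone`` plus fresh random periphery species."""
    n_webs: int
    backbone: FoodWeb
    periphery_species: int = 15
    periphery_connectance: float = 0.10
    attach_prob: float = 0.01
    seed: int = 0


def _species_names(n: int, prefix: str = "s") -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def niche_web(params: NicheParams, web_id: str | None = None) -> FoodWeb:
    """Generate one niche-model web (self-loops stripped).

    Niche values n_i ~ U(0,1); diet range r_i = x * n_i with
    x ~ Beta(1, b), b = 1/(2C) - 1, so the expected directed
    connectance is C; diet center c_i ~ U(r_i/2, n_i).  The species
    with the smallest niche value is forced basal.
    """
    rng = np.random.default_rng(params.seed)
    S, C = params.n_species, params.connectance
    beta = 1.0 / (2.0 * C) - 1.0
    nv = np.sort(rng.uniform(size=S))
    x = rng.beta(1.0, beta, size=S)
    r = x * nv
    r[0] = 0.0  # basal species
    centers = rng.uniform(r / 2.0, np.maximum(nv, r / 2.0 + 1e-12))
    names = _species_names(S)
    links = []
    for i in range(S):
        lo, hi = centers[i] - r[i] / 2.0, centers[i] + r[i] / 2.0
        for j in range(S):
            if i != j and lo <= nv[j] <= hi:
                links.append((names[j], names[i]))  # j is eaten by i
    return FoodWeb(web_id or f"niche{params.seed}", names, links)


def er_web(n_species: int, connectance: float, seed: int = 0,
           web_id: str | None = None) -> FoodWeb:
    """Directed Erdos-Renyi web (null alternative to the niche model)."""
    rng = np.random.default_rng(seed)
    names = _species_names(n_species)
    links = [(names[i], names[j])
             for i in range(n_species) for j in range(n_species)
             if i != j and rng.random() < connectance]
    return FoodWeb(web_id or f"er{seed}", names, links)


def permuted_copy(web: FoodWeb, seed: int = 0,
                  new_id: str | None = None) -> tuple[FoodWeb, dict]:
    """Isomorphic copy under a uniformly random relabeling.

    Returns ``(copy, mapping)`` with ``mapping[old] = new``.  The new
    labels are the old labels shuffled, so degree sequences and all
    structure are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    old = list(web.species)
    new = list(old)
    rng.shuffle(new)
    mapping = dict(zip(old, new))
    out = web.relabeled(mapping, new_id or f"{web.id}_perm{seed}")
    return out, mapping


def planted_backbone_ensemble(params: PlantedEnsembleParams
                              ) -> tuple[list[FoodWeb], list[set]]:
    """Ensemble of webs sharing an exact planted backbone.

    Each web keeps the backbone's species labels and links verbatim,
    adds ``periphery_species`` fresh species with random links among
    themselves (directed density ``periphery_connectance``) and random
    attachments to backbone species (each ordered periphery-backbone
    pair links with probability ``attach_prob``, random direction
    realized by the ordered-pair sweep).  Returns the webs and, per
    web, the set of planted links.
    """
    bb = params.backbone.without_self_loops()
    webs, planted = [], []
    for w in range(params.n_webs):
        rng = np.random.default_rng(params.seed + 7919 * w)
        per = _species_names(params.periphery_species, prefix="p")
        links = list(bb.links)
        for i, u in enumerate(per):
            for j, v in enumerate(per):
                if i != j and rng.random() < params.periphery_connectance:
                    links.append((u, v))
        for u in per:
            for v in bb.species:
                if rng.random() < params.attach_prob:
                    links.append((u, v))
                if rng.random() < params.attach_prob:
                    links.append((v, u))
        web = FoodWeb(f"{bb.id}_w{w}", list(bb.species) + per, links)
        webs.append(web)
        planted.append(set(bb.links))
    return webs, planted


def star_backbone(n_links: int = 6, web_id: str = "star") -> FoodWeb:
    """A centralized backbone: one resource consumed by n satellites."""
    sats = _species_names(n_links, prefix="v")
    return FoodWeb(web_id, ["hub"] + sats, [("hub", s) for s in sats])


def bipartite_backbone(n_links: int = 6, web_id: str = "bip") -> FoodWeb:
    """A two-level backbone: half the species consume the other half."""
    k = max(2, int(round(n_links / 2)))
    res = _species_names(k, prefix="r")
    con = _species_names(k, prefix="c")
    links = []
    for i in range(k):
        links.append((res[i], con[i]))
        links.append((res[i], con[(i + 1) % k]))
    return FoodWeb(web_id, res + con, links[:n_links] if n_links >= k else links)


def motif_rich_backbone(web_id: str = "core") -> FoodWeb:
    """A 6-link, 4-species backbone with distinctive species roles.

    A four-level food chain in which every consumer also feeds on all
    lower levels (maximal omnivory): basal -> grazer -> omni -> top
    plus all shortcut links.  Every member has within-core degree 3 and
    a unique in/out-degree signature, so roles are well separated and
    robust to a stray periphery attachment.  Unlike a star — whose
    satellite leaves are interchangeable with any periphery consumer of
    the hub — this core stays identifiable after random periphery is
    added, which makes it the default planted structure for
    backbone-recovery experiments.
    """
    sp = ["basal", "grazer", "omni", "top"]
    links = [("basal", "grazer"), ("basal", "omni"), ("basal", "top"),
             ("grazer", "omni"), ("grazer", "top"), ("omni", "top")]
    return FoodWeb(web_id, sp, links)


def fig_toy_triple() -> tuple[list[FoodWeb], list[Alignment]]:
    """Three small webs with reference alignments exercising transitivity.

    The triple realizes the two canonical pairing patterns: species
    ``c`` of the first web is paired with species in the other two webs
    that are themselves paired (alignment transitivity 1), while
    species ``d`` is paired with species that are never paired with
    each other (transitivity 0).
    """
    red = FoodWeb("red", ["a", "b", "c", "d"],
                  [("a", "c"), ("b", "c"), ("c", "d")])
    green = FoodWeb("green", ["g1", "g2", "g3", "g4"],
                    [("g1", "g3"), ("g2", "g3"), ("g3", "g4")])
    blue = FoodWeb("blue", ["b1", "b2", "b3", "b4"],
                   [("b1", "b3"), ("b2", "b3"), ("b3", "b4")])
    aln_rg = Alignment("red", "green", frozenset(
        [("a", "g1"), ("b", "g2"), ("c", "g3"), ("d", "g4")]))
    aln_rb = Alignment("red", "blue", frozenset(
        [("a", "b1"), ("b", "b2"), ("c", "b3"), ("d", "b4")]))
    # green-blue alignment closes the triangle for c's partners (g3, b3)
    # but pairs d's partners g4 and b4 elsewhere
    aln_gb = Alignment("green", "blue", frozenset(
        [("g1", "b1"), ("g2", "b4"), ("g3", "b3"), ("g4", "b2")]))
    return [red, green, blue], [aln_rg, aln_rb, aln_gb]
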