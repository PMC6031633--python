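"""Backbone extraction and clustering.

Builds an ensemble of webs sharing a planted 6-link core, computes each
web's link overlap across all alignments, extracts 6-link backbones,
aligns the backbones into the dissimilarity matrix E_6, and clusters a
mixed set of star-shaped and two-level backbones to show the
cluster-count vote and the consensus structures with link likelihoods.
"""

from fwalign import (AlignConfig, Backbone, all_pairs_align, backbone_matrix,
                     choose_n_clusters, cluster_and_consensus,
                     extract_backbone, link_overlap)
from fwalign.synthgen import (PlantedEnsembleParams, bipartite_backbone,
                              motif_rich_backbone, permuted_copy,
                              planted_backbone_ensemble, star_backbone)

webs, planted = planted_backbone_ensemble(PlantedEnsembleParams(
    n_webs=10, backbone=motif_rich_backbone(), periphery_species=12, seed=5))
config = AlignConfig.ensemble_preset(seed=0)
_, store = all_pairs_align(webs, config)

recovered = []
for web, truth in zip(webs, planted):
    bb = extract_backbone(link_overlap(web, store), k=6)
    hits = len({e for e, _ in bb.links} & truth)
    recovered.append(hits)
print(f"planted 6-link core links found in each web's backbone: {recovered}")
print(f"mean recovery {sum(recovered) / (6 * len(recovered)):.0%}")

# cluster two known backbone shapes: centralized star vs two-level
stars = [permuted_copy(star_backbone(6, "s"), seed=i, new_id=f"star{i}")[0]
         for i in range(5)]
bips = [permuted_copy(bipartite_backbone(6, "b"), seed=i, new_id=f"twolevel{i}")[0]
        for i in range(5)]
mk = lambda w: Backbone(w.id, 6, [(e, 1) for e in sorted(w.links)])
backbones = [mk(w) for w in stars + bips]
E6 = backbone_matrix(backbones, config)
n_clusters = choose_n_clusters(E6)
print(f"\ncluster-count vote on E_6 over {len(backbones)} backbones: "
      f"{n_clusters} clusters")

consensus = cluster_and_consensus(E6, backbones, n_clusters, config=config)
for c in consensus:
    shape = "star" if c.medoid_web_id.startswith("star") else "two-level"
    print(f"  cluster {c.cluster_id} ({shape}): medoid {c.medoid_web_id}, "
          f"{len(c.member_web_ids)} members, "
          f"{len(c.links)} consensus links, all with likelihood "
          f"{sorted(set(c.links.values()))}")
print("\nlink likelihood l = fraction of member backbones whose aligned "
      "image contains the link (l = 1.0 means every member shares it)")
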