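"""Alignment costs, quality, annealing and the exhaustive oracle."""

import numpy as np
import pytest

from fwalign.alignment import (AlignConfig, Alignment, _Problem,
                               cost_neighborhood, cost_simple,
                               exhaustive_alignment, optimize_alignment,
                               quality)
from fwalign.motifs import count_roles
from fwalign.synthgen import NicheParams, niche_web, permuted_copy
from fwalign.webio import FoodWeb


def identity_alignment(web, other_id=None):
    return Alignment(web.id, other_id or web.id,
                     frozenset((s, s) for s in web.species))


class TestAlignmentInvariants:
    def test_species_appear_once(self):
        with pytest.raises(ValueError, match="two pairs"):
            Alignment("A", "B", frozenset([("a", "x"), ("a", "y")]))

    def test_double_null_pair_rejected(self):
        with pytest.raises(ValueError):
            Alignment("A", "B", frozenset([(None, None)]))

    def test_partner_lookup_and_flip(self):
        aln = Alignment("A", "B", frozenset([("a", "x"), ("b", None)]))
        assert aln.partner_of("a") == "x"
        assert aln.partner_of("b") is None
        assert aln.flipped().partner_of("x") == "a"


class TestCostSimple:
    def test_identity_self_alignment_is_zero(self, catalog, niche_factory):
        web = niche_factory(12, seed=3)
        roles = count_roles(web, catalog)
        assert cost_simple(identity_alignment(web), roles, roles) == 0.0

    def test_all_unpaired_pays_epsilon_each(self):
        aln = Alignment("A", "B", frozenset(
            [("a1", None), ("a2", None), ("a3", None),
             (None, "b1"), (None, "b2")]))
        assert cost_simple(aln, {}, {}, epsilon=1.0) == pytest.approx(5.0)

    def test_mixed_pairs_sum_directly(self):
        # expected value assembled by hand from per-pair Pearson terms
        ra = {"a1": np.array([1., 2, 3, 4]), "a2": np.array([4., 1, 2, 2])}
        rb = {"b1": np.array([2., 1, 4, 3]), "b2": np.array([0., 3, 1, 2])}
        aln = Alignment("A", "B", frozenset(
            [("a1", "b1"), ("a2", "b2"), (None, "b3")]))
        rho1 = float(np.corrcoef(ra["a1"], rb["b1"])[0, 1])
        rho2 = float(np.corrcoef(ra["a2"], rb["b2"])[0, 1])
        expected = (1 - rho1) + (1 - rho2) + 1.0
        assert cost_simple(aln, ra, rb) == pytest.approx(expected, abs=1e-12)

    def test_missing_profile_raises(self):
        aln = Alignment("A", "B", frozenset([("a", "b")]))
        with pytest.raises(KeyError):
            cost_simple(aln, {}, {"b": np.ones(3)})

    def test_epsilon_monotonic_with_unpaired(self, catalog, niche_factory):
        wa, wb = niche_factory(8, seed=1), niche_factory(6, seed=2)
        ra, rb = count_roles(wa, catalog), count_roles(wb, catalog)
        pairs = [(a, b) for a, b in zip(wa.species, wb.species)]
        pairs += [(a, None) for a in wa.species[len(wb.species):]]
        aln = Alignment(wa.id, wb.id, frozenset(pairs))
        costs = [cost_simple(aln, ra, rb, epsilon=e) for e in (0.0, 0.5, 1.0, 2.0)]
        assert costs == sorted(costs) and costs[0] < costs[-1]


class TestCostNeighborhood:
    def test_identity_self_alignment_is_zero(self, catalog, niche_factory):
        web = niche_factory(10, seed=5)
        roles = count_roles(web, catalog)
        c = cost_neighborhood(identity_alignment(web), web, web, roles, roles)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_links_hand_evaluation(self, catalog):
        """Two isomorphic single-link webs aligned link-to-link: each
        pairing sees its one neighbor pairing with rho = 1, so cost 0."""
        wa = FoodWeb("A", ["a", "a2"], [("a", "a2")])
        wb = FoodWeb("B", ["b", "b2"], [("b", "b2")])
        ra, rb = count_roles(wa, catalog), count_roles(wb, catalog)
        good = Alignment("A", "B", frozenset([("a", "b"), ("a2", "b2")]))
        assert cost_neighborhood(good, wa, wb, ra, rb) == pytest.approx(0.0)
        # crossing the roles leaves every neighbor unpaired-in-context
        bad = Alignment("A", "B", frozenset([("a", "b2"), ("a2", "b")]))
        cb = cost_neighborhood(bad, wa, wb, ra, rb)
        # each of the two pairings pays (1 - rho(prey, predator)) via its
        # neighbor pairing; recompute that by hand
        from fwalign.motifs import role_similarity
        rho_x = role_similarity(ra["a"], rb["b2"])
        rho_y = role_similarity(ra["a2"], rb["b"])
        assert cb == pytest.approx((1 - rho_y) + (1 - rho_x), abs=1e-12)
        assert cb > 0

    def test_star_center_to_leaf_costs_more(self, catalog, star_web):
        other = FoodWeb("star2", ["HUB", "X", "Y", "Z"],
                        [("HUB", "X"), ("HUB", "Y"), ("HUB", "Z")])
        ra = count_roles(star_web, catalog)
        rb = count_roles(other, catalog)
        center = Alignment("star", "star2", frozenset(
            [("hub", "HUB"), ("x", "X"), ("y", "Y"), ("z", "Z")]))
        leaf = Alignment("star", "star2", frozenset(
            [("hub", "X"), ("x", "HUB"), ("y", "Y"), ("z", "Z")]))
        c_center = cost_neighborhood(center, star_web, other, ra, rb)
        c_leaf = cost_neighborhood(leaf, star_web, other, ra, rb)
        assert c_center == pytest.approx(0.0, abs=1e-12)
        assert c_leaf > c_center

    def test_unpaired_species_pays_per_neighbor(self, catalog, star_web):
        single = FoodWeb("s1", ["u", "v"], [("u", "v")])
        ra = count_roles(star_web, catalog)
        rb = count_roles(single, catalog)
        aln = Alignment("star", "s1", frozenset(
            [("hub", "u"), ("x", "v"), ("y", None), ("z", None)]))
        c = cost_neighborhood(aln, star_web, single, ra, rb, epsilon=0.75)
        # hand evaluation: pairing (hub,u): neighbor pairing (x,v) has
        # rho=1 (leaf roles identical), y,z unpaired -> 2 eps;
        # (x,v): neighbor pairing (hub,u) rho=1? hub has extra triads so
        # rho < 1 in general; recompute directly
        from fwalign.motifs import role_similarity
        rho_xu = role_similarity(ra["x"], rb["v"])
        rho_hu = role_similarity(ra["hub"], rb["u"])
        expected = ((1 - rho_xu) + 2 * 0.75) + (1 - rho_hu) \
            + 0.75 * 1 + 0.75 * 1   # y and z unpaired, one neighbor each
        assert c == pytest.approx(expected, abs=1e-12)


class TestQuality:
    def test_identity_is_zero(self, catalog, niche_factory):
        web = niche_factory(9, seed=7)
        roles = count_roles(web, catalog)
        assert quality(identity_alignment(web), roles, roles) == 0.0

    def test_exact_mean_over_matched_pairs(self):
        # rho values engineered exactly: 1, 0.5, -0.5
        ra = {"a1": np.array([1., 2, 3]), "a2": np.array([1., 2, 3]),
              "a3": np.array([1., 2, 3])}
        rb = {"b1": np.array([1., 2, 3]), "b2": np.array([1., 3, 2]),
              "b3": np.array([2., 3, 1])}
        aln = Alignment("A", "B", frozenset(
            [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]))
        assert quality(aln, ra, rb) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_unpaired_do_not_dilute(self):
        ra = {"a1": np.array([1., 2, 3])}
        rb = {"b1": np.array([1., 2, 3])}
        aln = Alignment("A", "B", frozenset([("a1", "b1"), (None, "b2"),
                                             (None, "b3")]))
        assert quality(aln, ra, rb) == 0.0

    def test_no_matches_is_maximal(self):
        aln = Alignment("A", "B", frozenset([("a1", None), (None, "b1")]))
        assert quality(aln, {}, {}) == 2.0


class TestKernelConsistency:
    """The fast index-space kernel must agree with the reference costs."""

    @pytest.mark.parametrize("seed", range(5))
    def test_full_costs_match_reference(self, seed):
        cfg = AlignConfig(seed=seed)
        wa = niche_web(NicheParams(8, 0.2, seed), web_id="A")
        wb = niche_web(NicheParams(7, 0.2, seed + 50), web_id="B")
        prob = _Problem(wa, wb, cfg)
        rng = np.random.default_rng(seed)
        p = prob.random_state(rng)
        aln = prob.to_alignment(p)
        assert prob.cost_neighborhood_state(p) == pytest.approx(
            cost_neighborhood(aln, wa, wb, prob.roles_a, prob.roles_b),
            abs=1e-9)
        assert prob.cost_simple_state(p) == pytest.approx(
            cost_simple(aln, prob.roles_a, prob.roles_b), abs=1e-9)

    @pytest.mark.parametrize("kind", ["simple", "neighborhood"])
    def test_swap_delta_matches_full_recompute(self, kind):
        cfg = AlignConfig(seed=0, cost_kind=kind)
        wa = niche_web(NicheParams(9, 0.2, 11), web_id="A")
        wb = niche_web(NicheParams(7, 0.2, 12), web_id="B")
        prob = _Problem(wa, wb, cfg)
        rng = np.random.default_rng(0)
        p = prob.random_state(rng)
        for _ in range(60):
            i1, i2 = rng.integers(prob.n, size=2)
            if i1 == i2:
                continue
            d = prob.delta_swap(p, int(i1), int(i2))
            c0 = prob.cost_state(p)
            p[i1], p[i2] = p[i2], p[i1]
            assert prob.cost_state(p) - c0 == pytest.approx(d, abs=1e-9)

    def test_directional_neighbors_variant_consistent(self):
        cfg = AlignConfig(seed=0, directional_neighbors=True)
        wa = niche_web(NicheParams(8, 0.2, 21), web_id="A")
        wb = niche_web(NicheParams(8, 0.2, 22), web_id="B")
        prob = _Problem(wa, wb, cfg)
        p = prob.random_state(np.random.default_rng(3))
        aln = prob.to_alignment(p)
        assert prob.cost_neighborhood_state(p) == pytest.approx(
            cost_neighborhood(aln, wa, wb, prob.roles_a, prob.roles_b,
                              directional=True), abs=1e-9)


class TestOptimize:
    def test_self_alignment_quality_zero(self, niche_factory, fast_config):
        web = niche_factory(20, seed=4, web_id="w")
        twin = FoodWeb("w2", web.species, web.links)
        aln, score = optimize_alignment(web, twin, fast_config)
        assert score.quality == pytest.approx(0.0, abs=1e-9)
        assert score.cost_neighborhood == pytest.approx(0.0, abs=1e-9)

    def test_isomorph_recovery_up_to_automorphism(self, niche_factory,
                                                  fast_config):
        web = niche_factory(15, seed=8, web_id="a_web")
        copy, mapping = permuted_copy(web, seed=3, new_id="b_web")
        aln, score = optimize_alignment(web, copy, fast_config)
        assert score.quality == pytest.approx(0.0, abs=1e-9)
        # the recovered mapping must be a link-preserving bijection
        m = aln.mapping()
        assert len(m) == web.n_species
        mapped = {(m[r], m[c]) for r, c in web.links}
        assert mapped == copy.links

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_on_tiny_pairs(self, seed):
        cfg = AlignConfig(seed=seed)
        wa = niche_web(NicheParams(5, 0.2, seed), web_id="A")
        wb = niche_web(NicheParams(6, 0.2, seed + 100), web_id="B")
        _, sa = optimize_alignment(wa, wb, cfg)
        _, ex = exhaustive_alignment(wa, wb, cfg)
        assert sa.cost_neighborhood >= ex.cost_neighborhood - 1e-9
        assert sa.cost_neighborhood == pytest.approx(ex.cost_neighborhood,
                                                     abs=1e-9)

    def test_symmetric_under_argument_order(self, niche_factory, fast_config):
        wa = niche_factory(8, seed=31, web_id="aa")
        wb = niche_factory(9, seed=32, web_id="bb")
        aln_ab, s_ab = optimize_alignment(wa, wb, fast_config)
        aln_ba, s_ba = optimize_alignment(wb, wa, fast_config)
        assert s_ab.quality == pytest.approx(s_ba.quality, abs=1e-12)
        assert aln_ab.pairs == aln_ba.flipped().pairs

    def test_cost_invariant_under_relabeling(self, niche_factory, fast_config):
        wa = niche_factory(10, seed=41, web_id="A")
        wb = niche_factory(10, seed=42, web_id="B")
        _, s1 = optimize_alignment(wa, wb, fast_config)
        wa2, _ = permuted_copy(wa, seed=5, new_id="A")
        _, s2 = optimize_alignment(wa2, wb, fast_config)
        assert s1.cost_neighborhood == pytest.approx(s2.cost_neighborhood,
                                                     abs=1e-9)

    def test_deterministic_given_seed(self, niche_factory):
        cfg = AlignConfig(seed=7, restarts=2, sweep_length=200,
                          max_stale_stages=5)
        wa = niche_factory(9, seed=51, web_id="A")
        wb = niche_factory(9, seed=52, web_id="B")
        aln1, s1 = optimize_alignment(wa, wb, cfg)
        aln2, s2 = optimize_alignment(wa, wb, cfg)
        assert aln1.pairs == aln2.pairs and s1 == s2

    def test_single_species_webs_align(self):
        wa = FoodWeb("x", ["s"], [])
        wb = FoodWeb("y", ["t"], [])
        aln, score = optimize_alignment(wa, wb, AlignConfig(seed=0))
        assert aln.mapping() == {"s": "t"}
        assert score.n_matched == 1


class TestExhaustive:
    def test_size_guard(self, niche_factory):
        wa, wb = niche_factory(8, seed=1), niche_factory(8, seed=2)
        with pytest.raises(ValueError, match="14"):
            exhaustive_alignment(wa, wb)

    def test_identical_chains_cost_zero(self, chain_web):
        twin = FoodWeb("chain2", chain_web.species, chain_web.links)
        aln, score = exhaustive_alignment(chain_web, twin)
        assert score.cost_neighborhood == pytest.approx(0.0, abs=1e-12)
        m = aln.mapping()
        assert {(m[r], m[c]) for r, c in chain_web.links} == twin.links

    def test_chain_vs_star_matches_independent_enumeration(self, catalog,
                                                           chain_web,
                                                           star_web):
        """Independent oracle: enumerate all padded bijections with
        itertools and the reference cost function."""
        from itertools import permutations as iperm
        cfg = AlignConfig()
        _, score = exhaustive_alignment(chain_web, star_web, cfg)
        ra = count_roles(chain_web, catalog)
        rb = count_roles(star_web, catalog)
        spa = list(chain_web.species) + [None]     # pad to 4
        best = np.inf
        for perm in iperm(star_web.species):
            pairs = [(a, b) for a, b in zip(spa, perm) if a is not None or b is not None]
            c = cost_neighborhood(Alignment("chain", "star", frozenset(pairs)),
                                  chain_web, star_web, ra, rb)
            best = min(best, c)
        assert score.cost_neighborhood == pytest.approx(best, abs=1e-9)

    def test_single_species_pairing(self, catalog):
        wa = FoodWeb("A", ["a"], [])
        wb = FoodWeb("B", ["b"], [])
        aln, score = exhaustive_alignment(wa, wb)
        assert aln.pairs == frozenset([("a", "b")])
        # both roles are all-zero vectors: degenerate-equal, rho = 1
        assert score.cost_simple == pytest.approx(0.0)
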