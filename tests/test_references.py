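"""Reference panels, size matching, and min-max normalization."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcoherence import (
    PanelError,
    ReferencePanel,
    SlopeFit,
    build_reference_panel,
    normalize_ci,
    normalize_slope,
    sample_random_geneset,
    select_size_matched_reference,
)
from tests.conftest import geneset


def panel(high, random, size=50):
    return ReferencePanel(target_size=size, high_slopes=list(high), random_slopes=list(random))


class TestSampleRandomGeneset:
    def test_full_pool(self):
        gs = sample_random_geneset({"A", "B", "C", "D", "E"}, 5, np.random.default_rng(0))
        assert gs.genes == {"A", "B", "C", "D", "E"}

    def test_seeded_determinism(self):
        pool = {f"G{i}" for i in range(100)}
        a = sample_random_geneset(pool, 10, np.random.default_rng(42))
        b = sample_random_geneset(pool, 10, np.random.default_rng(42))
        assert a.genes == b.genes

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            sample_random_geneset({"A", "B"}, 3, np.random.default_rng(0))

    def test_uniform_inclusion_frequency(self):
        """Drawing 2 of 5 genes 10,000 times: each gene's inclusion rate is
        ~0.4 within 3 binomial standard errors."""
        pool = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(7)
        counts = {g: 0 for g in pool}
        n = 10_000
        for _ in range(n):
            for g in sample_random_geneset(pool, 2, rng).genes:
                counts[g] += 1
        se = np.sqrt(0.4 * 0.6 / n)
        for g in pool:
            assert abs(counts[g] / n - 0.4) < 3 * se


class TestSelectSizeMatched:
    @staticmethod
    def _collection(sizes):
        return [geneset(f"set_{s:03d}", {f"G{s}_{i}" for i in range(s)}) for s in sizes]

    @staticmethod
    def _network_over(collections):
        g = nx.Graph()
        for sets in collections.values():
            for gs in sets:
                genes = sorted(gs.genes)
                g.add_edges_from(zip(genes, genes[1:]))
        return g

    def test_nearest_size_selection(self):
        collections = {"c": self._collection([10, 48, 52, 200])}
        net = self._network_over(collections)
        chosen = select_size_matched_reference(collections, net, target_size=50, per_collection=2)
        assert {gs.set_id for gs in chosen} == {"set_048", "set_052"}

    def test_tie_broken_lexicographically(self):
        a = geneset("alpha", {f"A{i}" for i in range(10)})
        b = geneset("beta", {f"B{i}" for i in range(14)})
        collections = {"c": [b, a]}
        net = self._network_over(collections)
        # target 12: both sets are 2 away; "alpha" < "beta"
        chosen = select_size_matched_reference(collections, net, target_size=12, per_collection=1)
        assert [gs.set_id for gs in chosen] == ["alpha"]

    def test_short_collection_returns_all(self):
        collections = {"c": self._collection([10, 20, 30, 40])}
        net = self._network_over(collections)
        chosen = select_size_matched_reference(collections, net, target_size=25, per_collection=10)
        assert len(chosen) == 4

    def test_matching_uses_effective_in_network_size(self):
        # set of 40 genes, none in the network, competes with a fully
        # annotated set of 20: for target 35 the absent set has effective
        # size 0 and loses
        present = geneset("present", {f"P{i}" for i in range(20)})
        absent = geneset("absent", {f"Q{i}" for i in range(40)})
        collections = {"c": [absent, present]}
        net = self._network_over({"c": [present]})
        chosen = select_size_matched_reference(collections, net, target_size=35, per_collection=1)
        assert [gs.set_id for gs in chosen] == ["present"]


class TestBuildReferencePanel:
    def test_planted_world_separates_anchors(self, world1):
        p = build_reference_panel(
            world1.network, world1.reference_collections, target_size=50,
            n_random=50, rng=np.random.default_rng(3),
        )
        assert p.beta_min < p.beta_max

    def test_single_random_slope_is_the_median(self, world1):
        p = build_reference_panel(
            world1.network, world1.reference_collections, target_size=40,
            n_random=1, rng=np.random.default_rng(5),
        )
        assert p.beta_max == p.random_slopes[0]

    def test_too_few_reference_slopes_rejected(self):
        # reference sets with no internal edges are all dropped
        g = nx.Graph([(f"A{i}", f"B{i}") for i in range(60)])
        collections = {"c": [geneset("s1", {"A0", "A1", "A2"}), geneset("s2", {"A3", "A4", "A5"})]}
        with pytest.raises(PanelError):
            build_reference_panel(g, collections, target_size=3, n_random=5, rng=np.random.default_rng(0))

    def test_oversized_target_rejected(self, world1):
        with pytest.raises(PanelError):
            build_reference_panel(
                world1.network, world1.reference_collections,
                target_size=world1.network.number_of_nodes() + 1, n_random=5,
            )

    def test_seeded_determinism(self, world1):
        kwargs = dict(target_size=30, n_random=20)
        a = build_reference_panel(
            world1.network, world1.reference_collections,
            rng=np.random.default_rng(9), **kwargs,
        )
        b = build_reference_panel(
            world1.network, world1.reference_collections,
            rng=np.random.default_rng(9), **kwargs,
        )
        assert a.random_slopes == b.random_slopes and a.high_slopes == b.high_slopes


class TestNormalize:
    def test_anchor_identities(self):
        p = panel(high=[1.0, 1.2, 0.8], random=[4.0, 5.0, 6.0])
        assert normalize_slope(p.beta_max, p) == pytest.approx(0.0)
        assert normalize_slope(p.beta_min, p) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        p = panel(high=[1.0], random=[5.0])
        assert normalize_slope(2.0, p) == pytest.approx(0.75)

    def test_values_beyond_one_not_clamped(self):
        p = panel(high=[1.0], random=[5.0])
        assert normalize_slope(0.5, p) == pytest.approx(1.125)

    def test_degenerate_panel_rejected(self):
        p = panel(high=[2.0], random=[2.0])
        assert p.degenerate
        with pytest.raises(PanelError):
            normalize_slope(1.0, p)

    def test_ci_reordered_to_coherence_scale(self):
        p = panel(high=[1.0], random=[5.0])
        fit = SlopeFit(beta=2.0, ci_low=1.5, ci_high=2.5, n_points=10, residual_df=9)
        assert normalize_ci(fit, p) == pytest.approx((0.625, 0.875))

    def test_ci_spanning_anchors(self):
        p = panel(high=[1.0], random=[5.0])
        fit = SlopeFit(beta=3.0, ci_low=1.0, ci_high=5.0, n_points=10, residual_df=9)
        assert normalize_ci(fit, p) == pytest.approx((0.0, 1.0))

    def test_zero_width_ci_at_random_anchor(self):
        p = panel(high=[1.0], random=[5.0])
        fit = SlopeFit(beta=5.0, ci_low=5.0, ci_high=5.0, n_points=10, residual_df=9)
        assert normalize_ci(fit, p) == pytest.approx((0.0, 0.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        beta=st.floats(0, 10),
        scale=st.floats(0.1, 10),
        low=st.floats(0.1, 2),
        spread=st.floats(0.5, 5),
    )
    def test_affine_invariance(self, beta, scale, low, spread):
        """Scaling every slope (query and panel) by a > 0 leaves coherence
        unchanged: coherence is a pure position within the panel range."""
        p1 = panel(high=[low], random=[low + spread])
        p2 = panel(high=[low * scale], random=[(low + spread) * scale])
        assert normalize_slope(beta, p1) == pytest.approx(
            normalize_slope(beta * scale, p2), rel=1e-9, abs=1e-9
        )

    def test_coherence_strictly_decreasing_in_slope(self):
        p = panel(high=[1.0], random=[5.0])
        values = [normalize_slope(b, p) for b in (0.5, 1.5, 3.0, 5.5)]
        assert values == sorted(values, reverse=True)
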