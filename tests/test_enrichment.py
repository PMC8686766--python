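"""Set enrichment statistics against enumeration and brute-force transport
oracles, plus network, overlap, composition and correlation-density ops."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

import proteotype as pt
from proteotype.data import DataError, ProteinSetCollection
from proteotype.enrichment import _running_sum_es

from conftest import make_annotation, make_matrix


def series(values, prefix="P"):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"{prefix}{i:03d}" for i in range(len(values))],
    )


def brute_force_emd(x, y):
    """Minimum-cost transport between two 1-D samples with uniform weights,
    via optimal assignment on lcm-expanded copies (independent of the
    sorted-CDF formula under test)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = np.lcm(len(x), len(y))
    xe = np.repeat(x, n // len(x))
    ye = np.repeat(y, n // len(y))
    cost = np.abs(xe[:, None] - ye[None, :])
    r, c = linear_sum_assignment(cost)
    return cost[r, c].sum() / n


def enumerate_es(values_sorted_desc, set_size, exponent=0.0):
    """ES of every membership of the given size (exhaustive null)."""
    n = len(values_sorted_desc)
    out = {}
    for combo in itertools.combinations(range(n), set_size):
        member = np.zeros(n, dtype=bool)
        member[list(combo)] = True
        out[combo] = _running_sum_es(values_sorted_desc, member, exponent)
    return out


class TestDirectionalEnrichment:
    def test_top_k_set_has_es_one(self):
        st = series(np.arange(20, 0, -1))
        sets = ProteinSetCollection({"top": frozenset(st.index[:5])})
        res = pt.directional_enrichment(st, sets, n_perm=50, seed=0, weight_exponent=0.0)
        assert res.table.loc["top", "es"] == pytest.approx(1.0)

    def test_small_case_exhaustive_oracle(self):
        # N=6, set at ranks 1 and 4 (0-based 0 and 3), exponent 0
        vals = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        member = np.zeros(6, dtype=bool)
        member[[0, 3]] = True
        # hand enumeration of the running sum: steps +1/2 at hits, -1/4 at misses
        running = np.cumsum([0.5, -0.25, -0.25, 0.5, -0.25, -0.25])
        expected_es = running[np.argmax(np.abs(running))]
        assert _running_sum_es(vals, member, 0.0) == pytest.approx(expected_es)
        # exhaustive permutation p over all C(6,2)=15 memberships (no +1
        # correction: the null is enumerated, not sampled)
        null = np.array(list(enumerate_es(vals, 2, 0.0).values()))
        es = expected_es
        same = null * np.sign(es) > 0
        p_exact = int((same & (np.abs(null) >= abs(es))).sum()) / len(null)
        st = series(vals)
        sets = ProteinSetCollection({"s": frozenset([st.index[0], st.index[3]])})
        n_perm = 2000
        res = pt.directional_enrichment(
            st, sets, n_perm=n_perm, seed=1, weight_exponent=0.0, min_size=2
        )
        assert res.table.loc["s", "es"] == pytest.approx(es)
        assert abs(res.table.loc["s", "p"] - p_exact) <= 2 / np.sqrt(n_perm)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(2)
        st = series(rng.normal(0, 1, 50))
        st.iloc[:8] += 2.0
        sets = ProteinSetCollection({"s": frozenset(st.index[:8])})
        res_pos = pt.directional_enrichment(st, sets, n_perm=500, seed=3)
        res_neg = pt.directional_enrichment(-st, sets, n_perm=500, seed=3)
        assert np.sign(res_pos.table.loc["s", "es"]) == -np.sign(res_neg.table.loc["s", "es"])
        assert res_pos.table.loc["s", "nes"] == pytest.approx(
            -res_neg.table.loc["s", "nes"], rel=0.2
        )

    def test_low_permutations_rejected(self):
        st = series(np.arange(10.0))
        sets = ProteinSetCollection({"s": frozenset(st.index[:3])})
        with pytest.raises(DataError, match="n_perm"):
            pt.directional_enrichment(st, sets, n_perm=5)

    def test_absent_set_excluded_with_warning(self):
        st = series(np.arange(10.0))
        sets = ProteinSetCollection({"gone": frozenset({"ZZZ"})})
        with pytest.warns(UserWarning, match="excluded"):
            res = pt.directional_enrichment(st, sets, n_perm=20, seed=0)
        assert res.excluded == ["gone"]

    def test_multi_symbol_probe_maps_to_sets(self):
        st = series(np.arange(12, 0, -1))
        symbol_map = {p: (f"SYM_{p}",) for p in st.index}
        symbol_map[st.index[0]] = ("SYM_X", "SYM_Y")
        sets = ProteinSetCollection(
            {"s": frozenset({"SYM_Y", f"SYM_{st.index[1]}", f"SYM_{st.index[2]}"})}
        )
        res = pt.directional_enrichment(st, sets, n_perm=20, seed=0, symbol_map=symbol_map)
        assert res.table.loc["s", "size"] == 3


class TestEMDEnrichment:
    def test_translation_property(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        st = series(np.concatenate([x + 2.5, x]))
        sets = ProteinSetCollection({"s": frozenset(st.index[:30])})
        res = pt.emd_enrichment(st, sets, n_perm=20, seed=0)
        assert res.table.loc["s", "emd_obs"] == pytest.approx(2.5)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([0.0, 1.0], [2.0, 3.0, 10.0]),
            ([1.0, 1.0, 2.0], [0.5, 4.0]),
            ([-3.0, 0.0, 1.0, 2.0], [0.0, 0.0, 5.0]),
            ([2.0], [1.0, 3.0, 4.0, 8.0, 9.0]),
            ([0.0, 0.1, 0.2, 0.3, 0.4], [1.0, 1.1, 1.2, 1.3, 1.4]),
        ],
    )
    def test_matches_brute_force_transport(self, x, y):
        assert stats.wasserstein_distance(x, y) == pytest.approx(
            brute_force_emd(x, y), abs=1e-10
        )

    def test_equal_size_sorted_pairing(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 8)
        expected = np.abs(np.sort(x) - np.sort(y)).mean()
        assert stats.wasserstein_distance(x, y) == pytest.approx(expected)

    def test_enriched_set_detected(self):
        rng = np.random.default_rng(6)
        st = series(rng.normal(0, 1, 200))
        st.iloc[:20] += 3.0
        sets = ProteinSetCollection({"hot": frozenset(st.index[:20])})
        res = pt.emd_enrichment(st, sets, n_perm=500, seed=7)
        assert res.table.loc["hot", "emd_ratio"] > 2.0
        assert res.table.loc["hot", "p"] == pytest.approx(1 / 501)


class TestEnrichmentNetwork:
    def _results(self, names, ps):
        table = pd.DataFrame(
            {"size": 5, "emd_obs": 1.0, "emd_null_mean": 1.0, "emd_ratio": 1.0, "p": ps, "q": ps},
            index=pd.Index(names, name="set"),
        )
        return pt.EnrichmentResult(table, 100, 0)

    def test_disjoint_sets_no_edges(self):
        sets = ProteinSetCollection(
            {"a": frozenset("ABC"), "b": frozenset("DEF"), "c": frozenset("GHI")}
        )
        net = pt.enrichment_network(self._results(["a", "b", "c"], [1e-4] * 3), sets)
        assert net.graph.number_of_edges() == 0
        assert net.n_components == 3

    def test_identical_sets_connected(self):
        sets = ProteinSetCollection({"a": frozenset("ABC"), "b": frozenset("ABC")})
        net = pt.enrichment_network(self._results(["a", "b"], [1e-4, 1e-4]), sets)
        assert net.graph.has_edge("a", "b")
        assert net.n_components == 1

    def test_subset_min_denominator(self):
        sets = ProteinSetCollection(
            {"small": frozenset("AB"), "big": frozenset("ABCDE")}
        )
        net = pt.enrichment_network(self._results(["small", "big"], [1e-4, 1e-4]), sets)
        assert net.graph.has_edge("small", "big")  # overlap / min = 1.0

    def test_threshold_filters_nodes(self):
        sets = ProteinSetCollection({"a": frozenset("ABC"), "b": frozenset("ABD")})
        net = pt.enrichment_network(self._results(["a", "b"], [1e-4, 0.5]), sets)
        assert list(net.graph.nodes) == ["a"]

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(8)
        universe = [f"G{i}" for i in range(40)]
        sets = {}
        for i in range(20):
            size = rng.integers(3, 10)
            sets[f"s{i:02d}"] = frozenset(rng.choice(universe, size, replace=False))
        coll = ProteinSetCollection(sets)
        res = self._results(list(sets), [1e-4] * 20)
        net = pt.enrichment_network(res, coll, overlap_threshold=0.5)
        for a, b in itertools.combinations(sorted(sets), 2):
            expected = len(sets[a] & sets[b]) / min(len(sets[a]), len(sets[b])) > 0.5
            assert net.graph.has_edge(a, b) == expected

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(30)]
        sets = {
            f"s{i}": frozenset(rng.choice(universe, 6, replace=False)) for i in range(10)
        }
        coll1 = ProteinSetCollection(dict(sets))
        coll2 = ProteinSetCollection(dict(reversed(list(sets.items()))))
        res1 = self._results(list(coll1.sets), [1e-4] * 10)
        res2 = self._results(list(coll2.sets), [1e-4] * 10)
        n1 = pt.enrichment_network(res1, coll1)
        n2 = pt.enrichment_network(res2, coll2)
        assert set(map(frozenset, n1.graph.edges)) == set(map(frozenset, n2.graph.edges))


def exhaustive_hypergeom_p(M, nA, nB, k):
    """P(overlap >= k) by summing the exact overlap pmf computed from
    binomial coefficients (independent of scipy.hypergeom)."""
    from math import comb

    total = comb(M, nB)
    return sum(
        comb(nA, j) * comb(M - nA, nB - j) / total
        for j in range(k, min(nA, nB) + 1)
    )


class TestHypergeometricOverlap:
    def test_enumeration_oracle(self):
        universe = [f"G{i}" for i in range(20)]
        a, b = set(universe[:5]), set(universe[2:6])
        res = pt.hypergeometric_overlap(a, b, universe)
        assert res.overlap == 3
        assert res.p == pytest.approx(exhaustive_hypergeom_p(20, 5, 4, 3), rel=1e-12)

    def test_overlap_equal_expected_fold_zero(self):
        universe = [f"G{i}" for i in range(20)]
        a, b = set(universe[:10]), set(universe[5:15])  # overlap 5 = 10*10/20
        res = pt.hypergeometric_overlap(a, b, universe)
        assert res.log2_fold == pytest.approx(0.0)

    def test_certainty_case(self):
        universe = list("ABCDE")
        res = pt.hypergeometric_overlap(universe, universe, universe)
        assert res.overlap == 5 and res.p == pytest.approx(1.0)

    def test_zero_overlap(self):
        universe = [f"G{i}" for i in range(10)]
        res = pt.hypergeometric_overlap(universe[:3], universe[5:8], universe)
        assert res.log2_fold == -np.inf
        assert res.p == pytest.approx(1.0)

    def test_empty_universe(self):
        with pytest.raises(DataError, match="universe"):
            pt.hypergeometric_overlap(set(), set(), set())

    def test_agrees_with_fisher_tail(self):
        # shared one-sided tail with Fisher's exact (cross-module consistency)
        universe = [f"G{i}" for i in range(25)]
        a, b = set(universe[:8]), set(universe[4:12])
        res = pt.hypergeometric_overlap(a, b, universe)
        k = res.overlap
        table = [[k, len(a) - k], [len(b) - k, 25 - len(a) - len(b) + k]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert res.p == pytest.approx(p_fisher, rel=1e-12)


class TestLocationComposition:
    def test_identical_composition(self):
        locs = ["nucleus"] * 10 + ["cytoplasm"] * 10
        ann = make_annotation([f"P{i:03d}" for i in range(20)], locations=locs)
        probes = ann.probe_ids
        res = pt.location_composition(probes, ann, probes)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # group (10, 0) against background proportions (0.5, 0.5):
        # chi2 = (10-5)^2/5 + (0-5)^2/5 = 10
        ann = make_annotation(
            [f"P{i:03d}" for i in range(30)],
            locations=["nucleus"] * 15 + ["cytoplasm"] * 15,
        )
        group = ann.probe_ids[:10]  # all nucleus
        res = pt.location_composition(group, ann, ann.probe_ids)
        assert res.chi2 == pytest.approx(10.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(10)
        locs = list(rng.choice(pt.CELLULAR_LOCATIONS, 50))
        ann = make_annotation([f"P{i:03d}" for i in range(50)], locations=locs)
        res = pt.location_composition(ann.probe_ids[:20], ann, ann.probe_ids)
        assert res.table["group_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert res.table["background_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_small_group_flagged(self):
        ann = make_annotation(
            ["P1", "P2", "P3"], locations=["nucleus", "nucleus", "cytoplasm"]
        )
        res = pt.location_composition(["P1", "P2"], ann, ann.probe_ids)
        assert res.low_count


class TestMarkerCorrelationDensity:
    def test_two_markers_single_pair(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(10, 1, size=(30, 20)), log=True)
        res = pt.marker_correlation_density(m, m.probe_ids[:2])
        assert len(res.marker_rhos) == 1

    def test_latent_factor_markers_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n_sub = 40
            f = rng.standard_normal(n_sub)
            markers = f[None, :] + rng.normal(0, 0.5, size=(15, n_sub))
            background = rng.normal(0, 1, size=(185, n_sub))
            m = make_matrix(np.vstack([markers, background]) + 10, log=True)
            res = pt.marker_correlation_density(m, m.probe_ids[:15], seed=seed)
            med_shift = np.median(res.marker_rhos) > np.median(res.background_rhos)
            hits += med_shift and res.p < 0.01
        assert hits >= 9

    def test_fewer_than_two_markers(self):
        m = make_matrix(np.random.default_rng(12).normal(10, 1, (5, 8)), log=True)
        with pytest.raises(DataError, match="at least 2"):
            pt.marker_correlation_density(m, m.probe_ids[:1])
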