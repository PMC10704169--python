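"""Spectrum filtering, modified cosine vs brute force, network rules."""

import itertools

import numpy as np
import pytest

from halolip.features_io import Ms2Spectrum
from halolip.molecular_network import (
    NetworkConfig,
    build_network,
    categorize_components,
    filter_network,
    filter_spectrum,
    modified_cosine,
    network_summary,
)

CFG = NetworkConfig()


def spec(prec, peaks, fid="S"):
    return Ms2Spectrum(prec, 10.0, peaks, feature_id=fid)


# ---------------------------------------------------------------------------
# Brute-force oracle for the modified cosine
# ---------------------------------------------------------------------------

def brute_force_modified_cosine(a, b, tol=0.05):
    """Exhaustive search over all one-to-one eligible peak assignments."""
    shift = a.precursor_mz - b.precursor_mz
    sa = np.sqrt(a.intensity_array)
    sb = np.sqrt(b.intensity_array)
    eligible = [
        (i, j)
        for i, (ma, _) in enumerate(a.peaks)
        for j, (mb, _) in enumerate(b.peaks)
        if abs(ma - mb) <= tol or abs(ma - (mb + shift)) <= tol
    ]
    best, best_n = 0.0, 0
    for r in range(len(eligible) + 1):
        for combo in itertools.combinations(eligible, r):
            if len({i for i, _ in combo}) != r:
                continue
            if len({j for _, j in combo}) != r:
                continue
            s = sum(sa[i] * sb[j] for i, j in combo)
            if s > best:
                best, best_n = s, r
    if best == 0.0:
        return 0.0, 0
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    return best / norm, best_n


class TestFilterSpectrum:
    def test_small_spectrum_unchanged(self):
        s = spec(800.0, [(100.0, 5.0), (200.0, 10.0), (300.0, 1.0)])
        assert filter_spectrum(s, CFG).peaks == s.peaks

    def test_precursor_proximal_peak_removed(self):
        s = spec(800.0, [(790.0, 100.0), (300.0, 10.0)])
        out = filter_spectrum(s, CFG)
        assert (790.0, 100.0) not in out.peaks
        assert (300.0, 10.0) in out.peaks

    def test_top6_in_window_survive(self):
        """8 equally spaced peaks within 50 Da: exactly the 6 most intense
        survive (checked against a direct windowed-rank computation)."""
        peaks = [(300.0 + 3 * i, float(10 + i)) for i in range(8)]
        out = filter_spectrum(spec(800.0, peaks), CFG)
        expected = sorted(peaks, key=lambda p: -p[1])[:6]
        assert sorted(out.peaks) == sorted(expected)

    def test_idempotent(self, sim_default):
        for s in sim_default.spectra[:40]:
            once = filter_spectrum(s, CFG)
            twice = filter_spectrum(once, CFG)
            assert once.peaks == twice.peaks


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = spec(800.0, [(100.0, 5.0), (200.0, 10.0), (300.0, 1.0),
                         (400.0, 7.0)])
        score, n = modified_cosine(s, s)
        assert score == pytest.approx(1.0)
        assert n == 4

    def test_disjoint_spectra_score_zero(self):
        a = spec(800.0, [(100.0, 5.0), (200.0, 10.0)])
        b = spec(800.0, [(150.0, 5.0), (250.0, 10.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_empty_spectrum_scores_zero(self):
        a = spec(800.0, [(100.0, 5.0)])
        b = Ms2Spectrum(700.0, 1.0, [])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_symmetry(self):
        a = spec(800.0, [(100.0, 5.0), (300.0, 8.0), (500.0, 2.0)])
        b = spec(820.0, [(100.0, 4.0), (320.0, 9.0), (520.0, 1.0)])
        assert modified_cosine(a, b) == pytest.approx(modified_cosine(b, a))

    def test_direct_plus_shifted_matches_against_oracle(self):
        """5-peak pair with two direct and one shifted match equals the
        exhaustive-assignment oracle."""
        a = spec(800.0, [(100.0, 10.0), (200.0, 20.0), (450.0, 5.0),
                         (600.0, 8.0), (700.0, 3.0)])
        b = spec(820.0, [(100.0, 12.0), (200.0, 18.0), (470.0, 6.0),
                         (555.0, 2.0), (777.0, 1.0)])
        assert modified_cosine(a, b, 0.05) == pytest.approx(
            brute_force_modified_cosine(a, b, 0.05)
        )

    def test_random_battery_matches_oracle(self):
        """Seeded random spectra with <= 8 peaks: optimal-assignment
        equivalence for every pair."""
        rng = np.random.default_rng(7)
        specs = []
        for k in range(10):
            n = int(rng.integers(2, 9))
            prec = float(rng.uniform(600, 900))
            # cluster m/z on a coarse grid so collisions/shift-matches occur
            mzs = np.sort(rng.choice(np.arange(100, 560, 20.0), n,
                                     replace=False)
                          + rng.normal(0, 0.02, n))
            ints = rng.uniform(1, 100, n)
            specs.append(spec(prec, list(zip(mzs, ints)), fid=f"R{k}"))
        for a, b in itertools.combinations(specs, 2):
            mine = modified_cosine(a, b, 0.05)
            oracle = brute_force_modified_cosine(a, b, 0.05)
            assert mine[0] == pytest.approx(oracle[0], abs=1e-9)
            assert mine[1] == oracle[1]

    def test_bounded_in_unit_interval(self, sim_default):
        specs = [filter_spectrum(s, CFG) for s in sim_default.spectra[:25]]
        for a, b in itertools.combinations(specs, 2):
            score, _ = modified_cosine(a, b)
            assert 0.0 <= score <= 1.0


SIX = [(100.0, 10.0), (150.0, 20.0), (220.0, 30.0), (300.0, 40.0),
       (380.0, 50.0), (460.0, 60.0)]


class TestBuildNetwork:
    def test_identical_spectra_link(self):
        a = spec(800.0, SIX, "A")
        b = spec(800.0, SIX, "B")
        g = build_network([a, b], CFG)
        assert g.number_of_edges() == 1

    def test_high_cosine_but_few_peaks_no_edge(self):
        a = spec(800.0, SIX[:4], "A")
        b = spec(800.0, SIX[:4], "B")
        g = build_network([a, b], CFG)  # cosine 1.0 but only 4 matched
        assert g.number_of_edges() == 0

    def test_dissimilar_singletons(self):
        specs = [
            spec(600.0 + 50 * i, [(50.0 + 13 * i + j, 10.0) for j in range(6)],
                 f"S{i}")
            for i in range(4)
        ]
        g = build_network(specs, CFG)
        assert g.number_of_edges() == 0

    def test_edge_set_invariant_under_input_order(self):
        a, b, c = (spec(800.0, SIX, "A"), spec(800.0, SIX, "B"),
                   spec(650.0, [(90.0 + i, 5.0) for i in range(6)], "C"))
        g1 = build_network([a, b, c], CFG)
        g2 = build_network([c, b, a], CFG)
        assert set(g1.edges) == set(g2.edges)
        assert set(g1.nodes) == set(g2.nodes)


def _chain_graph(ids, mz=800.0):
    import networkx as nx
    g = nx.Graph()
    for n in ids:
        g.add_node(n, mz=mz)
    for u, v in zip(ids, ids[1:]):
        g.add_edge(u, v, cosine=0.9, matched_peaks=6, delta_mz=0.0)
    return g


class TestFilterNetwork:
    def test_small_component_removed(self):
        g = _chain_graph(["a", "b", "c"])
        assert filter_network(g, CFG).number_of_nodes() == 0

    def test_mz_boundary(self):
        g = _chain_graph(["a", "b", "c", "d"])
        g.nodes["a"]["mz"] = 499.9
        out = filter_network(g, CFG)
        assert "a" not in out  # and the remaining 3-node component dies
        assert out.number_of_nodes() == 0
        g2 = _chain_graph(["a", "b", "c", "d"], mz=500.0)
        assert filter_network(g2, CFG).number_of_nodes() == 4

    def test_blank_removal_can_kill_component(self):
        g = _chain_graph(["a", "b", "c", "d", "e"])
        out = filter_network(g, CFG, blank_features={"a", "b"})
        assert out.number_of_nodes() == 0

    def test_exactly_min_size_kept(self):
        g = _chain_graph(["a", "b", "c", "d"])
        assert filter_network(g, CFG).number_of_nodes() == 4


class TestCategorizeAndSummary:
    def _graph(self):
        import networkx as nx
        g = nx.Graph()
        # component 1: 3 PG-annotated + 1 unknown
        for n, cls in [("p1", "PG"), ("p2", "PG"), ("p3", "PG"), ("u1", "")]:
            g.add_node(n, mz=800.0, annotation=cls and f"{cls} x",
                       lipid_class=cls, taxa=["Haloferacales"])
        g.add_edges_from([("p1", "p2"), ("p2", "p3"), ("p3", "u1")])
        # component 2: all unknown, one taxon only
        for n in ("h1", "h2", "h3", "h4"):
            g.add_node(n, mz=900.0, annotation="", lipid_class="",
                       taxa=["Haloferacales"])
        g.add_edges_from([("h1", "h2"), ("h2", "h3"), ("h3", "h4")])
        # component 3: all unknown, mixed taxa
        for i, n in enumerate(("m1", "m2", "m3", "m4")):
            g.add_node(n, mz=900.0, annotation="", lipid_class="",
                       taxa=["Haloferacales" if i % 2 else "Natrialbales",
                             "Halobacteriales"])
        g.add_edges_from([("m1", "m2"), ("m2", "m3"), ("m3", "m4")])
        return g

    def test_majority_annotation_wins(self):
        g = self._graph()
        labels = categorize_components(g)
        assert labels[frozenset({"p1", "p2", "p3", "u1"})] == "PG"

    def test_taxon_dominant_unknown(self):
        g = self._graph()
        labels = categorize_components(g)
        assert labels[frozenset({"h1", "h2", "h3", "h4"})] == \
            "Haloferacales-dominant unknown"

    def test_mixed_taxa_unknown(self):
        g = self._graph()
        labels = categorize_components(g)
        assert labels[frozenset({"m1", "m2", "m3", "m4"})] == "unknown"

    def test_summary_partition_identity(self):
        g = self._graph()
        s = network_summary(g)
        assert s["n_nodes"] == 12
        assert s["n_identified"] + s["n_analogs"] + s["n_new"] == s["n_nodes"]
        assert s["n_identified"] == 3
        assert s["n_analogs"] == 1
        assert s["n_new"] == 8

    def test_empty_network_all_zero(self):
        import networkx as nx
        s = network_summary(nx.Graph())
        assert all(v == 0 for v in s.values())

    def test_all_identified(self):
        import networkx as nx
        g = nx.Graph()
        g.add_node("a", annotation="PG x", lipid_class="PG")
        g.add_node("b", annotation="PG y", lipid_class="PG")
        g.add_edge("a", "b")
        assert network_summary(g)["n_unknown"] == 0


def test_partition_identity_on_synthetic_network(sim_default):
    """On the simulated study the summary identity holds after filtration."""
    from halolip.molecular_network import annotate_network

    sim = sim_default
    blank_ids = {
        f.feature_id for f in sim.features
        if any(f.intensities.get(b, 0) > 0 for b in sim.metadata.blank_ids)
    }
    specs = sim.spectra[:120]
    g = build_network(specs, CFG)
    g = filter_network(g, CFG, blank_ids)
    annotate_network(g)
    s = network_summary(g)
    assert s["n_identified"] + s["n_analogs"] + s["n_new"] == s["n_nodes"]
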