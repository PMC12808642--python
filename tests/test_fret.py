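"""Orientation factor, Forster rates and the transfer network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigmentnet import (
    FretParameters,
    build_network,
    fret_rate,
    generate_complex,
    kappa_squared,
    lifetime_filtered,
    outer_to_inner_table,
    transition_dipole,
    trimer_double_ring,
)
from pigmentnet.fret import export_graph, import_graph
from pigmentnet.geometry import GeometryThresholds
from pigmentnet.records import PigmentClass, PigmentRecord, SubunitRecord

from conftest import make_chlorophyll, random_chlorophyll_model

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


class TestKappaSquared:
    @pytest.mark.parametrize("u_d,u_a,r,expected", [
        (Z, Z, Z, 4.0),        # collinear head-to-tail
        (X, Y, Z, 0.0),        # mutually orthogonal
        (X, X, Z, 1.0),        # parallel, perpendicular to R
        (X, Y, X, 0.0),        # acceptor orthogonal to both
    ])
    def test_analytic_cases(self, u_d, u_a, r, expected):
        assert kappa_squared(u_d, u_a, r * 17.0) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_range_and_symmetries(self):
        """kappa^2 in [0,4]; invariant under dipole flips and
        donor/acceptor exchange."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            ud, ua, r = (v / np.linalg.norm(v)
                         for v in rng.normal(size=(3, 3)))
            k = kappa_squared(ud, ua, r)
            assert 0.0 <= k <= 4.0
            assert kappa_squared(-ud, ua, r) == pytest.approx(k, rel=1e-12)
            assert kappa_squared(ud, -ua, r) == pytest.approx(k, rel=1e-12)
            assert kappa_squared(ua, ud, -r) == pytest.approx(k, rel=1e-12)

    def test_isotropic_average_is_two_thirds(self):
        """Monte-Carlo over uniform orientations converges to 2/3."""
        rng = np.random.default_rng(42)
        n = 10 ** 6
        def units():
            v = rng.normal(size=(n, 3))
            return v / np.linalg.norm(v, axis=1, keepdims=True)
        ud, ua, r = units(), units(), units()
        k = (np.einsum("ij,ij->i", ud, ua)
             - 3 * np.einsum("ij,ij->i", ud, r)
             * np.einsum("ij,ij->i", ua, r)) ** 2
        se = k.std(ddof=1) / math.sqrt(n)
        assert k.mean() == pytest.approx(2 / 3, abs=3 * se)

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            kappa_squared(X, Y, np.zeros(3))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1, 1), min_size=9, max_size=9))
    def test_bounds_hold_for_arbitrary_orientations(self, raw):
        v = np.array(raw).reshape(3, 3)
        norms = np.linalg.norm(v, axis=1)
        if (norms < 1e-3).any():
            return  # no direction defined
        ud, ua, r = v / norms[:, None]
        assert 0.0 <= kappa_squared(ud, ua, r) <= 4.0 + 1e-12


class TestDipole:
    def test_direction_and_normalization(self):
        sub = SubunitRecord("A")
        p = PigmentRecord(("A", 1, "CLA"), PigmentClass.CHLOROPHYLL_A, sub,
                          mg=(1, 0, 0), nb=(0, 0, 0), nd=(2, 0, 0))
        np.testing.assert_allclose(transition_dipole(p), [1, 0, 0])

    def test_degenerate_axis_rejected_at_construction(self):
        sub = SubunitRecord("A")
        with pytest.raises(ValueError, match="NB and ND coincide"):
            PigmentRecord(("A", 1, "CLA"), PigmentClass.CHLOROPHYLL_A, sub,
                          mg=(0, 0, 0), nb=(1, 1, 1), nd=(1, 1, 1))

    def test_flip_leaves_rates_unchanged(self):
        rng = np.random.default_rng(9)
        model = random_chlorophyll_model(rng, 10, n_subunits=5)
        chls = model.chlorophylls()
        for i in range(0, 8, 2):
            a, b = chls[i], chls[i + 1]
            k1 = fret_rate(a, b).rate
            a.nb, a.nd = a.nd, a.nb  # flip donor axis
            assert fret_rate(a, b).rate == pytest.approx(k1, rel=1e-12)


class TestRate:
    def test_closed_form_value(self):
        """kappa^2=1, R=2.0 nm, C=32.26, n=1.55: the rate equals the hand
        evaluation 32.26/(1.55^4 * 2^6) ~ 0.0873 ps^-1 (tau ~ 11.45 ps)."""
        sub_a, sub_b = SubunitRecord("A"), SubunitRecord("B")
        d = make_chlorophyll(sub_a, 1, (0, 0, 0), u=X)
        a = make_chlorophyll(sub_b, 1, (0, 0, 20.0), u=X)
        edge = fret_rate(d, a)
        assert edge.kappa_sq == pytest.approx(1.0, abs=1e-12)
        assert edge.rate == pytest.approx(32.26 / (1.55 ** 4 * 2.0 ** 6),
                                          rel=1e-12)
        assert edge.lifetime == pytest.approx(11.4510, abs=1e-3)

    def test_zero_kappa_means_no_transfer(self):
        sub_a, sub_b = SubunitRecord("A"), SubunitRecord("B")
        d = make_chlorophyll(sub_a, 1, (0, 0, 0), u=X)
        a = make_chlorophyll(sub_b, 1, (0, 0, 20.0), u=Y)
        edge = fret_rate(d, a)
        assert edge.rate == 0.0 and math.isinf(edge.lifetime)

    def test_r6_scaling_and_kappa_linearity(self):
        sub_a, sub_b = SubunitRecord("A"), SubunitRecord("B")
        d = make_chlorophyll(sub_a, 1, (0, 0, 0), u=X)
        near = make_chlorophyll(sub_b, 1, (0, 0, 10.0), u=X)
        far = make_chlorophyll(sub_b, 2, (0, 0, 20.0), u=X)
        assert fret_rate(d, near).rate == pytest.approx(
            64 * fret_rate(d, far).rate, rel=1e-12)

    def test_rate_symmetric_in_donor_acceptor(self):
        rng = np.random.default_rng(31)
        model = random_chlorophyll_model(rng, 20, n_subunits=4)
        chls = model.chlorophylls()
        for i in range(0, 18, 3):
            e1 = fret_rate(chls[i], chls[i + 1])
            e2 = fret_rate(chls[i + 1], chls[i])
            assert e1.rate == pytest.approx(e2.rate, rel=1e-12)

    def test_coincident_mg_rejected(self):
        sub_a, sub_b = SubunitRecord("A"), SubunitRecord("B")
        d = make_chlorophyll(sub_a, 1, (0, 0, 0))
        a = make_chlorophyll(sub_b, 1, (0, 0, 0))
        with pytest.raises(ValueError, match="coincident"):
            fret_rate(d, a)


def brute_force_edges(model, cutoff, C=32.26, n=1.55):
    """Independent O(N^2) evaluation of the rate expression."""
    chls = model.chlorophylls()
    out = {}
    for i in range(len(chls)):
        for j in range(i + 1, len(chls)):
            a, b = chls[i], chls[j]
            rv = b.mg - a.mg
            R = np.linalg.norm(rv)
            if R > cutoff:
                continue
            ua = (a.nd - a.nb) / np.linalg.norm(a.nd - a.nb)
            ub = (b.nd - b.nb) / np.linalg.norm(b.nd - b.nb)
            rh = rv / R
            k2 = (ua @ ub - 3 * (ua @ rh) * (ub @ rh)) ** 2
            out[frozenset((a.key, b.key))] = C * k2 / (n ** 4 * (R / 10) ** 6)
    return out


class TestNetwork:
    def test_empty_model_gives_empty_graph(self):
        from pigmentnet.records import ComplexModel
        g = build_network(ComplexModel(name="none"))
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_matches_brute_force_oracle(self):
        """Edge sets and rates equal the O(N^2) oracle on random clouds."""
        rng = np.random.default_rng(77)
        for trial in range(6):
            model = random_chlorophyll_model(rng, int(rng.integers(20, 120)))
            cutoff = float(rng.uniform(10, 24))
            g = build_network(model, geometry_thresholds=GeometryThresholds(
                pair_cutoff=cutoff, highlight_cutoff=cutoff / 2))
            expect = brute_force_edges(model, cutoff)
            got = {frozenset((u, v)): d["rate"]
                   for u, v, d in g.edges(data=True)}
            assert set(got) == set(expect)
            for k in got:
                assert got[k] == pytest.approx(expect[k], rel=1e-9)

    def test_planted_pair_tops_the_ranking(self):
        """Planted close, collinear inter-ring pairs rank fastest, in
        planted order."""
        model, truth = generate_complex(trimer_double_ring(
            seed=13, plant_close_pairs=3))
        from pigmentnet import assign_rings, membrane_frame
        assign_rings(model, membrane_frame(model))
        g = build_network(model)
        edges, summary = outer_to_inner_table(g)
        top = [frozenset((r.donor_node, r.acceptor_node))
               for r in edges.head(3).itertuples()]
        planted = [frozenset((f"{a[0]}/{a[1]}", f"{b[0]}/{b[1]}"))
                   for a, b in truth.planted_pairs]
        assert top == planted
        assert (edges["rate"].diff().dropna() <= 1e-12).all()  # sorted
        assert (summary["n_fast"] >= 1).sum() >= 3

    def test_lifetime_filters_nest(self, trimer):
        model, _, _ = trimer
        g = build_network(model)
        g40 = lifetime_filtered(g, 40.0)
        g20 = lifetime_filtered(g, 20.0)
        assert set(g20.edges()) <= set(g40.edges()) <= set(g.edges())
        assert all(d["lifetime"] < 40 for _, _, d in g40.edges(data=True))
        assert g.number_of_nodes() == g40.number_of_nodes()

    def test_outer_to_inner_table_empty_without_rings(self):
        rng = np.random.default_rng(3)
        model = random_chlorophyll_model(rng, 10)
        edges, summary = outer_to_inner_table(build_network(model))
        assert edges.empty and summary.empty


class TestExport:
    @pytest.mark.parametrize("fmt", ["gexf", "graphml", "tsv"])
    def test_roundtrip(self, small_spec, tmp_path, fmt):
        model, _ = generate_complex(small_spec)
        from pigmentnet import assign_rings, membrane_frame
        assign_rings(model, membrane_frame(model))
        g = build_network(model)
        path = tmp_path / f"g.{fmt}"
        export_graph(g, path, fmt)
        g2 = import_graph(path, fmt)
        assert {frozenset(e) for e in g2.edges()} == \
               {frozenset(e) for e in g.edges()}
        if fmt != "tsv":  # edge lists cannot carry isolated nodes
            assert set(g2.nodes()) == set(g.nodes())
        for u, v, d in g.edges(data=True):
            assert float(g2.edges[u, v]["rate"]) == pytest.approx(
                d["rate"], rel=1e-9)
            assert d["rate"] >= 0.0

    def test_empty_graph_exports(self, tmp_path):
        import networkx as nx
        for fmt in ("gexf", "graphml", "tsv"):
            path = tmp_path / f"empty.{fmt}"
            export_graph(nx.Graph(), path, fmt)
            assert import_graph(path, fmt).number_of_edges() == 0

    def test_unknown_format_rejected(self, tmp_path):
        import networkx as nx
        with pytest.raises(ValueError, match="unknown graph format"):
            export_graph(nx.Graph(), tmp_path / "x", "dot")
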