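"""Membrane frame, sidedness, ring assignment, interfacial pairs."""

import math

import numpy as np
import pytest

from pigmentnet import (
    ComplexModel,
    GeometryThresholds,
    SubunitRecord,
    assign_rings,
    classify_sidedness,
    generate_complex,
    interfacial_pairs,
    membrane_frame,
    perturb_complex,
    trimer_double_ring,
)
from pigmentnet.geometry import PairCategory
from pigmentnet.records import ISIA, Ring

from conftest import make_chlorophyll, random_chlorophyll_model


def angle_between(u, v):
    c = abs(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(c, 1.0)))


class TestMembraneFrame:
    def test_recovers_generator_normal(self, trimer):
        """Built with normal +z and the extrinsic marker above the
        membrane; the estimated normal must point along +z."""
        _, truth, frame = trimer
        assert angle_between(frame.normal, truth.normal) < 0.5
        assert np.dot(frame.normal, truth.normal) > 0  # marker side positive

    def test_equivariance_under_rigid_motion(self, small_spec):
        model, _ = generate_complex(small_spec)
        frame = membrane_frame(model)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [25, -40, 60], degrees=True)
        moved = perturb_complex(model, rotation_deg=np.linalg.norm(
            rot.as_rotvec(degrees=True)), axis=rot.as_rotvec(),
            translation=(12, -7, 30))
        frame2 = membrane_frame(moved)
        expected = rot.as_matrix() @ frame.normal
        assert angle_between(frame2.normal, expected) < 0.5
        assert np.dot(frame2.normal, expected) > 0

    def test_too_few_chlorophylls(self):
        sub = SubunitRecord("A", role=ISIA)
        model = ComplexModel(name="two", subunits=[sub], pigments=[
            make_chlorophyll(sub, 501, (0, 0, 0)),
            make_chlorophyll(sub, 502, (10, 0, 0))])
        with pytest.raises(ValueError, match="at least 3"):
            membrane_frame(model)

    def test_no_marker_no_sign_is_an_error(self):
        sub = SubunitRecord("A", role=ISIA)
        model = ComplexModel(name="m", subunits=[sub], pigments=[
            make_chlorophyll(sub, 500 + i, p) for i, p in enumerate(
                [(0, 0, 1), (10, 0, -1), (0, 10, 1), (10, 10, -1)])])
        with pytest.raises(ValueError, match="marker"):
            membrane_frame(model)
        frame = membrane_frame(model, cytoplasmic_sign=+1)
        assert abs(np.linalg.norm(frame.normal) - 1) < 1e-9


class TestSidedness:
    def test_two_layer_counts(self, trimer):
        """Default double ring: 473 cytoplasmic / 258 lumenal antenna
        chlorophylls, matching the generated layer allocation."""
        model, truth, frame = trimer
        labels, counts = classify_sidedness(model.chlorophylls(role=ISIA),
                                            frame)
        assert counts == {"cytoplasmic": 473, "lumenal": 258}
        assert labels == {pid: truth.sidedness[pid] for pid in labels}

    def test_counts_sum_and_one_sided_case(self, trimer):
        model, truth, frame = trimer
        chls = model.chlorophylls(role=ISIA)
        _, counts = classify_sidedness(chls, frame)
        assert counts["cytoplasmic"] + counts["lumenal"] == len(chls)
        # classifying only one layer's pigments leaves the other side empty
        upper = [p for p in chls
                 if truth.sidedness[p.pigment_id] == "cytoplasmic"]
        _, counts_up = classify_sidedness(upper, frame)
        assert counts_up["lumenal"] == 0 and counts_up["cytoplasmic"] == len(upper)

    def test_invariance_under_rigid_motion(self, small_spec):
        model, _ = generate_complex(small_spec)
        frame = membrane_frame(model)
        _, counts = classify_sidedness(model.chlorophylls(role=ISIA), frame)
        moved = perturb_complex(model, rotation_deg=77, axis=(1, 2, 3),
                                translation=(-20, 4, 9))
        _, counts2 = classify_sidedness(
            moved.chlorophylls(role=ISIA), membrane_frame(moved))
        assert counts == counts2


class TestRingAssignment:
    def test_default_double_ring_split(self, trimer):
        model, truth, _ = trimer
        inner = [s for s in model.subunits if s.ring is Ring.INNER]
        outer = [s for s in model.subunits if s.ring is Ring.OUTER]
        assert (len(inner), len(outer)) == (18, 25)
        for s in inner + outer:
            assert (s.ring.value, s.ring_index) == truth.rings[s.chain_id]

    def test_monomer_layers(self, monomer):
        model, truth, _ = monomer
        got = {s.chain_id: (s.ring.value, s.ring_index)
               for s in model.subunits if s.is_antenna}
        assert got == truth.rings

    def test_explicit_radii_split(self):
        """Protomers at 90 and 140 A split perfectly by the radial gap."""
        model, truth = generate_complex(trimer_double_ring(
            inner_count=6, outer_count=8, inner_radius=90.0,
            outer_radius=140.0, chl_per_subunit=5, layer_allocation=(3, 2),
            core_count=1, seed=3))
        frame = membrane_frame(model)
        res = assign_rings(model, frame)
        assert not res.single_ring
        assert {model.subunit(c).ring_index for c in res.inner} == set(range(1, 7))
        got = {c: (model.subunit(c).ring.value, model.subunit(c).ring_index)
               for c in truth.rings}
        assert got == truth.rings

    def test_single_ring_flagged_not_raised(self):
        model, _ = generate_complex(trimer_double_ring(
            inner_count=8, outer_count=0, chl_per_subunit=5,
            layer_allocation=(3, 2), core_count=1, seed=3))
        res = assign_rings(model, membrane_frame(model))
        assert res.single_ring and len(res.inner) == 8 and res.outer == []

    def test_invariant_to_subunit_order_and_rigid_motion(self, small_spec):
        model, _ = generate_complex(small_spec)
        res = assign_rings(model, membrane_frame(model))
        shuffled, _ = generate_complex(small_spec)
        shuffled.subunits = list(reversed(shuffled.subunits))
        res2 = assign_rings(shuffled, membrane_frame(shuffled))
        assert (res.inner, res.outer) == (res2.inner, res2.outer)
        moved = perturb_complex(model, rotation_deg=33, axis=(3, 1, 2),
                                translation=(5, 5, -11))
        res3 = assign_rings(moved, membrane_frame(moved))
        assert (res.inner, res.outer) == (res3.inner, res3.outer)


class TestInterfacialPairs:
    def _two_chl_model(self, distance):
        a, b = SubunitRecord("A", role=ISIA), SubunitRecord("B", role=ISIA)
        a.ring, a.ring_index = Ring.INNER, 1
        b.ring, b.ring_index = Ring.OUTER, 1
        return ComplexModel(name="pair", subunits=[a, b], pigments=[
            make_chlorophyll(a, 501, (0, 0, 0)),
            make_chlorophyll(b, 501, (distance, 0, 0))])

    @pytest.mark.parametrize("distance,expected", [
        (22.9, 1), (23.0, 1), (23.1, 0)])
    def test_cutoff_boundary_inclusive(self, distance, expected):
        pairs = interfacial_pairs(self._two_chl_model(distance))
        assert len(pairs) == expected
        if pairs:
            assert pairs[0].category is PairCategory.INNER_OUTER
            assert not pairs[0].highlight  # 22.9 >= 18

    def test_highlight_is_strict(self):
        pairs = interfacial_pairs(self._two_chl_model(17.9))
        assert pairs[0].highlight
        pairs = interfacial_pairs(self._two_chl_model(18.0))
        assert not pairs[0].highlight

    def test_same_subunit_excluded(self):
        sub = SubunitRecord("A", role=ISIA)
        model = ComplexModel(name="intra", subunits=[sub], pigments=[
            make_chlorophyll(sub, 501, (0, 0, 0)),
            make_chlorophyll(sub, 502, (10, 0, 0))])
        assert interfacial_pairs(model) == []

    def test_matches_ground_truth_brute_force(self, trimer):
        model, truth, _ = trimer
        for cutoff in (16.0, 23.0):
            got = {(p.pigment_a, p.pigment_b) for p in interfacial_pairs(
                model, GeometryThresholds(pair_cutoff=cutoff,
                                          highlight_cutoff=min(18.0, cutoff)))}
            assert got == truth.interfacial_pairs(cutoff)

    def test_matches_brute_force_on_random_clouds(self):
        """k-d-tree pair search equals O(N^2) filtering on random fixtures."""
        rng = np.random.default_rng(2024)
        for trial in range(8):
            model = random_chlorophyll_model(rng, n=60)
            cutoff = float(rng.uniform(8, 25))
            got = {(p.pigment_a, p.pigment_b) for p in interfacial_pairs(
                model, GeometryThresholds(pair_cutoff=cutoff,
                                          highlight_cutoff=cutoff / 2))}
            expect = set()
            chls = model.chlorophylls()
            for i in range(len(chls)):
                for j in range(i + 1, len(chls)):
                    if chls[i].subunit is chls[j].subunit:
                        continue
                    if np.linalg.norm(chls[i].mg - chls[j].mg) <= cutoff:
                        expect.add(tuple(sorted((chls[i].pigment_id,
                                                 chls[j].pigment_id))))
            assert got == expect
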