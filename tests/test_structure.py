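import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jetcool import structure as S
from jetcool.structure import DihedralSet, Geometry, StructuralType
from jetcool.synthetic import build_dipeptide_geometry


class TestDihedral:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            # planar cis / trans by symmetry, +90 by hand evaluation
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, -1)], -90.0),
        ],
    )
    def test_reference_values(self, pts, expected):
        assert S.dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(S.GeometryError):
            S.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.floats(-179.99, 180))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_any_angle(self, angle):
        """Placing a point at a requested torsion and re-measuring recovers it."""
        a, b, c = np.array([0.0, 1.0, -1.0]), np.zeros(3), np.array([1.0, 0.0, 0.0])
        from jetcool.synthetic import _nerf

        d = _nerf(a, b, c, 1.5, 109.5, angle)
        assert S.dihedral(a, b, c, d) == pytest.approx(angle, abs=1e-9)


class TestSwing:
    @pytest.mark.parametrize(
        "chi1, cls",
        [(175, "g+"), (58, "g−"), (-60, "a"), (180, "g+"), (120, "g+"), (0, "g−"), (-100, "a")],
    )
    def test_classes(self, chi1, cls):
        assert S.classify_swing(chi1) == cls

    def test_tie_prefers_g_plus(self):
        # +120 is equidistant from +180 and +60
        assert S.classify_swing(120.0) == "g+"

    def test_reflection_swaps_gauche_classes(self):
        # mirror image negates chi1: g- (+60) <-> a (-60), g+ maps to itself
        assert S.classify_swing(-58) == "a"
        assert S.classify_swing(58) == "g−"
        assert S.classify_swing(-175) == "g+"


class TestBackbone:
    @pytest.mark.parametrize(
        "phi, psi, bb, fold",
        [
            (-84, 68, "γ_L", "F"),
            (84, -68, "γ_D", "F"),
            (170, -175, "β", "E"),  # periodic wrap onto the beta centre
            (80, -150, "ε_D", "E"),
            (-75, 160, "ε_L", "E"),
            (60, 45, "α_L", "E"),
        ],
    )
    def test_centres_and_wrap(self, phi, psi, bb, fold):
        assert S.classify_backbone(phi, psi) == (bb, fold)

    @given(st.floats(-180, 180), st.floats(-180, 180))
    @settings(max_examples=100, deadline=None)
    def test_mirror_symmetry(self, phi, psi):
        """Negating both torsions maps D<->L partners (beta is self-mirror).

        alpha_L has no alpha_D partner in the class set, so points whose
        nearest centre is alpha_L on either side are outside the property.
        """
        from hypothesis import assume

        dists = sorted(
            math.hypot(
                S.circular_difference(phi, pc), S.circular_difference(psi, sc)
            )
            for pc, sc in S.BACKBONE_CENTERS.values()
        )
        assume(dists[1] - dists[0] > 1e-6)  # off the class boundary
        bb, fold = S.classify_backbone(phi, psi)
        mbb, mfold = S.classify_backbone(-phi, -psi)
        if "α_L" in (bb, mbb):
            return
        partner = {"γ_L": "γ_D", "γ_D": "γ_L", "ε_L": "ε_D", "ε_D": "ε_L", "β": "β"}
        assert mbb == partner[bb]
        assert mfold == fold


class TestHBonds:
    def _oh_probe(self, acceptor_distance):
        """Methanol O-H pointing at a formaldehyde carbonyl O."""
        return Geometry(
            "probe",
            ["O", "H", "C", "O", "C", "H", "H"],
            [
                [0.0, 0.0, 0.0],  # donor O
                [0.96, 0.0, 0.0],  # H, pointing +x
                [-0.7, -1.2, 0.0],  # methyl C on donor O
                [0.96 + acceptor_distance, 0.0, 0.0],  # acceptor carbonyl O
                [0.96 + acceptor_distance + 1.22, 0.0, 0.0],
                [0.96 + acceptor_distance + 1.9, 0.9, 0.0],
                [0.96 + acceptor_distance + 1.9, -0.9, 0.0],
            ],
        )

    def test_cutoff_is_inclusive(self):
        bonds = S.detect_hbonds(self._oh_probe(2.79))
        assert len(bonds) == 1 and bonds[0].distance == pytest.approx(2.79)
        assert S.detect_hbonds(self._oh_probe(2.81)) == []

    def test_monotone_in_cutoff(self, folded_yg, extended_pi_yg):
        for geom, roles in (folded_yg, extended_pi_yg):
            previous: set[str] = set()
            for cutoff in (2.0, 2.4, 2.8, 3.2):
                labels = {f"{b.label}@{b.hydrogen}" for b in S.detect_hbonds(geom, cutoff, roles)}
                assert previous <= labels
                previous = labels

    def test_folded_gamma_turn_pattern(self, folded_yg):
        """gamma_D fold shows the amino->peptide and carboxyl->carbonyl bonds."""
        geom, roles = folded_yg
        labels = {b.label for b in S.detect_hbonds(geom, roles=roles)}
        assert labels == {"N_PB_H···N_1", "O_T_H···OC_PB"}

    def test_pi_acceptor_from_gauche_side_chain(self, extended_pi_yg):
        geom, roles = extended_pi_yg
        bonds = S.detect_hbonds(geom, roles=roles)
        labels = {b.label for b in bonds}
        assert labels == {"N_PB_H···N_1", "N_1_H···π"}
        pi = next(b for b in bonds if b.label.endswith("π"))
        assert pi.acceptor_atom is None and pi.distance <= 2.8

    def test_no_polar_hydrogen_gives_empty_list(self):
        geom = Geometry("methane", ["C", "H", "H", "H", "H"],
                        [[0, 0, 0], [1.1, 0, 0], [-1.1, 0, 0], [0, 1.1, 0], [0, -1.1, 0]])
        assert S.detect_hbonds(geom) == []


class TestTerminus:
    def test_b_terminus(self):
        assert S.classify_terminus({"N_1_H···OC_PB", "O_T_H···OC_PB"}, 30.0) == "B"

    def test_a_family_by_swing_sign(self):
        assert S.classify_terminus({"N_PB_H···N_1"}, 35.0) == "A1"
        assert S.classify_terminus({"N_PB_H···N_1"}, -35.0) == "A2"

    def test_untyped_without_diagnostic_bonds(self):
        assert S.classify_terminus(set(), 10.0) == "U"


class TestStructuralType:
    @pytest.mark.parametrize(
        "label",
        ["A1-γ_D(F)-g+/+", "A2-β(E)-g−/+", "B-γ_L(F)-a/−", "A1-ε_D(E)-g+/−", "A2-α_L(E)-g−/−"],
    )
    def test_label_round_trip(self, label):
        st_ = StructuralType.from_label(label)
        assert st_.label == label
        assert StructuralType.from_label(st_.label) == st_

    def test_fold_consistency_enforced(self):
        with pytest.raises(S.TypingError):
            StructuralType.from_label("A1-γ_D(E)-g+/+")
        with pytest.raises(S.TypingError):
            StructuralType.from_label("A1-β(F)-g+/+")

    def test_ascii_minus_accepted(self):
        st_ = StructuralType.from_label("A2-β(E)-g-/-")
        assert st_.swing == "g−" and st_.orientation == "−"
        assert st_.side_chain == "g−/−"


class TestTypeLabel:
    def test_folded_yg1_like(self, folded_yg):
        geom, _ = folded_yg
        assert S.type_label(geom).label == "A1-γ_D(F)-g+/+"

    def test_extended_yg26_like(self, extended_pi_yg):
        geom, _ = extended_pi_yg
        assert S.type_label(geom).label == "A2-ε_D(E)-g−/+"

    def test_b_terminus_yg6_like(self, b_terminus_yg):
        geom, _ = b_terminus_yg
        assert S.type_label(geom).label == "B-γ_L(F)-a/−"

    def test_extended_beta_types(self, build_geometry):
        yg14_like = build_geometry(
            DihedralSet(phi2=-180, psi2=180, chi1=175, orient_dihedral=5,
                        amino_swing=35, psi1=0, carboxyl=180)
        )
        assert S.type_label(yg14_like).label == "A1-β(E)-g+/+"
        yg31_like = build_geometry(
            DihedralSet(phi2=-180, psi2=180, chi1=58, orient_dihedral=5,
                        amino_swing=-35, psi1=0, chi2=90, carboxyl=180)
        )
        assert S.type_label(yg31_like).label == "A2-β(E)-g−/+"

    def test_mirror_image_flips_backbone_chirality(self, folded_yg):
        geom, _ = folded_yg
        mirrored = Geometry(geom.label + "_mirror", geom.symbols, geom.coords * [1, 1, -1])
        st_ = S.type_label(mirrored)
        assert st_.backbone == "γ_L"  # gamma_D fixture reflects onto gamma_L
        assert st_.fold == "F"

    def test_rigid_motion_invariance(self, extended_pi_yg):
        geom, _ = extended_pi_yg
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = Geometry(geom.label, geom.symbols, geom.coords @ rot.T + [3.0, -2.0, 11.0])
        assert S.type_label(moved) == S.type_label(geom)
        hb0 = sorted(b.label for b in S.detect_hbonds(geom))
        hb1 = sorted(b.label for b in S.detect_hbonds(moved))
        assert hb0 == hb1
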