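"""Interface geometry, SASA and conservation statistics."""

import math

import numpy as np
import pytest

from essint.constants import vdw_radii
from essint.interface import (
    InterfaceConfig,
    analyze_interface,
    buried_interface_area,
    conservation_contrast,
    find_contact_residues,
    find_interface_residues,
    find_surface_residues,
    residue_type_network,
    shrake_rupley_sasa,
)
from essint.structio import Atom, Chain, Residue, StructureModel
from essint import synthetic as syn
from oracles import (
    bruteforce_contacts,
    exact_ranksum_onesided,
    monte_carlo_sasa,
    random_rotation,
)


def single_atom_model(*atom_specs):
    """One-chain model; atom_specs = (name, element, xyz) per residue."""
    residues = [
        Residue("ALA", i + 1, [Atom(name, element, np.asarray(xyz, float))])
        for i, (name, element, xyz) in enumerate(atom_specs)
    ]
    return StructureModel("atoms", [Chain("A", residues)])


class TestContactsAndInterface:
    def test_far_chains_empty(self, two_far_chains):
        assert find_contact_residues(two_far_chains) == set()
        assert find_interface_residues(two_far_chains) == set()

    def test_contact_cutoff_inclusive(self, cb_pair_factory):
        model = cb_pair_factory(4.4)
        pairs = find_contact_residues(model)
        assert pairs == {(("A", 1), ("B", 1))}

    def test_interface_but_not_contact_at_9p8(self, cb_pair_factory):
        model = cb_pair_factory(9.8)
        assert find_contact_residues(model) == set()
        assert find_interface_residues(model) == {("A", 1), ("B", 1)}

    def test_excluded_beyond_interface_cutoff(self, cb_pair_factory):
        assert find_interface_residues(cb_pair_factory(12.0)) == set()

    def test_matches_bruteforce(self, native):
        cfg = InterfaceConfig()
        assert find_contact_residues(native, cfg) == bruteforce_contacts(
            native, cfg.contact_cutoff
        )

    def test_contact_subset_of_interface(self, native):
        cfg = InterfaceConfig()
        contact_res = {r for pair in find_contact_residues(native, cfg) for r in pair}
        assert contact_res <= find_interface_residues(native, cfg)

    def test_rigid_invariance(self, native):
        rng = np.random.default_rng(3)
        moved = native.transformed(random_rotation(rng), rng.normal(size=3))
        def as_sets(m):
            return (find_contact_residues(m), find_interface_residues(m))
        assert as_sets(moved) == as_sets(native)


class TestSasa:
    def test_isolated_carbon_analytic_sphere(self):
        model = single_atom_model(("C", "C", (0, 0, 0)))
        area = sum(shrake_rupley_sasa(model).values())
        r = vdw_radii()["C"] + 1.4
        assert area == pytest.approx(4 * math.pi * r**2, rel=1e-6)

    def test_distant_atoms_additive(self):
        model = single_atom_model(("C", "C", (0, 0, 0)), ("O", "O", (100, 0, 0)))
        per_atom = shrake_rupley_sasa(model)
        rc, ro = vdw_radii()["C"] + 1.4, vdw_radii()["O"] + 1.4
        assert sum(per_atom.values()) == pytest.approx(
            4 * math.pi * (rc**2 + ro**2), rel=1e-6
        )

    def test_overlapping_pair_vs_monte_carlo(self):
        coords = [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0)]
        model = single_atom_model(("C", "C", coords[0]), ("N", "N", coords[1]))
        per_atom = shrake_rupley_sasa(model, sphere_points=960)
        radii = [vdw_radii()["C"], vdw_radii()["N"]]
        oracle = monte_carlo_sasa(coords, radii, 1.4, n_points=200_000, seed=0)
        got = [per_atom[("A", 1, "C")], per_atom[("A", 2, "N")]]
        assert got == pytest.approx(list(oracle), rel=0.01)

    def test_quadrature_convergence_small_fixture(self):
        """Doubling the point count moves per-atom areas by < 0.5%."""
        model = single_atom_model(
            ("C", "C", (0.0, 0.0, 0.0)), ("N", "N", (2.0, 0.0, 0.0)),
        )
        a = shrake_rupley_sasa(model, sphere_points=960)
        b = shrake_rupley_sasa(model, sphere_points=1920)
        for key, val in a.items():
            assert abs(val - b[key]) / val < 0.005

    def test_quadrature_convergence_total(self, native):
        """On a full model the summed SASA is converged at 960 points."""
        a = sum(shrake_rupley_sasa(native, sphere_points=960).values())
        b = sum(shrake_rupley_sasa(native, sphere_points=1920).values())
        assert abs(a - b) / a < 0.005

    def test_unknown_element_uses_default(self, caplog):
        model = single_atom_model(("X1", "XX", (0, 0, 0)))
        with caplog.at_level("WARNING"):
            area = sum(shrake_rupley_sasa(model).values())
        r = vdw_radii()["default"] + 1.4
        assert area == pytest.approx(4 * math.pi * r**2, rel=1e-6)
        assert "default radius" in caplog.text


class TestBuriedArea:
    def test_far_apart_zero(self, two_far_chains):
        assert buried_interface_area(two_far_chains) == pytest.approx(0.0, abs=0.5)

    def test_docked_dimer_positive(self, native):
        assert buried_interface_area(native) > 50.0

    def test_decreases_when_pulled_apart(self):
        near, _ = syn.synth_dimer(syn.SimConfig(seed=1, interface_separation=10.0))
        far, _ = syn.synth_dimer(syn.SimConfig(seed=1, interface_separation=12.0))
        assert buried_interface_area(far) < buried_interface_area(near)

    def test_rigid_invariance_to_quadrature_tolerance(self, native):
        # the sphere point lattice is fixed in space, so SASA-derived areas
        # are rotation-invariant only up to quadrature resolution
        rng = np.random.default_rng(9)
        moved = native.transformed(random_rotation(rng), rng.normal(size=3))
        assert buried_interface_area(moved) == pytest.approx(
            buried_interface_area(native), rel=0.01
        )


class TestSurfaceResidues:
    def test_matches_per_atom_thresholding_oracle(self, native):
        cfg = InterfaceConfig()
        surface = find_surface_residues(native, cfg, exclude_interface=False)
        oracle = set()
        for i, chain in enumerate(native.chains):
            isolated = StructureModel("iso", [chain])
            per_atom = shrake_rupley_sasa(
                isolated, cfg.probe_radius, cfg.sphere_points
            )
            for (cid, seq, _name), area in per_atom.items():
                if area >= cfg.surface_atom_sasa_min:
                    oracle.add((cid, seq))
        assert surface == oracle

    def test_interface_excluded_from_contrast_set(self, native):
        cfg = InterfaceConfig()
        surface = find_surface_residues(native, cfg, exclude_interface=True)
        assert surface.isdisjoint(find_interface_residues(native, cfg))


class TestConservationContrast:
    def test_identical_samples_p_one(self):
        res = conservation_contrast([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_extreme_separation_vs_permutation_oracle(self):
        interface, surface = [9, 9, 9], [1, 1, 1]
        res = conservation_contrast(interface, surface)
        w_obs, p_exact = exact_ranksum_onesided(interface, surface)
        assert res.statistic == pytest.approx(w_obs)
        assert p_exact == pytest.approx(1 / 20)  # 1 of C(6,3) splits
        assert res.median_interface == 9 and res.median_surface == 1

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            conservation_contrast([5], [1, 2, 3])

    def test_shifted_track_detected(self):
        rng = np.random.default_rng(0)
        iface, surf = syn.conservation_samples(100, 100, shift=3, rng=rng)
        assert conservation_contrast(iface, surf).p_one_sided < 0.01


class TestResidueTypeNetwork:
    def make_pair(self, name_a, name_b):
        res_a = Residue(name_a, 1, [
            Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
            Atom("CG", "C", np.array([0.0, 1.5, 0.0])),
        ])
        res_b = Residue(name_b, 1, [
            Atom("CA", "C", np.array([3.0, 0.0, 0.0])),
            Atom("CD", "C", np.array([3.0, 1.5, 0.0])),
        ])
        return StructureModel("m", [Chain("A", [res_a]), Chain("B", [res_b])])

    def test_single_contact_weight_one(self):
        g = residue_type_network([self.make_pair("ARG", "GLU")])
        assert g["ARG"]["GLU"]["weight"] == 1

    def test_additivity_across_models(self):
        models = [self.make_pair("ARG", "GLU")] * 3
        g = residue_type_network(models)
        assert g["ARG"]["GLU"]["weight"] == 3

    def test_self_edge_allowed(self):
        g = residue_type_network([self.make_pair("LEU", "LEU")])
        assert g["LEU"]["LEU"]["weight"] == 1

    def test_matches_bruteforce_on_dimer(self, native):
        cfg = InterfaceConfig()
        g = residue_type_network([native], cfg)
        sidechain = bruteforce_contacts(
            native, cfg.contact_cutoff,
            atom_filter=lambda res, a: (
                a.name == "CA" if res.name == "GLY"
                else a.name not in {"N", "CA", "C", "O", "OXT"}
            ),
        )
        expected = len(sidechain)  # polyalanine: every pair is ALA-ALA
        if expected:
            assert g["ALA"]["ALA"]["weight"] == expected
        else:
            assert g.number_of_edges() == 0

    def test_backbone_contacts_ignored(self):
        # only backbone atoms close; side chains far apart
        res_a = Residue("SER", 1, [
            Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
            Atom("OG", "O", np.array([0.0, 20.0, 0.0])),
        ])
        res_b = Residue("THR", 1, [
            Atom("CA", "C", np.array([3.0, 0.0, 0.0])),
            Atom("OG1", "O", np.array([3.0, -20.0, 0.0])),
        ])
        g = residue_type_network(
            [StructureModel("m", [Chain("A", [res_a]), Chain("B", [res_b])])]
        )
        assert g.number_of_edges() == 0


def test_analyze_interface_report(native):
    track = syn.synth_conservation(native, shift=2, seed=4)
    report = analyze_interface(native, conservation=track)
    assert report.contact_residues <= report.interface_residues
    assert report.buried_area >= 0
    assert report.per_chain_delta_sasa_half == pytest.approx(report.buried_area / 2)
    assert report.conservation is not None
    assert 1 <= report.conservation.median_surface <= 9
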