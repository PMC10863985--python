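"""Model-vs-native metrics, crosslink restraints, benchmark filter."""

import datetime as dt

import numpy as np
import pytest

from essint import synthetic as syn
from essint.constants import score_constants
from essint.structio import Atom, Chain, Residue, StructureModel
from essint.validation import (
    BenchmarkEntry,
    CrosslinkRestraint,
    benchmark_filter,
    crosslink_check,
    dockq,
    fnat,
    interface_rmsd,
    kabsch_superpose,
    ligand_rmsd,
    tm_score,
    validate_model,
)
from oracles import quaternion_superpose, random_rotation


def moved_copy(model, seed):
    rng = np.random.default_rng(seed)
    return model.transformed(random_rotation(rng), rng.normal(scale=10, size=3))


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert R == pytest.approx(np.eye(3), abs=1e-9)

    def test_pure_translation(self):
        P = np.random.default_rng(1).normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(P, P + [5.0, 0.0, 0.0])
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(4 + seed, 3)) * 5
        Q = (P @ random_rotation(rng).T) + rng.normal(size=3) \
            + rng.normal(scale=0.3, size=P.shape)
        R1, t1, rmsd1 = kabsch_superpose(P, Q)
        R2, t2, rmsd2 = quaternion_superpose(P, Q)
        assert rmsd1 == pytest.approx(rmsd2, abs=1e-9)
        assert R1 == pytest.approx(R2, abs=1e-7)

    def test_proper_rotation(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(5, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]  # reflection
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_raises(self):
        P = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(P, P * 1.0 + 2.0)


class TestInterfaceRmsd:
    def test_identity_zero(self, native):
        assert interface_rmsd(native, native) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, native):
        assert interface_rmsd(moved_copy(native, 2), native) == pytest.approx(
            0.0, abs=1e-7
        )

    def test_displaced_chain_matches_direct_recomputation(self, dimer):
        native, perturbed = dimer
        got = interface_rmsd(perturbed, native, cutoff=10.0)
        # independent recomputation: enumerate native interface residues by
        # a double loop, superpose backbone with the quaternion oracle
        iface = set()
        ch_a, ch_b = native.chains
        for ra in ch_a.residues:
            for rb in ch_b.residues:
                d = min(
                    np.linalg.norm(a.xyz - b.xyz)
                    for a in ra.heavy_atoms for b in rb.heavy_atoms
                )
                if d <= 10.0:
                    iface.add(("A", ra.seq_index))
                    iface.add(("B", rb.seq_index))
        mp, nq = [], []
        for cid, seq in sorted(iface):
            rm = perturbed.chain(cid).residue(seq)
            rn = native.chain(cid).residue(seq)
            for name in ("N", "CA", "C", "O"):
                if rm.atom(name) is not None and rn.atom(name) is not None:
                    mp.append(rm.atom(name).xyz)
                    nq.append(rn.atom(name).xyz)
        _, _, expected = quaternion_superpose(np.array(mp), np.array(nq))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_no_interface_raises(self, two_far_chains):
        with pytest.raises(ValueError):
            interface_rmsd(two_far_chains, two_far_chains)


class TestFnat:
    def test_identity_one(self, native):
        assert fnat(native, native) == pytest.approx(1.0)

    def test_chains_pulled_apart_zero(self, native):
        far = native.transformed(np.eye(3), np.zeros(3))
        for res in far.chains[1].residues:
            for a in res.atoms:
                a.xyz = a.xyz + np.array([100.0, 0.0, 0.0])
        assert fnat(far, native) == 0.0

    def test_half_contacts_broken_by_design(self):
        """4 enumerated native contacts; the model breaks exactly 2."""
        za = [0.0, 10.0, 20.0, 30.0]
        native = _contact_ladder(za, contact=[True] * 4)
        model = _contact_ladder(za, contact=[True, True, False, False])
        assert fnat(model, native) == pytest.approx(0.5)

    def test_no_native_contacts_raises(self, two_far_chains):
        with pytest.raises(ValueError):
            fnat(two_far_chains, two_far_chains)


def _contact_ladder(z_positions, contact):
    """Two single-atom-residue chains; rung i is in contact (4 A) or not (50 A)."""
    res_a, res_b = [], []
    for i, z in enumerate(z_positions):
        res_a.append(Residue("ALA", i + 1,
                             [Atom("CA", "C", np.array([0.0, 0.0, z]))]))
        x = 4.0 if contact[i] else 50.0
        res_b.append(Residue("ALA", i + 1,
                             [Atom("CA", "C", np.array([x, 0.0, z]))]))
    return StructureModel("ladder", [Chain("A", res_a), Chain("B", res_b)])


class TestDockq:
    def test_identity_one(self, native):
        assert dockq(moved_copy(native, 4), native) == pytest.approx(1.0, abs=1e-6)

    def test_far_apart_low(self, native):
        far = native.transformed(np.eye(3), np.zeros(3))
        for res in far.chains[1].residues:
            for a in res.atoms:
                a.xyz = a.xyz + np.array([100.0, 0.0, 0.0])
        assert dockq(far, native) < 0.1

    def test_composition_from_component_oracles(self, dimer):
        """DockQ equals the hand-composed mean of its three terms."""
        native, perturbed = dimer
        c = score_constants()["dockq"]
        f = fnat(perturbed, native, c["fnat_cutoff"])
        irms = interface_rmsd(perturbed, native, c["interface_cutoff"])
        lrms = ligand_rmsd(perturbed, native)
        expected = (
            f + 1 / (1 + (irms / c["d1"]) ** 2) + 1 / (1 + (lrms / c["d2"]) ** 2)
        ) / 3
        assert dockq(perturbed, native) == pytest.approx(expected, abs=1e-12)


class TestTmScore:
    def test_identity_and_rigid_motion(self, native):
        assert tm_score(native, native) == pytest.approx(1.0, abs=1e-9)
        assert tm_score(moved_copy(native, 8), native) == pytest.approx(1.0, abs=1e-6)

    def test_bounded_and_monotone_under_displacement(self, native):
        scores = []
        for offset in (0.0, 2.0, 5.0, 10.0):
            cfg = syn.SimConfig(seed=7, dimer_length=20, rigid_offset=offset)
            _, moved = syn.synth_dimer(cfg)
            s = tm_score(moved, native)
            assert 0 < s <= 1
            scores.append(s)
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_matches_exhaustive_seed_search(self, dimer):
        native, perturbed = dimer
        got = tm_score(perturbed, native)
        expected = _tm_oracle(perturbed, native)
        assert got == pytest.approx(expected, abs=1e-3)


def _tm_oracle(model, native):
    """Brute-force TM-score: every fragment start at step 1, same iteration."""
    from essint.validation import _matched_coords, _map_chain, _tm_d0

    cmap = _map_chain(model, native, None)
    keys = [(c.chain_id, r.seq_index) for c in native.chains for r in c.residues]
    mp, nq = _matched_coords(model, native, keys, ("CA",), cmap)
    L = len(nq)
    d0 = _tm_d0(L)
    best = 0.0
    for fl in {L, max(L // 2, 4), max(L // 4, 4)}:
        for start in range(0, L - fl + 1):
            sel = np.arange(start, start + fl)
            try:
                R, t, _ = quaternion_superpose(mp[sel], nq[sel])
            except np.linalg.LinAlgError:
                continue
            for _ in range(50):
                d = np.linalg.norm((mp @ R.T + t) - nq, axis=1)
                new_sel = np.where(d < max(d0, 3.0))[0]
                if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                    break
                sel = new_sel
                R, t, _ = quaternion_superpose(mp[sel], nq[sel])
            d = np.linalg.norm((mp @ R.T + t) - nq, axis=1)
            best = max(best, float(np.sum(1 / (1 + (d / d0) ** 2)) / L))
    return best


class TestCrosslinks:
    def lysine_pair(self, distance):
        res_a = Residue("LYS", 10, [Atom("CA", "C", np.zeros(3))])
        res_b = Residue("LYS", 20, [Atom("CA", "C", np.array([distance, 0.0, 0.0]))])
        return StructureModel("xl", [Chain("A", [res_a]), Chain("B", [res_b])])

    def test_within_reach_satisfied(self):
        model = self.lysine_pair(18.0)
        restraint = CrosslinkRestraint(("A", 10), ("B", 20), max_distance=20.0)
        assert crosslink_check(model, [restraint]) == (1, 1)

    def test_beyond_reach_violated(self):
        model = self.lysine_pair(35.0)
        restraint = CrosslinkRestraint(("A", 10), ("B", 20))
        assert crosslink_check(model, [restraint]) == (0, 1)

    def test_empty_restraints(self):
        assert crosslink_check(self.lysine_pair(18.0), []) == (0, 0)

    def test_missing_residue_skipped(self, caplog):
        model = self.lysine_pair(18.0)
        restraints = [
            CrosslinkRestraint(("A", 10), ("B", 99)),
            CrosslinkRestraint(("A", 10), ("B", 20)),
        ]
        with caplog.at_level("WARNING"):
            assert crosslink_check(model, restraints) == (1, 1)
        assert "skipped" in caplog.text

    def test_non_lysine_raises(self):
        model = self.lysine_pair(18.0)
        model.chains[0].residues[0].name = "ARG"
        with pytest.raises(ValueError):
            crosslink_check(model, [CrosslinkRestraint(("A", 10), ("B", 20))])


class TestBenchmarkFilter:
    def entry(self, **kw):
        base = dict(
            pdb_id="1abc", release_date=dt.date(2022, 6, 1), method="xray",
            resolution=1.8, n_distinct_chains=2, cluster_representative=True,
            max_identity_to_training=0.25,
        )
        base.update(kw)
        return BenchmarkEntry(**base)

    def test_boundary_resolution_kept(self):
        assert benchmark_filter([self.entry(resolution=2.0)]) != []

    def test_identity_boundary_dropped(self):
        assert benchmark_filter([self.entry(max_identity_to_training=0.30)]) == []

    def test_non_representative_dropped(self):
        assert benchmark_filter([self.entry(cluster_representative=False)]) == []

    def test_old_release_dropped(self):
        assert benchmark_filter([self.entry(release_date=dt.date(2021, 9, 30))]) == []

    def test_method_and_chain_count(self):
        assert benchmark_filter([self.entry(method="nmr")]) == []
        assert benchmark_filter([self.entry(n_distinct_chains=3)]) == []

    def test_order_invariant_and_idempotent(self):
        entries = [
            self.entry(pdb_id="2xyz"),
            self.entry(pdb_id="1abc", resolution=2.5),
            self.entry(pdb_id="3foo"),
        ]
        out = benchmark_filter(entries)
        assert out == benchmark_filter(entries[::-1]) == benchmark_filter(out)
        assert [e.pdb_id for e in out] == ["2xyz", "3foo"]


def test_validate_model_panel(dimer):
    native, perturbed = dimer
    report = validate_model(perturbed, native)
    assert 0 < report.tm_score <= 1
    assert report.i_rmsd > 0
    assert 0 <= report.fnat <= 1
    assert 0 <= report.dockq <= 1
    assert report.crosslink_fraction is None
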