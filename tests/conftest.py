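import numpy as np
import pytest

from essint import synthetic as syn
from essint.structio import Atom, Chain, Residue, StructureModel


@pytest.fixture(scope="session")
def dimer():
    """Native/perturbed helix dimer pair (2 A rigid offset on chain B)."""
    cfg = syn.SimConfig(seed=7, dimer_length=20, rigid_offset=2.0)
    return syn.synth_dimer(cfg)


@pytest.fixture(scope="session")
def native(dimer):
    return dimer[0]


@pytest.fixture(scope="session")
def scored_dimer(native):
    """Native dimer with high-quality surrogate pLDDT/PAE/ipTM."""
    return syn.synth_confidence(native, "high", seed=11)


def ca_cb_residue(name, seq_index, ca_xyz, cb_offset=(0.0, 1.5, 0.0), b=80.0):
    ca = np.asarray(ca_xyz, float)
    return Residue(name, seq_index, [
        Atom("CA", "C", ca, b),
        Atom("CB", "C", ca + np.asarray(cb_offset, float), b),
    ])


@pytest.fixture
def two_far_chains():
    """Two single-residue chains 100 A apart (no contacts at any cutoff used)."""
    return StructureModel("far", [
        Chain("A", [ca_cb_residue("ALA", 1, (0.0, 0.0, 0.0))]),
        Chain("B", [ca_cb_residue("ALA", 1, (100.0, 0.0, 0.0))]),
    ])


@pytest.fixture
def cb_pair_factory():
    """Model with exactly one interchain Cbeta pair at a chosen distance."""
    def make(distance):
        return StructureModel("pair", [
            Chain("A", [ca_cb_residue("ALA", 1, (0.0, -1.5, 0.0))]),
            Chain("B", [ca_cb_residue("ALA", 1, (distance, -1.5, 0.0))]),
        ])
    return make


def point_residue(name, seq_index, xyz, atom_name="CA", element="C", b=50.0):
    return Residue(name, seq_index,
                   [Atom(atom_name, element, np.asarray(xyz, float), b)])


def two_chain_points(coords_a, coords_b, names=("ALA", "ALA")):
    """Minimal two-chain model of single-atom residues at given coords."""
    chain_a = Chain("A", [point_residue(names[0], i + 1, c)
                          for i, c in enumerate(coords_a)])
    chain_b = Chain("B", [point_residue(names[1], i + 1, c)
                          for i, c in enumerate(coords_b)])
    return StructureModel("points", [chain_a, chain_b])
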