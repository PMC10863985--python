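"""Model-vs-native validation metrics and restraint checks.

Implements the standard complex-quality stack: optimal rigid superposition
(Kabsch), interface RMSD over native-defined interface residues, fraction
of native contacts (Fnat), ligand RMSD after receptor superposition, their
DockQ combination, and the length-normalized TM-score with iterative
superposition refinement.  Also: lysine-lysine crosslink restraint
checking (Calpha-Calpha distance against the crosslinker reach) and the
metadata filter used to assemble an unbiased benchmark of experimentally
solved heterodimers.

Residue correspondence between model and native is fixed by chain mapping
plus author sequence index — the models share their sequences with the
reference structures, so no alignment search is performed.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import score_constants
from .structio import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "BenchmarkEntry",
    "CrosslinkRestraint",
    "kabsch_superpose",
    "interface_rmsd",
    "fnat",
    "ligand_rmsd",
    "dockq",
    "tm_score",
    "crosslink_check",
    "benchmark_filter",
    "validate_model",
]

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class ValidationReport:
    tm_score: float
    i_rmsd: float
    l_rmsd: float
    fnat: float
    dockq: float
    crosslink_satisfied: int = 0
    crosslink_total: int = 0

    @property
    def crosslink_fraction(self) -> float | None:
        if self.crosslink_total == 0:
            return None
        return self.crosslink_satisfied / self.crosslink_total


@dataclass(frozen=True)
class BenchmarkEntry:
    pdb_id: str
    release_date: _dt.date
    method: str  # xray | cryoem | other
    resolution: float
    n_distinct_chains: int
    cluster_representative: bool
    max_identity_to_training: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass(frozen=True)
class CrosslinkRestraint:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    max_distance: float = 20.0  # A; crosslinked lysines sit ~15-20 A apart


# ---------------------------------------------------------------------------
# rigid superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition of P onto Q.

    Returns ``(rotation, translation, rmsd)`` with ``R @ p + t ~= q`` and a
    proper rotation (reflections corrected).  Collinear/degenerate point
    sets raise ``ValueError``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matched (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 => points collinear: rotation about the line is undetermined
    if S[1] <= 1e-8 * max(S[0], 1.0):
        raise ValueError("collinear point set: superposition is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# correspondence helpers
# ---------------------------------------------------------------------------

def _map_chain(model: StructureModel, native: StructureModel,
               chain_map: Mapping[str, str] | None) -> dict[str, str]:
    """model chain id -> native chain id (by identity unless given)."""
    if chain_map is not None:
        return dict(chain_map)
    model_ids = [c.chain_id for c in model.chains]
    native_ids = [c.chain_id for c in native.chains]
    if set(model_ids) == set(native_ids):
        return {c: c for c in model_ids}
    if len(model_ids) == len(native_ids):
        logger.info("chain ids differ; mapping by order: %s",
                    dict(zip(model_ids, native_ids)))
        return dict(zip(model_ids, native_ids))
    raise ValueError("cannot establish chain correspondence; pass chain_map")


def _matched_coords(
    model: StructureModel,
    native: StructureModel,
    residues: Sequence[tuple[str, int]],
    atom_names: Sequence[str],
    chain_map: Mapping[str, str],
):
    """Matched coordinate arrays over native residue keys, model first."""
    inv = {v: k for k, v in chain_map.items()}
    mp, nq = [], []
    for cid_native, seq_index in residues:
        res_n = native.chain(cid_native).residue(seq_index)
        chain_m = inv.get(cid_native)
        res_m = None if chain_m is None else model.chain(chain_m).residue(seq_index)
        if res_n is None or res_m is None:
            continue
        for name in atom_names:
            an, am = res_n.atom(name), res_m.atom(name)
            if an is not None and am is not None:
                nq.append(an.xyz)
                mp.append(am.xyz)
    return np.asarray(mp, dtype=float), np.asarray(nq, dtype=float)


def _interchain_residue_contacts(
    model: StructureModel, cutoff: float
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    if len(model.chains) != 2:
        raise ValueError("need a two-chain model")
    sides = []
    for chain in model.chains:
        coords, keys = [], []
        for res in chain.residues:
            for a in res.heavy_atoms:
                coords.append(a.xyz)
                keys.append((chain.chain_id, res.seq_index))
        sides.append((np.asarray(coords, dtype=float), keys))
    (xa, ka), (xb, kb) = sides
    if len(xa) == 0 or len(xb) == 0:
        return set()
    hits = cKDTree(xa).query_ball_tree(cKDTree(xb), r=cutoff)
    return {(ka[i], kb[j]) for i, js in enumerate(hits) for j in js}


def _native_interface_residues(
    native: StructureModel, cutoff: float
) -> list[tuple[str, int]]:
    pairs = _interchain_residue_contacts(native, cutoff)
    return sorted({r for pair in pairs for r in pair})


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def interface_rmsd(
    model: StructureModel,
    native: StructureModel,
    cutoff: float = 10.0,
    chain_map: Mapping[str, str] | None = None,
    atoms: Sequence[str] = BACKBONE,
) -> float:
    """Backbone RMSD over the native interface after superposing on it.

    Interface residues are those of the *native* with any heavy atom
    within ``cutoff`` of the partner chain.
    """
    cmap = _map_chain(model, native, chain_map)
    residues = _native_interface_residues(native, cutoff)
    if not residues:
        raise ValueError("native has no interface residues at this cutoff")
    mp, nq = _matched_coords(model, native, residues, atoms, cmap)
    if len(mp) < 3:
        raise ValueError("fewer than 3 matched interface atoms")
    _, _, rmsd = kabsch_superpose(mp, nq)
    return rmsd


def fnat(
    model: StructureModel,
    native: StructureModel,
    contact_cutoff: float = 5.0,
    chain_map: Mapping[str, str] | None = None,
) -> float:
    """Fraction of native interchain residue contacts preserved in the model."""
    cmap = _map_chain(model, native, chain_map)
    native_contacts = _interchain_residue_contacts(native, contact_cutoff)
    if not native_contacts:
        raise ValueError("native has no interchain contacts at this cutoff")
    model_contacts = _interchain_residue_contacts(model, contact_cutoff)
    # express model contacts in native chain labels; orientation-free pairs
    model_in_native = {
        frozenset(((cmap[a[0]], a[1]), (cmap[b[0]], b[1])))
        for a, b in model_contacts
    }
    native_canon = {frozenset(c) for c in native_contacts}
    preserved = sum(1 for c in native_canon if c in model_in_native)
    return preserved / len(native_canon)


def ligand_rmsd(
    model: StructureModel,
    native: StructureModel,
    chain_map: Mapping[str, str] | None = None,
    atoms: Sequence[str] = BACKBONE,
) -> float:
    """Ligand backbone RMSD after superposing on the receptor.

    Receptor = the longer native chain (first on ties, the DockQ
    convention).
    """
    cmap = _map_chain(model, native, chain_map)
    if len(native.chains) != 2:
        raise ValueError("ligand_rmsd needs two-chain structures")
    lengths = [len(c) for c in native.chains]
    receptor_idx = 0 if lengths[0] >= lengths[1] else 1
    receptor = native.chains[receptor_idx].chain_id
    ligand = native.chains[1 - receptor_idx].chain_id
    rec_keys = [(receptor, r.seq_index) for r in native.chain(receptor).residues]
    lig_keys = [(ligand, r.seq_index) for r in native.chain(ligand).residues]
    mp_rec, nq_rec = _matched_coords(model, native, rec_keys, atoms, cmap)
    if len(mp_rec) < 3:
        raise ValueError("too few matched receptor atoms")
    R, t, _ = kabsch_superpose(mp_rec, nq_rec)
    mp_lig, nq_lig = _matched_coords(model, native, lig_keys, atoms, cmap)
    if len(mp_lig) == 0:
        raise ValueError("no matched ligand atoms")
    diff = (mp_lig @ R.T + t) - nq_lig
    return float(np.sqrt((diff**2).sum() / len(mp_lig)))


def dockq(
    model: StructureModel,
    native: StructureModel,
    chain_map: Mapping[str, str] | None = None,
) -> float:
    """DockQ = mean of Fnat and the scaled i-RMSD / L-RMSD terms.

    ``DockQ = (Fnat + 1/(1+(iRMS/d1)^2) + 1/(1+(LRMS/d2)^2)) / 3`` with the
    published scaling constants held in the package config.
    """
    consts = score_constants()["dockq"]
    f = fnat(model, native, consts["fnat_cutoff"], chain_map)
    irms = interface_rmsd(model, native, consts["interface_cutoff"], chain_map)
    lrms = ligand_rmsd(model, native, chain_map)
    term_i = 1.0 / (1.0 + (irms / consts["d1"]) ** 2)
    term_l = 1.0 / (1.0 + (lrms / consts["d2"]) ** 2)
    return (f + term_i + term_l) / 3.0


def _tm_d0(n: int) -> float:
    c = score_constants()["tm_score"]
    if n <= c["d0_shift"]:
        return c["d0_min"]
    d0 = c["d0_coeff"] * (n - c["d0_shift"]) ** (1.0 / 3.0) - c["d0_offset"]
    return max(d0, c["d0_min"])


def tm_score(
    model: StructureModel,
    native: StructureModel,
    chain_map: Mapping[str, str] | None = None,
) -> float:
    """TM-score of the complex over concatenated Calpha traces.

    Correspondence is fixed by chain mapping + sequence index; the score
    is maximized over superpositions seeded from sliding fragments and
    refined by iterating on the close-residue subset (d < d0), the
    standard TM-score search.  d0 is computed from the native length.
    """
    cmap = _map_chain(model, native, chain_map)
    keys = [
        (c.chain_id, r.seq_index)
        for c in native.chains
        for r in c.residues
    ]
    mp, nq = _matched_coords(model, native, keys, ("CA",), cmap)
    L = len(nq)
    if L < 3:
        raise ValueError("need at least 3 matched Calpha atoms")
    d0 = _tm_d0(L)

    def score_for(R, t) -> float:
        d = np.linalg.norm((mp @ R.T + t) - nq, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)

    best = 0.0
    frag_lengths = sorted({L, max(L // 2, 4), max(L // 4, 4)}, reverse=True)
    for fl in frag_lengths:
        step = max(fl // 2, 1)
        for start in range(0, L - fl + 1, step):
            sel = np.arange(start, start + fl)
            try:
                R, t, _ = kabsch_superpose(mp[sel], nq[sel])
            except ValueError:
                continue
            for _ in range(20):
                d = np.linalg.norm((mp @ R.T + t) - nq, axis=1)
                new_sel = np.where(d < max(d0, 3.0))[0]
                if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                    break
                sel = new_sel
                try:
                    R, t, _ = kabsch_superpose(mp[sel], nq[sel])
                except ValueError:
                    break
            best = max(best, score_for(R, t))
    return best


def crosslink_check(
    model: StructureModel,
    restraints: Sequence[CrosslinkRestraint],
) -> tuple[int, int]:
    """Count crosslink restraints satisfied by the model.

    A restraint is satisfied when the Calpha-Calpha distance between the
    two crosslinked lysines is within the crosslinker reach.  Restraints
    whose residues are missing from the model are skipped and reported;
    non-lysine residues raise ``ValueError``.
    """
    satisfied = total = 0
    for r in restraints:
        residues = []
        missing = False
        for cid, seq_index in (r.residue_a, r.residue_b):
            try:
                res = model.chain(cid).residue(seq_index)
            except KeyError:
                res = None
            if res is None or res.atom("CA") is None:
                logger.warning("crosslink residue %s:%d missing; restraint skipped",
                               cid, seq_index)
                missing = True
                break
            if res.name != "LYS":
                raise ValueError(
                    f"crosslink restraint touches non-lysine {res.name} "
                    f"at {cid}:{seq_index}"
                )
            residues.append(res)
        if missing:
            continue
        total += 1
        d = float(np.linalg.norm(residues[0].atom("CA").xyz
                                 - residues[1].atom("CA").xyz))
        if d <= r.max_distance:
            satisfied += 1
    return satisfied, total


def benchmark_filter(
    entries: Sequence[BenchmarkEntry],
    date_cutoff: _dt.date = _dt.date(2021, 9, 30),
    resolution_max: float = 2.0,
    identity_max: float = 0.30,
) -> list[BenchmarkEntry]:
    """Unbiased-benchmark metadata filter.

    Keeps heterodimers released after the predictor's training cutoff,
    solved by X-ray or cryo-EM at ``resolution_max`` or better, cluster
    representatives only, with sequence identity to the training set
    strictly below ``identity_max``.  Order-invariant and idempotent.
    """
    kept = [
        e for e in entries
        if e.release_date > date_cutoff
        and e.method in {"xray", "cryoem"}
        and e.resolution <= resolution_max
        and e.n_distinct_chains == 2
        and e.cluster_representative
        and e.max_identity_to_training < identity_max
    ]
    return sorted(kept, key=lambda e: e.pdb_id)


def validate_model(
    model: StructureModel,
    native: StructureModel,
    chain_map: Mapping[str, str] | None = None,
    restraints: Sequence[CrosslinkRestraint] = (),
) -> ValidationReport:
    """Full validation panel of a predicted complex against its reference."""
    consts = score_constants()["dockq"]
    sat, tot = crosslink_check(model, restraints) if restraints else (0, 0)
    return ValidationReport(
        tm_score=tm_score(model, native, chain_map),
        i_rmsd=interface_rmsd(model, native, consts["interface_cutoff"], chain_map),
        l_rmsd=ligand_rmsd(model, native, chain_map),
        fnat=fnat(model, native, consts["fnat_cutoff"], chain_map),
        dockq=dockq(model, native, chain_map),
        crosslink_satisfied=sat,
        crosslink_total=tot,
    )
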