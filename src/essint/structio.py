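"""Structure and confidence-artifact I/O.

Predicted binary complexes arrive as PDB or mmCIF files whose B-factor
column carries per-residue pLDDT (the AlphaFold convention), accompanied
by a ranking JSON (ipTM per model) and a PAE JSON (residue-pair predicted
aligned error, Angstrom).  This module parses those artifacts into light
in-memory containers and selects the representative model of a prediction
job (best ipTM, lexicographic tie-break).

Parsing of the coordinate formats is delegated to :mod:`gemmi`; the
containers here keep only what the downstream geometry needs: chains,
author-numbered residues, heavy/all atoms with coordinates and B-factors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ConfidenceBundle",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "read_ranking",
    "read_pae",
    "select_best_model",
]


class StructureParseError(ValueError):
    """Raised when a coordinate or confidence file cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom
    bfactor: float = 0.0
    occupancy: float = 1.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    name: str  # 3-letter code
    seq_index: int  # author numbering
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def plddt(self) -> float | None:
        """Per-residue pLDDT, read from the B-factor of the Calpha atom."""
        ca = self.atom("CA")
        return None if ca is None else ca.bfactor


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_index: int) -> Residue | None:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        return None


@dataclass
class StructureModel:
    """A (possibly multi-chain) atomic model; two chains for binary complexes."""

    model_id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            return
        for ch in self.chains:
            idx = [r.seq_index for r in ch.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureParseError(
                    f"chain {ch.chain_id}: seq_index not strictly increasing"
                )

    @property
    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        """Residues in chain-concatenation (file) order; matches PAE layout."""
        for ch in self.chains:
            for res in ch.residues:
                yield ch.chain_id, res

    def heavy_coords(self) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
        """All heavy-atom coordinates with (chain, seq_index, atom name) keys."""
        coords: list[np.ndarray] = []
        keys: list[tuple[str, int, str]] = []
        for cid, res in self.iter_residues():
            for a in res.heavy_atoms:
                coords.append(a.xyz)
                keys.append((cid, res.seq_index, a.name))
        if not coords:
            return np.empty((0, 3)), keys
        return np.asarray(coords, dtype=float), keys

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        chains = []
        for ch in self.chains:
            residues = []
            for res in ch.residues:
                atoms = [
                    Atom(a.name, a.element, rotation @ a.xyz + translation,
                         a.bfactor, a.occupancy)
                    for a in res.atoms
                ]
                residues.append(Residue(res.name, res.seq_index, atoms))
            chains.append(Chain(ch.chain_id, residues))
        return StructureModel(self.model_id, chains)


@dataclass
class ConfidenceBundle:
    """ipTM ranking and PAE matrix for one prediction job."""

    iptm_by_model: dict[str, float]
    ranking: list[str] = field(default_factory=list)
    pae: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = sorted(
                self.iptm_by_model, key=lambda m: (-self.iptm_by_model[m], m)
            )
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
                raise StructureParseError("PAE matrix must be square")
            if (self.pae < 0).any():
                raise StructureParseError("PAE entries must be non-negative")


def _structure_from_gemmi(st: gemmi.Structure, model_id: str) -> StructureModel:
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError("file contains no models")
    if len(st) > 1:
        logger.info("multi-model file %s: keeping first model only", model_id)
    gmodel = st[0]

    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        renumber_needed = any(r.seqid.icode.strip() for r in gchain)
        renumber_map: dict[str, int] = {}
        next_index = 1
        last_index: int | None = None
        for gres in gchain:
            if gres.is_water():
                continue
            # collapse altlocs to the highest-occupancy copy per atom name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    bfactor=float(ga.b_iso),
                    occupancy=float(ga.occ),
                )
                for ga in best.values()
            ]
            if not atoms:
                continue
            if renumber_needed:
                seq_index = next_index
                renumber_map[f"{gres.seqid.num}{gres.seqid.icode.strip()}"] = seq_index
                next_index += 1
            else:
                seq_index = gres.seqid.num
                if last_index is not None and seq_index <= last_index:
                    raise StructureParseError(
                        f"chain {gchain.name}: non-increasing residue numbering"
                    )
                last_index = seq_index
            residues.append(Residue(gres.name, seq_index, atoms))
        if renumber_map:
            logger.warning(
                "chain %s carries insertion codes; renumbered sequentially (%s)",
                gchain.name, renumber_map,
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise StructureParseError("no polymer/HET chains after dropping waters")
    return StructureModel(model_id, chains)


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` may be ``"pdb"`` or ``"mmcif"``; when ``None`` it is inferred
    from the file suffix.  Waters are dropped, altlocs collapsed to the
    highest-occupancy conformer, author residue numbering preserved.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    return _structure_from_gemmi(st, model_id=path.stem)


def write_structure(model: StructureModel, path: str | Path,
                    format: str | None = None) -> Path:
    """Write a model as PDB or mmCIF (inverse of :func:`read_structure`)."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    for ch in model.chains:
        gchain = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.xyz)
                ga.b_iso = a.bfactor
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureParseError(f"unknown format {format!r}")
    return path


def read_ranking(path: str | Path, prefer_raw_iptm: bool = True) -> ConfidenceBundle:
    """Parse an AlphaFold-dialect ranking JSON (``ranking_debug.json``).

    Two dialects are accepted: a raw ``"iptm"`` map and the weighted
    ``"iptm+ptm"`` ranking-confidence map.  When both are present,
    ``prefer_raw_iptm`` picks which one populates the bundle.
    """
    with open(path) as fh:
        doc = json.load(fh)
    keys = ["iptm", "iptm+ptm"] if prefer_raw_iptm else ["iptm+ptm", "iptm"]
    scores: dict[str, float] | None = None
    for key in keys:
        if key in doc and isinstance(doc[key], dict):
            scores = {str(k): float(v) for k, v in doc[key].items()}
            break
    if not scores:
        raise StructureParseError(f"{path}: no 'iptm' or 'iptm+ptm' score map")
    for m, v in scores.items():
        if not (0.0 <= v <= 1.0) or not math.isfinite(v):
            raise StructureParseError(f"{path}: score {v} for {m} outside [0,1]")
    return ConfidenceBundle(iptm_by_model=scores)


def read_pae(path: str | Path) -> np.ndarray:
    """Read a PAE JSON in any of the common AlphaFold dialects.

    Accepts ``{"pae": [[...]]}``, ``{"predicted_aligned_error": [[...]]}``
    and the EBI list-wrapped form ``[{"predicted_aligned_error": [[...]]}]``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        if not doc:
            raise StructureParseError(f"{path}: empty PAE document")
        doc = doc[0]
    matrix = None
    for key in ("pae", "predicted_aligned_error"):
        if isinstance(doc, dict) and key in doc:
            matrix = doc[key]
            break
    if matrix is None:
        raise StructureParseError(f"{path}: no PAE matrix key found")
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise StructureParseError(f"{path}: PAE matrix is not square ({arr.shape})")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise StructureParseError(f"{path}: PAE entries must be finite and >= 0")
    return arr


def select_best_model(bundle: ConfidenceBundle) -> str:
    """Representative model of a prediction job: highest ipTM, ties broken
    by lexicographically smallest model id."""
    if not bundle.iptm_by_model:
        raise ValueError("empty confidence bundle")
    return min(bundle.iptm_by_model, key=lambda m: (-bundle.iptm_by_model[m], m))
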