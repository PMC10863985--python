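"""Seeded synthetic inputs with known ground truth.

Structure prediction at GPU scale and database retrievals are outside the
desk-scale pipeline, so every input class it consumes is emulated here:

* ``synth_interactome`` — multi-species essentiality tables, an ortholog
  map, STRING-dialect per-species edge lists, family annotations and
  synthetic-lethal pairs, together with the exact subset of planted edges
  that satisfies the candidate-interactome filters;
* ``synth_dimer`` — a two-chain polyalanine coordinate model (ideal
  alpha-helices packed at a controllable axis separation) plus a
  perturbed copy (Gaussian coordinate noise and/or a rigid offset of one
  chain);
* ``synth_confidence`` — pLDDT B-factors, a five-model ipTM ranking and
  a PAE matrix at a controllable quality level;
* ``synth_conservation`` — 1-9 integer conservation tracks with an
  optional planted shift on the interface residues.

Every generator is a pure function of its seed and configuration; the
confidence distributions are invented surrogates whose only contract is
ordinal (high quality scores above low quality), never absolute values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .interactome import EdgeFilterConfig
from .interface import InterfaceConfig, find_interface_residues
from .structio import Atom, Chain, ConfidenceBundle, Residue, StructureModel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedEdge",
    "synth_interactome",
    "synth_dimer",
    "synth_confidence",
    "synth_conservation",
    "conservation_samples",
    "build_helix",
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # interactome generator
    n_species: int = 4          # four species per gram group, as compiled
    n_proteins: int = 60        # ortholog groups
    essential_fraction: float = 0.6
    n_true_edges: int = 40
    score_noise_sd: float = 0.03
    # dimer generator
    dimer_length: int = 24      # residues per chain
    interface_separation: float = 10.0  # A between helix axes
    stagger_fraction: float = 0.5       # axial stagger of chain B (fraction
                                        # of helix length); keeps part of
                                        # each chain away from the interface
    perturbation_sd: float = 0.0        # A Gaussian coordinate noise
    rigid_offset: float = 0.0           # A extra x-offset of chain B
    # confidence generator
    confidence_quality: str = "high"    # high | medium | low
    # conservation generator
    conservation_shift: float = 0.0     # added to interface residues

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_proteins, self.n_true_edges,
               self.dimer_length) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ValueError("essential_fraction must lie in [0,1]")
        if self.confidence_quality not in {"high", "medium", "low"}:
            raise ValueError("confidence_quality must be high|medium|low")
        max_edges = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_true_edges > max_edges:
            raise ValueError(
                f"n_true_edges={self.n_true_edges} exceeds the "
                f"{max_edges} possible pairs"
            )


@dataclass(frozen=True)
class PlantedEdge:
    pair: tuple[str, str]
    per_species: Mapping[str, tuple[float, float]]  # species -> (combined, experimental)


@dataclass
class GroundTruth:
    species: list[str]
    essential_by_species: dict[str, set[str]]   # species -> essential groups
    consensus_essential: set[str]               # essential in >= 2 species
    family_by_group: dict[str, str]
    planted: list[PlantedEdge]
    expected_kept: set[tuple[str, str]]         # pairs surviving all filters
    sl_pairs: list[tuple[str, str]]             # accession-level SL pairs
    sl_groups: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# interactome tables
# ---------------------------------------------------------------------------

def _accession(species: str, group: str) -> str:
    return f"{species}_{group}"


def synth_interactome(
    cfg: SimConfig,
    out_dir: str | Path,
    filter_config: EdgeFilterConfig | None = None,
) -> GroundTruth:
    """Emit a full synthetic interactome input set under ``out_dir``.

    Files written (all TSV): ``essentiality_<species>.tsv``,
    ``orthologs.tsv``, ``families.tsv``, ``edges_<species>.tsv``
    (STRING dialect, 0-1000 integer scores) and ``sl_pairs.tsv``.
    The returned :class:`GroundTruth` records which planted edges satisfy
    the full filter cascade, computed directly from the planted
    parameters (never by running the pipeline under test).
    """
    cfg_f = filter_config or EdgeFilterConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    groups = [f"OG{i:04d}" for i in range(cfg.n_proteins)]

    # essentiality: a slice of groups is consensus-essential (flagged in >=
    # min_essential_species species), the rest in at most one species
    n_consensus = int(round(cfg.essential_fraction * cfg.n_proteins))
    shuffled = list(groups)
    rng.shuffle(shuffled)
    consensus_groups = set(shuffled[:n_consensus])
    essential_by_species: dict[str, set[str]] = {sp: set() for sp in species}
    for g in groups:
        if g in consensus_groups:
            k = int(rng.integers(cfg_f.min_essential_species, cfg.n_species + 1))
        else:
            k = int(rng.integers(0, min(cfg_f.min_essential_species, 2)))
        for sp in rng.choice(species, size=k, replace=False):
            essential_by_species[str(sp)].add(g)

    # families: a sprinkle of excluded families among all groups
    excluded_labels = sorted(cfg_f.excluded_families)
    family_by_group: dict[str, str] = {}
    for g in groups:
        if rng.random() < 0.10 and excluded_labels:
            family_by_group[g] = str(rng.choice(excluded_labels))
        else:
            family_by_group[g] = "other"

    # planted edges with per-species score profiles
    all_pairs = [
        (a, b) for i, a in enumerate(groups) for b in groups[i + 1:]
    ]
    idx = rng.choice(len(all_pairs), size=cfg.n_true_edges, replace=False)
    planted: list[PlantedEdge] = []
    for k in sorted(idx):
        pair = all_pairs[k]
        n_present = int(rng.integers(1, cfg.n_species + 1))
        present = [str(s) for s in rng.choice(species, size=n_present, replace=False)]
        strong = rng.random() < 0.6
        per_species: dict[str, tuple[float, float]] = {}
        for sp in sorted(present):
            if strong:
                combined = rng.uniform(0.75, 0.99)
                experimental = rng.uniform(0.0, 0.9)
            else:
                combined = rng.uniform(0.05, 0.65)
                experimental = rng.uniform(0.0, 0.12)
            combined = float(np.clip(combined + rng.normal(0, cfg.score_noise_sd), 0, 1))
            experimental = float(
                np.clip(experimental + rng.normal(0, cfg.score_noise_sd), 0, 1)
            )
            # planted scores live at the emitted file precision (STRING's
            # 0-1000 integer dialect) so truth and files agree exactly
            per_species[sp] = (round(combined, 3), round(experimental, 3))
        planted.append(PlantedEdge(pair=pair, per_species=per_species))

    # ground truth: direct evaluation of the filter cascade on the planted
    # parameters
    expected_kept: set[tuple[str, str]] = set()
    for edge in planted:
        a, b = edge.pair
        if a not in consensus_groups or b not in consensus_groups:
            continue
        if (family_by_group.get(a) in cfg_f.excluded_families
                or family_by_group.get(b) in cfg_f.excluded_families):
            continue
        n_support = sum(
            1 for (c, e) in edge.per_species.values()
            if c > cfg_f.combined_min or e > cfg_f.experimental_min
        )
        if n_support >= cfg_f.min_species_support:
            expected_kept.add(edge.pair)

    # synthetic-lethal pairs: accessions of the first species, drawn from
    # groups without a planted edge between them
    sl_candidates = [p for p in all_pairs if p not in {e.pair for e in planted}]
    n_sl = min(3, len(sl_candidates))
    sl_groups: set[tuple[str, str]] = set()
    if n_sl:
        for k in rng.choice(len(sl_candidates), size=n_sl, replace=False):
            sl_groups.add(sl_candidates[int(k)])
    sl_pairs = [
        (_accession(species[0], a), _accession(species[0], b))
        for a, b in sorted(sl_groups)
    ]

    # ------------------------------------------------------------------ files
    ortho_rows = [
        {"accession": _accession(sp, g), "ortholog_group": g}
        for sp in species for g in groups
    ]
    pd.DataFrame(ortho_rows).to_csv(out_dir / "orthologs.tsv", sep="\t", index=False)

    fam_rows = [
        {"accession": _accession(species[0], g), "family": family_by_group[g]}
        for g in groups
    ]
    pd.DataFrame(fam_rows).to_csv(out_dir / "families.tsv", sep="\t", index=False)

    for sp in species:
        ess_rows = [
            {
                "species_id": sp,
                "accession": _accession(sp, g),
                "locus_tag": f"{sp}_{g}_lt",
                "gene_name": g.lower(),
                "source": "synthetic_screen",
            }
            for g in sorted(essential_by_species[sp])
        ]
        pd.DataFrame(
            ess_rows,
            columns=["species_id", "accession", "locus_tag", "gene_name", "source"],
        ).to_csv(out_dir / f"essentiality_{sp}.tsv", sep="\t", index=False)

        edge_rows = []
        for edge in planted:
            if sp not in edge.per_species:
                continue
            combined, experimental = edge.per_species[sp]
            edge_rows.append(
                {
                    "protein1": _accession(sp, edge.pair[0]),
                    "protein2": _accession(sp, edge.pair[1]),
                    "experimental": int(round(experimental * 1000)),
                    "combined": int(round(combined * 1000)),
                }
            )
        pd.DataFrame(
            edge_rows, columns=["protein1", "protein2", "experimental", "combined"]
        ).to_csv(out_dir / f"edges_{sp}.tsv", sep="\t", index=False)

    pd.DataFrame(sl_pairs, columns=["accession_a", "accession_b"]).to_csv(
        out_dir / "sl_pairs.tsv", sep="\t", index=False
    )

    return GroundTruth(
        species=species,
        essential_by_species=essential_by_species,
        consensus_essential={
            g for g in groups
            if sum(g in essential_by_species[sp] for sp in species)
            >= cfg_f.min_essential_species
        },
        family_by_group=family_by_group,
        planted=planted,
        expected_kept=expected_kept,
        sl_pairs=sl_pairs,
        sl_groups=sl_groups,
    )


# ---------------------------------------------------------------------------
# coordinate models
# ---------------------------------------------------------------------------

# idealized backbone internal coordinates (lengths A, angles deg)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.521
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_ANGLE_N_CA_CB = 110.4
_PHI_HELIX = -57.0
_PSI_HELIX = -47.0
_OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: new atom D bonded to c, with angle b-c-D and
    torsion a-b-c-D."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(n_res: int, chain_id: str = "A",
                phi: float = _PHI_HELIX, psi: float = _PSI_HELIX) -> Chain:
    """Ideal polyalanine helix with standard bond geometry, axis-aligned
    to z and centred at the origin."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    # seed the first residue in an arbitrary frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    angle = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _place(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _place(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    residues: list[Residue] = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        atoms = [
            Atom("N", "N", n_i.copy()),
            Atom("CA", "C", ca_i.copy()),
            Atom("C", "C", c_i.copy()),
        ]
        if i + 1 < len(backbone):
            o_i = _place(backbone[i + 1][0], ca_i, c_i, _BOND_C_O,
                         _ANGLE_CA_C_O, 180.0)
        else:
            # carboxy-terminal O placed anti to the psi direction
            pseudo_n = _place(n_i, ca_i, c_i, _BOND_C_N, _ANGLE_CA_C_N, psi)
            o_i = _place(pseudo_n, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, 180.0)
        atoms.append(Atom("O", "O", o_i))
        cb_i = _place(c_i, n_i, ca_i, _BOND_CA_CB, _ANGLE_N_CA_CB, -122.5)
        atoms.append(Atom("CB", "C", cb_i))
        residues.append(Residue("ALA", i + 1, atoms))

    # align the helix axis (leading CA principal direction) with z
    ca = np.array([r.atom("CA").xyz for r in residues])
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    for res in residues:
        for atom in res.atoms:
            atom.xyz = rot @ (atom.xyz - center)
    return Chain(chain_id, residues)


def synth_dimer(cfg: SimConfig) -> tuple[StructureModel, StructureModel]:
    """Native and perturbed two-chain polyalanine helix dimers.

    Chain B is the same helix rotated 180 deg about x (antiparallel
    packing), shifted by ``interface_separation`` along x and staggered
    along the helix axis by ``stagger_fraction`` of the helix length, so
    that only the overlapping segment forms the interface and the
    protruding ends stay solvent-exposed.  The perturbed copy adds seeded
    Gaussian coordinate noise of ``perturbation_sd`` to every atom and/or
    a rigid ``rigid_offset`` translation of chain B along x.
    """
    chain_a = build_helix(cfg.dimer_length, "A")
    chain_b = build_helix(cfg.dimer_length, "B")
    helix_span = (
        chain_a.residues[-1].atom("CA").xyz[2]
        - chain_a.residues[0].atom("CA").xyz[2]
    )
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    shift = np.array([cfg.interface_separation, 0.0,
                      cfg.stagger_fraction * helix_span])
    for res in chain_b.residues:
        for atom in res.atoms:
            atom.xyz = flip @ atom.xyz + shift
    native = StructureModel("native_dimer", [chain_a, chain_b])

    rng = np.random.default_rng(cfg.seed)
    perturbed = native.transformed(np.eye(3), np.zeros(3))
    perturbed.model_id = "perturbed_dimer"
    offset = np.array([cfg.rigid_offset, 0.0, 0.0])
    for chain in perturbed.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if cfg.perturbation_sd > 0:
                    atom.xyz = atom.xyz + rng.normal(0, cfg.perturbation_sd, 3)
                if chain.chain_id == "B":
                    atom.xyz = atom.xyz + offset
    return native, perturbed


# ---------------------------------------------------------------------------
# confidence surrogates
# ---------------------------------------------------------------------------

_QUALITY_PARAMS = {
    # (plddt mean, plddt sd, interchain pae mean, pae sd, iptm range)
    "high": (90.0, 3.0, 3.0, 1.0, (0.65, 0.95)),
    "medium": (70.0, 7.0, 12.0, 3.0, (0.40, 0.60)),
    "low": (50.0, 10.0, 25.0, 4.0, (0.10, 0.38)),
}
_PAE_MAX = 31.75


def synth_confidence(
    model: StructureModel,
    quality: str = "high",
    seed: int = 0,
    symmetric_pae: bool = True,
) -> tuple[StructureModel, ConfidenceBundle]:
    """Surrogate pLDDT/PAE/ipTM bundle for a model.

    Returns a copy of the model whose B-factors carry the sampled
    per-residue pLDDT, and a five-model :class:`ConfidenceBundle` whose
    PAE matrix has low intra-chain error and quality-controlled
    interchain error.  Deterministic in ``seed``.
    """
    if quality not in _QUALITY_PARAMS:
        raise ValueError(f"unknown quality {quality!r}")
    plddt_mu, plddt_sd, pae_mu, pae_sd, iptm_range = _QUALITY_PARAMS[quality]
    rng = np.random.default_rng(seed)

    scored = model.transformed(np.eye(3), np.zeros(3))
    for chain in scored.chains:
        for res in chain.residues:
            plddt = float(np.clip(rng.normal(plddt_mu, plddt_sd), 0.0, 100.0))
            for atom in res.atoms:
                atom.bfactor = plddt

    n = model.n_residues
    chain_of = np.array([
        ci for ci, chain in enumerate(model.chains) for _ in chain.residues
    ])
    intra = np.clip(rng.normal(2.0, 0.5, size=(n, n)), 0.2, _PAE_MAX)
    inter = np.clip(rng.normal(pae_mu, pae_sd, size=(n, n)), 0.2, _PAE_MAX)
    same_chain = chain_of[:, None] == chain_of[None, :]
    pae = np.where(same_chain, intra, inter)
    np.fill_diagonal(pae, 0.2)
    if symmetric_pae:
        pae = 0.5 * (pae + pae.T)

    lo, hi = iptm_range
    iptms = sorted(rng.uniform(lo, hi, size=5), reverse=True)
    bundle = ConfidenceBundle(
        iptm_by_model={f"model_{i + 1}": float(v) for i, v in enumerate(iptms)},
        pae=pae,
    )
    return scored, bundle


def write_confidence_files(bundle: ConfidenceBundle, out_dir: str | Path) -> None:
    """Emit the ranking and PAE JSON artifacts in the predictor dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "ranking_debug.json", "w") as fh:
        json.dump({"iptm": bundle.iptm_by_model, "order": bundle.ranking}, fh,
                  indent=1)
    if bundle.pae is not None:
        with open(out_dir / "pae.json", "w") as fh:
            json.dump({"pae": np.round(bundle.pae, 3).tolist()}, fh)


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------

def synth_conservation(
    model: StructureModel,
    shift: float = 0.0,
    seed: int = 0,
    config: InterfaceConfig | None = None,
) -> dict[tuple[str, int], int]:
    """1-9 conservation track for every residue of a two-chain model.

    Baseline scores are uniform on {1..9}; interface residues (10 A
    heavy-atom criterion) receive ``+shift`` before clipping back to
    [1, 9].
    """
    rng = np.random.default_rng(seed)
    interface = find_interface_residues(model, config)
    track: dict[tuple[str, int], int] = {}
    for cid, res in model.iter_residues():
        score = float(rng.integers(1, 10))
        if (cid, res.seq_index) in interface:
            score += shift
        track[(cid, res.seq_index)] = int(np.clip(round(score), 1, 9))
    return track


def conservation_samples(
    n_interface: int,
    n_surface: int,
    shift: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired interface/surface conservation samples for calibration runs:
    both uniform on {1..9}, interface shifted by ``shift`` and clipped."""
    surface = rng.integers(1, 10, size=n_surface)
    interface = np.clip(rng.integers(1, 10, size=n_interface) + shift, 1, 9)
    return interface.astype(float), surface.astype(float)


def write_conservation_tsv(
    track: Mapping[tuple[str, int], int], path: str | Path
) -> Path:
    rows = [
        {"chain": cid, "seq_index": idx, "score": score}
        for (cid, idx), score in sorted(track.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_conservation_tsv(path: str | Path) -> dict[tuple[str, int], int]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    out: dict[tuple[str, int], int] = {}
    for row in df.itertuples(index=False):
        score = int(row.score)
        if not 1 <= score <= 9:
            raise ValueError(f"{path}: conservation score {score} outside 1..9")
        out[(row.chain, int(row.seq_index))] = score
    return out
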