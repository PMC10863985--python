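"""Interface geometry, solvent accessibility and conservation contrasts.

Definitions used throughout (heavy atoms only — predicted models carry no
hydrogens):

* **contact residues** — interchain residue pairs with any heavy-atom pair
  within 4.5 A;
* **interface residues** — residues with any heavy atom within 10 A of the
  partner chain;
* **surface residues** — residues of the *isolated* chain owning at least
  one atom with solvent-accessible area >= 6.5 A^2 (the exposed-area
  threshold of the usual surface-atom finder);
* **buried interface area** — SASA(A) + SASA(B) - SASA(AB).

SASA is computed with the Shrake-Rupley quadrature: each atom's van der
Waals sphere is inflated by the probe radius (water, 1.4 A) and covered
with near-uniform test points (golden-spiral lattice); the accessible
fraction is the share of points not inside any neighbouring inflated
sphere.  Conservation scores are 9-level integer tracks (1 = most
variable, 9 = most conserved); the interface-vs-surface contrast is a
Wilcoxon rank-sum (Mann-Whitney) test with tie correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .constants import vdw_radii
from .structio import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceConfig",
    "InterfaceReport",
    "ConservationResult",
    "find_contact_residues",
    "find_interface_residues",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "find_surface_residues",
    "conservation_contrast",
    "residue_type_network",
    "analyze_interface",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class InterfaceConfig:
    contact_cutoff: float = 4.5       # A, heavy-atom contact distance
    interface_cutoff: float = 10.0    # A, heavy-atom interface distance
    surface_atom_sasa_min: float = 6.5  # A^2 exposed area per atom
    probe_radius: float = 1.4         # A, water probe
    sphere_points: int = 960

    def __post_init__(self) -> None:
        if not (0 < self.contact_cutoff <= self.interface_cutoff):
            raise ValueError("need 0 < contact_cutoff <= interface_cutoff")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")


ResidueKey = tuple[str, int]  # (chain_id, seq_index)


@dataclass
class ConservationResult:
    statistic: float          # rank-sum W of the interface sample
    p_two_sided: float
    p_one_sided: float        # H1: interface more conserved than surface
    median_interface: float
    median_surface: float


@dataclass
class InterfaceReport:
    contact_residues: set[ResidueKey]
    interface_residues: set[ResidueKey]
    surface_residues: set[ResidueKey]
    per_atom_sasa: dict[tuple[str, int, str], float]
    buried_area: float
    per_chain_delta_sasa_half: float
    conservation: ConservationResult | None = None


def _two_chain_heavy(model: StructureModel):
    if len(model.chains) != 2:
        raise ValueError("operation requires a two-chain model")
    out = []
    for chain in model.chains:
        coords, keys = [], []
        for res in chain.residues:
            for a in res.heavy_atoms:
                coords.append(a.xyz)
                keys.append((chain.chain_id, res.seq_index))
        out.append((np.asarray(coords, dtype=float), keys))
    return out


def find_contact_residues(
    model: StructureModel, config: InterfaceConfig | None = None
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Interchain residue pairs with any heavy-atom distance <= contact cutoff."""
    config = config or InterfaceConfig()
    (xyz_a, keys_a), (xyz_b, keys_b) = _two_chain_heavy(model)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return set()
    hits = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=config.contact_cutoff)
    return {
        (keys_a[i], keys_b[j]) for i, js in enumerate(hits) for j in js
    }


def find_interface_residues(
    model: StructureModel, config: InterfaceConfig | None = None
) -> set[ResidueKey]:
    """Residues (either chain) with any heavy atom within the interface
    cutoff of any heavy atom of the partner chain."""
    config = config or InterfaceConfig()
    (xyz_a, keys_a), (xyz_b, keys_b) = _two_chain_heavy(model)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return set()
    hits = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=config.interface_cutoff)
    out: set[ResidueKey] = set()
    for i, js in enumerate(hits):
        if js:
            out.add(keys_a[i])
            out.update(keys_b[j] for j in js)
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere lattice (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> dict[tuple[str, int, str], float]:
    """Per-atom solvent-accessible surface area (A^2), heavy atoms only.

    Unknown elements fall back to the configured default radius with a
    warning.
    """
    radii = radii or vdw_radii()
    default_r = radii.get("default", 1.7)
    coords, keys = model.heavy_coords()
    elements = [
        a.element.upper()
        for _, res in model.iter_residues()
        for a in res.heavy_atoms
    ]
    n = len(coords)
    if n == 0:
        return {}
    atom_radii = np.empty(n)
    warned: set[str] = set()
    for i, el in enumerate(elements):
        if el in radii:
            atom_radii[i] = radii[el]
        else:
            if el not in warned:
                logger.warning("unknown element %r: using default radius %.2f",
                               el, default_r)
                warned.add(el)
            atom_radii[i] = default_r
    inflated = atom_radii + probe_radius
    unit = _sphere_points(sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    out: dict[tuple[str, int, str], float] = {}
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(coords[i], inflated[i] + max_reach / 2.0)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]
        ]
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= inflated[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        area = 4.0 * np.pi * inflated[i] ** 2 * frac
        out[keys[i]] = out.get(keys[i], 0.0) + float(area)
    return out


def _isolated_chain(model: StructureModel, index: int) -> StructureModel:
    return StructureModel(
        f"{model.model_id}:{model.chains[index].chain_id}",
        [model.chains[index]],
    )


def buried_interface_area(
    model: StructureModel, config: InterfaceConfig | None = None
) -> float:
    """SASA buried on complex formation: SASA(A) + SASA(B) - SASA(AB)."""
    config = config or InterfaceConfig()
    if len(model.chains) != 2:
        raise ValueError("buried_interface_area requires a two-chain model")
    kwargs = dict(probe_radius=config.probe_radius,
                  sphere_points=config.sphere_points)
    sasa_complex = sum(shrake_rupley_sasa(model, **kwargs).values())
    sasa_alone = sum(
        sum(shrake_rupley_sasa(_isolated_chain(model, i), **kwargs).values())
        for i in (0, 1)
    )
    return sasa_alone - sasa_complex


def find_surface_residues(
    model: StructureModel,
    config: InterfaceConfig | None = None,
    exclude_interface: bool = True,
) -> set[ResidueKey]:
    """Residues owning >= 1 atom with exposed area above the surface
    threshold, computed per *isolated* chain; interface residues are
    removed when ``exclude_interface`` (the conservation contrast set)."""
    config = config or InterfaceConfig()
    surface: set[ResidueKey] = set()
    for i, chain in enumerate(model.chains):
        per_atom = shrake_rupley_sasa(
            _isolated_chain(model, i),
            probe_radius=config.probe_radius,
            sphere_points=config.sphere_points,
        )
        for (cid, seq_index, _atom), area in per_atom.items():
            if area >= config.surface_atom_sasa_min:
                surface.add((cid, seq_index))
    if exclude_interface and len(model.chains) == 2:
        surface -= find_interface_residues(model, config)
    return surface


def conservation_contrast(
    interface_scores, surface_scores
) -> ConservationResult:
    """Wilcoxon rank-sum contrast of interface vs. surface conservation.

    Two-sided p with tie correction, plus the one-sided p for the
    directional hypothesis that interfaces are more conserved.
    """
    x = np.asarray(interface_scores, dtype=float)
    y = np.asarray(surface_scores, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    two = stats.mannwhitneyu(x, y, alternative="two-sided")
    one = stats.mannwhitneyu(x, y, alternative="greater")
    # rank-sum W of the interface sample = U + n1(n1+1)/2
    w = float(two.statistic + len(x) * (len(x) + 1) / 2.0)
    return ConservationResult(
        statistic=w,
        p_two_sided=float(two.pvalue),
        p_one_sided=float(one.pvalue),
        median_interface=float(np.median(x)),
        median_surface=float(np.median(y)),
    )


def _sidechain_atoms(res) -> list:
    if res.name == "GLY":
        ca = res.atom("CA")
        return [ca] if ca is not None else []
    return [a for a in res.heavy_atoms if a.name not in BACKBONE_ATOMS]


def residue_type_network(
    models: list[StructureModel], config: InterfaceConfig | None = None
) -> nx.Graph:
    """Aggregate side-chain contact network over the 20 residue types.

    For every interchain side-chain-atom contact within the contact
    cutoff, the (typeA, typeB) edge weight is incremented once per
    residue pair per model; undirected, self-edges (e.g. LEU-LEU)
    allowed.  Feed it the high-confidence models only.
    """
    config = config or InterfaceConfig()
    graph = nx.Graph()
    for model in models:
        if len(model.chains) != 2:
            raise ValueError(f"{model.model_id}: residue-type network needs 2 chains")
        per_chain = []
        for chain in model.chains:
            coords, names = [], []
            for res in chain.residues:
                for a in _sidechain_atoms(res):
                    coords.append(a.xyz)
                    names.append((res.seq_index, res.name))
            per_chain.append((np.asarray(coords, dtype=float), names))
        (xyz_a, meta_a), (xyz_b, meta_b) = per_chain
        if len(xyz_a) == 0 or len(xyz_b) == 0:
            continue
        hits = cKDTree(xyz_a).query_ball_tree(
            cKDTree(xyz_b), r=config.contact_cutoff
        )
        pairs = {
            (meta_a[i], meta_b[j]) for i, js in enumerate(hits) for j in js
        }
        for (_, type_a), (_, type_b) in pairs:
            u, v = sorted((type_a, type_b))
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += 1
            else:
                graph.add_edge(u, v, weight=1)
    return graph


def analyze_interface(
    model: StructureModel,
    config: InterfaceConfig | None = None,
    conservation: dict[ResidueKey, int] | None = None,
) -> InterfaceReport:
    """Full interface report for one two-chain model.

    ``conservation`` maps (chain_id, seq_index) to 1-9 scores; when given,
    the interface-vs-surface Wilcoxon contrast is included.
    """
    config = config or InterfaceConfig()
    contacts = find_contact_residues(model, config)
    contact_res = {r for pair in contacts for r in pair}
    interface = find_interface_residues(model, config)
    surface = find_surface_residues(model, config, exclude_interface=True)
    per_atom = shrake_rupley_sasa(
        model, probe_radius=config.probe_radius, sphere_points=config.sphere_points
    )
    buried = buried_interface_area(model, config)
    result = None
    if conservation is not None:
        iface_scores = [conservation[r] for r in sorted(interface) if r in conservation]
        surf_scores = [conservation[r] for r in sorted(surface) if r in conservation]
        if len(iface_scores) >= 2 and len(surf_scores) >= 2:
            result = conservation_contrast(iface_scores, surf_scores)
        else:
            logger.warning("%s: too few scored residues for the conservation "
                           "contrast", model.model_id)
    return InterfaceReport(
        contact_residues=contact_res,
        interface_residues=interface,
        surface_residues=surface,
        per_atom_sasa=per_atom,
        buried_area=buried,
        per_chain_delta_sasa_half=buried / 2.0,
        conservation=result,
    )
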