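"""Structure-aware confidence scoring of predicted binary complexes.

Three complementary confidences are handled:

* **ipTM** — the predictor's own interface confidence, read from the
  ranking JSON (0-1);
* **pDockQ** — sigmoid of (mean interface pLDDT) x ln(n interchain
  Cbeta-Cbeta contacts at 8 A);
* **pDockQ2** — per-chain sigmoid of (mean interface pLDDT) x (mean
  PAE-derived contact weight 1/(1+(PAE/d0)^2)), averaged over the two
  chains; requires the PAE matrix.

Models are triaged into ``unlikely`` (ipTM < 0.4), ``plausible``
(0.4 <= ipTM <= 0.6) and ``high_confidence`` (ipTM > 0.6).  All sigmoid
constants come from the versioned package config, never inline literals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .constants import score_constants
from .structio import StructureModel

__all__ = [
    "CATEGORY_UNLIKELY",
    "CATEGORY_PLAUSIBLE",
    "CATEGORY_HIGH",
    "ClassificationThresholds",
    "ScorePanel",
    "interface_contacts_cb",
    "compute_pdockq",
    "compute_pdockq2",
    "classify_iptm",
    "pearson_correlation",
]

CATEGORY_UNLIKELY = "unlikely"
CATEGORY_PLAUSIBLE = "plausible"
CATEGORY_HIGH = "high_confidence"


@dataclass(frozen=True)
class ClassificationThresholds:
    low: float = 0.4
    high: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high < 1.0):
            raise ValueError("need 0 < low < high < 1")


@dataclass(frozen=True)
class ScorePanel:
    """Confidence summary for one predicted binary complex."""

    edge_id: str
    model_id: str
    iptm: float
    pdockq: float
    pdockq2: float | None
    category: str


def _cb_coords(model: StructureModel, chain_index: int):
    """Cbeta coordinate per residue (Calpha for glycine); skips residues
    lacking both, which are logged by the caller's discretion."""
    chain = model.chains[chain_index]
    coords, residues = [], []
    for res in chain.residues:
        atom = res.atom("CB") if res.name != "GLY" else res.atom("CA")
        if atom is None:
            atom = res.atom("CA")
        if atom is None:
            continue
        coords.append(atom.xyz)
        residues.append(res)
    if not coords:
        return np.empty((0, 3)), residues
    return np.asarray(coords, dtype=float), residues


def interface_contacts_cb(
    model: StructureModel, cutoff: float = 8.0
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Interchain residue pairs with Cbeta-Cbeta distance <= ``cutoff``.

    This is the contact definition used by the pDockQ family of scores,
    distinct from the 4.5/10 A heavy-atom cutoffs of the interface
    analysis module.
    """
    if len(model.chains) != 2:
        raise ValueError("interface_contacts_cb requires exactly 2 chains")
    xyz_a, res_a = _cb_coords(model, 0)
    xyz_b, res_b = _cb_coords(model, 1)
    if len(res_a) == 0 or len(res_b) == 0:
        return []
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=cutoff)
    cid_a, cid_b = model.chains[0].chain_id, model.chains[1].chain_id
    out = []
    for i, js in enumerate(pairs):
        for j in js:
            out.append(((cid_a, res_a[i].seq_index), (cid_b, res_b[j].seq_index)))
    return sorted(out)


def _interface_plddt(model: StructureModel, residues: set[tuple[str, int]]) -> float:
    values = []
    for cid, seq_index in residues:
        res = model.chain(cid).residue(seq_index)
        if res is None:
            continue
        plddt = res.plddt
        if plddt is None:
            raise ValueError(f"residue {cid}:{seq_index} lacks a Calpha pLDDT")
        values.append(plddt)
    if not values:
        raise ValueError("no pLDDT values available on interface residues")
    return float(np.mean(values))


def compute_pdockq(model: StructureModel) -> float:
    """pDockQ of a two-chain model with pLDDT in its B-factors.

    ``pDockQ = L / (1 + exp(-k (x - x0))) + b`` with
    ``x = <pLDDT over interface residues> * ln(n_contacts)``;
    defined as 0 when the chains make no Cbeta contact.
    """
    consts = score_constants()["pdockq"]
    contacts = interface_contacts_cb(model, cutoff=consts["contact_cutoff"])
    if not contacts:
        return 0.0
    interface = {r for pair in contacts for r in pair}
    x = _interface_plddt(model, interface) * math.log(len(contacts))
    return consts["L"] / (1.0 + math.exp(-consts["k"] * (x - consts["x0"]))) + consts["b"]


def _global_residue_index(model: StructureModel) -> dict[tuple[str, int], int]:
    return {
        (cid, res.seq_index): i
        for i, (cid, res) in enumerate(model.iter_residues())
    }


def compute_pdockq2(model: StructureModel, pae: np.ndarray) -> float:
    """pDockQ2 of a two-chain model given its PAE matrix.

    For each chain, ``x = <pLDDT over that chain's interface residues> *
    <1 / (1 + (PAE_ij / d0)^2)>`` averaged over the interchain contact
    pairs (PAE symmetrized over the two directions), passed through the
    published sigmoid; the complex score is the mean over the two chains.
    Defined as 0 when there are no contacts.
    """
    pae = np.asarray(pae, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("PAE matrix must be square")
    if pae.shape[0] != model.n_residues:
        raise ValueError(
            f"PAE dimension {pae.shape[0]} != model residue count {model.n_residues}"
        )
    consts = score_constants()["pdockq2"]
    contacts = interface_contacts_cb(model, cutoff=consts["contact_cutoff"])
    if not contacts:
        return 0.0
    gidx = _global_residue_index(model)
    d0 = consts["d0"]
    weights = []
    for ra, rb in contacts:
        i, j = gidx[ra], gidx[rb]
        pae_ij = 0.5 * (pae[i, j] + pae[j, i])
        weights.append(1.0 / (1.0 + (pae_ij / d0) ** 2))
    mean_weight = float(np.mean(weights))

    scores = []
    for chain in model.chains:
        cid = chain.chain_id
        iface = {r for pair in contacts for r in pair if r[0] == cid}
        x = _interface_plddt(model, iface) * mean_weight
        scores.append(
            consts["L"] / (1.0 + math.exp(-consts["k"] * (x - consts["x0"])))
            + consts["b"]
        )
    return float(np.mean(scores))


def classify_iptm(
    score: float, th: ClassificationThresholds | None = None
) -> str:
    """Triage an ipTM into unlikely / plausible / high_confidence.

    Boundaries are assigned to ``plausible`` (both the < low and > high
    comparisons are strict).
    """
    th = th or ClassificationThresholds()
    if not (0.0 <= score <= 1.0) or not math.isfinite(score):
        raise ValueError(f"ipTM {score} outside [0,1]")
    if score < th.low:
        return CATEGORY_UNLIKELY
    if score > th.high:
        return CATEGORY_HIGH
    return CATEGORY_PLAUSIBLE


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation of two equal-length score columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def score_model(
    edge_id: str,
    model: StructureModel,
    iptm: float,
    pae: np.ndarray | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> ScorePanel:
    """Assemble the full confidence panel for one predicted complex."""
    return ScorePanel(
        edge_id=edge_id,
        model_id=model.model_id,
        iptm=iptm,
        pdockq=compute_pdockq(model),
        pdockq2=None if pae is None else compute_pdockq2(model, pae),
        category=classify_iptm(iptm, thresholds),
    )
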