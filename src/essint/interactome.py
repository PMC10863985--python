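"""Candidate essential-interactome construction.

The essential interactome is bounded above by the set of interactions in
which both partners are essential: a complex can only be essential if every
protein forming it is.  This module assembles that candidate set from
per-species essential-protein tables, an ortholog-group map (which equates
proteins across species), and STRING-dialect edge lists, then adds
synthetic-lethal pairs and draws seeded random negative pairs as the control
set for downstream confidence scoring.

Filtering rules
---------------
* a protein (ortholog group) counts as essential only when flagged essential
  in at least ``min_essential_species`` distinct species (default 2);
* an edge is kept when its combined score exceeds ``combined_min`` (default
  0.7) *or* its experimental sub-score exceeds ``experimental_min`` (default
  0.15) — strict inequalities;
* both endpoints must be essential, neither may belong to an excluded
  family (ribosomal proteins, tRNA ligases by default);
* an edge must be recovered in at least ``min_species_support`` species
  (default 2) to enter the consensus set;
* synthetic-lethal pairs bypass the both-essential and multi-species rules:
  they capture pairs of individually dispensable proteins that are lethal
  in combination, and come from a single-species screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ORIGIN_STRING",
    "ORIGIN_SL",
    "ORIGIN_NEGATIVE",
    "EssentialityRecord",
    "OrthologMap",
    "CandidateEdge",
    "EdgeFilterConfig",
    "compile_essential_set",
    "filter_string_edges",
    "consensus_edges",
    "merge_synthetic_lethal",
    "generate_random_negatives",
    "families_by_group",
    "read_essentiality_tsv",
    "read_ortholog_map_tsv",
    "read_string_edges_tsv",
    "write_edges_tsv",
    "read_edges_tsv",
    "read_family_tsv",
    "read_sl_pairs_tsv",
    "run_interactome_pipeline",
]

ORIGIN_STRING = "string_evidence"
ORIGIN_SL = "synthetic_lethal"
ORIGIN_NEGATIVE = "random_negative"
_VALID_ORIGINS = {ORIGIN_STRING, ORIGIN_SL, ORIGIN_NEGATIVE}


@dataclass(frozen=True)
class EssentialityRecord:
    """One essential-protein row from a per-species compilation."""

    species_id: str
    accession: str
    locus_tag: str = ""
    gene_name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")


class OrthologMap:
    """accession -> ortholog-group id; each accession maps to one group."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    def __len__(self) -> int:
        return len(self._map)

    def group_of(self, accession: str) -> str | None:
        return self._map.get(accession)

    def items(self):
        return self._map.items()


@dataclass(frozen=True)
class CandidateEdge:
    """Unordered protein-pair candidate at the ortholog-group level.

    ``origin`` is one or more provenance tags joined with ``+`` (an edge
    found both in STRING and the synthetic-lethal screen records both).
    """

    group_a: str
    group_b: str
    combined_score: float = 0.0
    experimental_score: float = 0.0
    species_support: frozenset[str] = frozenset()
    origin: str = ORIGIN_STRING
    gram_group: str = ""

    def __post_init__(self) -> None:
        a, b = sorted((self.group_a, self.group_b))
        if a == b:
            raise ValueError(f"self-edge {a!r} is not a valid candidate")
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)
        object.__setattr__(self, "species_support", frozenset(self.species_support))
        for s in (self.combined_score, self.experimental_score):
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} outside [0,1]")
        tags = set(self.origin.split("+"))
        if not tags <= _VALID_ORIGINS:
            raise ValueError(f"unknown origin tag(s) in {self.origin!r}")
        object.__setattr__(self, "origin", "+".join(sorted(tags)))
        if not self.species_support and ORIGIN_NEGATIVE not in tags:
            raise ValueError("species_support empty for a non-negative edge")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


@dataclass(frozen=True)
class EdgeFilterConfig:
    combined_min: float = 0.7
    experimental_min: float = 0.15
    min_species_support: int = 2
    min_essential_species: int = 2
    excluded_families: frozenset[str] = frozenset({"ribosomal", "tRNA_ligase"})
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.combined_min <= 1.0 and 0.0 <= self.experimental_min <= 1.0):
            raise ValueError("score thresholds must lie in [0,1]")
        if self.min_species_support < 1 or self.min_essential_species < 1:
            raise ValueError("minimum counts must be >= 1")
        object.__setattr__(self, "excluded_families", frozenset(self.excluded_families))


def compile_essential_set(
    records: Sequence[EssentialityRecord],
    orthologs: OrthologMap,
    min_essential_species: int = 2,
    return_unresolved: bool = False,
):
    """Ortholog groups flagged essential in >= ``min_essential_species``
    distinct species.

    Duplicate (species, accession) rows are deduplicated silently;
    accessions absent from the ortholog map are collected, logged and
    skipped (returned as a second value when ``return_unresolved``).
    """
    if not records:
        logger.warning("compile_essential_set: empty record list")
        return (set(), []) if return_unresolved else set()
    species_by_group: dict[str, set[str]] = {}
    unresolved: list[EssentialityRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.species_id, rec.accession)
        if key in seen:
            continue
        seen.add(key)
        group = orthologs.group_of(rec.accession)
        if group is None:
            unresolved.append(rec)
            continue
        species_by_group.setdefault(group, set()).add(rec.species_id)
    if unresolved:
        logger.warning(
            "compile_essential_set: %d accession(s) not in ortholog map "
            "(e.g. %s); skipped", len(unresolved), unresolved[0].accession,
        )
    essential = {
        g for g, sp in species_by_group.items() if len(sp) >= min_essential_species
    }
    return (essential, unresolved) if return_unresolved else essential


def _passes_scores(edge: CandidateEdge, config: EdgeFilterConfig) -> bool:
    return (
        edge.combined_score > config.combined_min
        or edge.experimental_score > config.experimental_min
    )


def filter_string_edges(
    edges: Sequence[CandidateEdge],
    essential: set[str],
    config: EdgeFilterConfig | None = None,
    family_annotation: Mapping[str, str] | None = None,
) -> list[CandidateEdge]:
    """Apply the score, both-essential and family-exclusion filters.

    ``family_annotation`` maps ortholog-group ids to family labels (use
    :func:`families_by_group` to translate an accession-keyed table).
    Endpoints absent from the annotation are treated as not excluded.
    The output keeps one record per unordered pair (first occurrence wins;
    inputs are expected deduplicated per species).
    """
    config = config or EdgeFilterConfig()
    family_annotation = family_annotation or {}
    kept: dict[tuple[str, str], CandidateEdge] = {}
    for edge in edges:
        if not _passes_scores(edge, config):
            continue
        if edge.group_a not in essential or edge.group_b not in essential:
            continue
        fam_a = family_annotation.get(edge.group_a)
        fam_b = family_annotation.get(edge.group_b)
        if fam_a is None and edge.group_a not in family_annotation:
            logger.debug("no family annotation for %s; not excluded", edge.group_a)
        if fam_b is None and edge.group_b not in family_annotation:
            logger.debug("no family annotation for %s; not excluded", edge.group_b)
        if fam_a in config.excluded_families or fam_b in config.excluded_families:
            continue
        kept.setdefault(edge.pair, edge)
    return [kept[p] for p in sorted(kept)]


def consensus_edges(
    per_species_edges: Mapping[str, Sequence[CandidateEdge]],
    min_species_support: int = 2,
) -> list[CandidateEdge]:
    """Shortlist edges recovered in >= ``min_species_support`` species.

    The merged edge carries the union of contributing species and the
    maximum of each sub-score across species.
    """
    merged: dict[tuple[str, str], CandidateEdge] = {}
    for species, edges in sorted(per_species_edges.items()):
        for edge in edges:
            support = edge.species_support or frozenset({species})
            prev = merged.get(edge.pair)
            if prev is None:
                merged[edge.pair] = replace(edge, species_support=support)
            else:
                merged[edge.pair] = replace(
                    prev,
                    combined_score=max(prev.combined_score, edge.combined_score),
                    experimental_score=max(
                        prev.experimental_score, edge.experimental_score
                    ),
                    species_support=prev.species_support | support,
                    origin="+".join(
                        sorted(set(prev.origin.split("+")) | set(edge.origin.split("+")))
                    ),
                )
    return [
        merged[p]
        for p in sorted(merged)
        if len(merged[p].species_support) >= min_species_support
    ]


def merge_synthetic_lethal(
    edges: Sequence[CandidateEdge],
    sl_pairs: Sequence[tuple[str, str]],
    orthologs: OrthologMap,
    species_id: str = "E_coli_K12_BW25113",
) -> list[CandidateEdge]:
    """Append synthetic-lethal pairs (accession pairs, mapped to groups).

    SL edges bypass the both-essential filter.  A pair duplicating an
    existing edge is merged into it, recording both origins.  Self-pairs
    (identical accession, or two accessions of one ortholog group) are
    rejected with :class:`ValueError`.
    """
    merged: dict[tuple[str, str], CandidateEdge] = {e.pair: e for e in edges}
    for acc_a, acc_b in sl_pairs:
        if acc_a == acc_b:
            raise ValueError(f"synthetic-lethal self-pair {acc_a!r}")
        ga, gb = orthologs.group_of(acc_a), orthologs.group_of(acc_b)
        if ga is None or gb is None:
            missing = acc_a if ga is None else acc_b
            logger.warning("SL pair (%s, %s): %s not in ortholog map; skipped",
                           acc_a, acc_b, missing)
            continue
        if ga == gb:
            raise ValueError(
                f"synthetic-lethal pair ({acc_a}, {acc_b}) collapses to one "
                f"ortholog group {ga!r}"
            )
        sl_edge = CandidateEdge(
            ga, gb, species_support=frozenset({species_id}), origin=ORIGIN_SL
        )
        prev = merged.get(sl_edge.pair)
        if prev is None:
            merged[sl_edge.pair] = sl_edge
        else:
            merged[sl_edge.pair] = replace(
                prev,
                species_support=prev.species_support | sl_edge.species_support,
                origin="+".join(sorted(set(prev.origin.split("+")) | {ORIGIN_SL})),
            )
    return [merged[p] for p in sorted(merged)]


def generate_random_negatives(
    proteins: set[str],
    n: int,
    positives: set[tuple[str, str]],
    seed: int,
    gram_group: str = "",
) -> list[CandidateEdge]:
    """Draw ``n`` distinct random pairs absent from the positive set.

    Rejection sampling without replacement from a seeded generator; the
    same seed yields the identical edge list.
    """
    proteins_sorted = sorted(proteins)
    canon_pos = {tuple(sorted(p)) for p in positives}
    total = len(proteins_sorted) * (len(proteins_sorted) - 1) // 2
    pos_inside = {
        p for p in canon_pos
        if p[0] != p[1] and p[0] in proteins and p[1] in proteins
    }
    available = total - len(pos_inside)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > available:
        raise ValueError(
            f"requested {n} negatives but only {available} unordered pairs "
            f"outside the positive set exist among {len(proteins_sorted)} proteins"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[CandidateEdge] = []
    while len(out) < n:
        i, j = rng.integers(0, len(proteins_sorted), size=2)
        if i == j:
            continue
        pair = tuple(sorted((proteins_sorted[i], proteins_sorted[j])))
        if pair in canon_pos or pair in chosen:
            continue
        chosen.add(pair)
        out.append(
            CandidateEdge(pair[0], pair[1], origin=ORIGIN_NEGATIVE,
                          gram_group=gram_group)
        )
    return out


def families_by_group(
    annotation_by_accession: Mapping[str, str], orthologs: OrthologMap
) -> dict[str, str]:
    """Lift an accession-keyed family table to the ortholog-group level.

    If two accessions of one group disagree, the first (sorted accession)
    wins and a warning is emitted.
    """
    out: dict[str, str] = {}
    for acc in sorted(annotation_by_accession):
        group = orthologs.group_of(acc)
        if group is None:
            continue
        fam = annotation_by_accession[acc]
        if group in out and out[group] != fam:
            logger.warning("group %s: conflicting family labels %r / %r",
                           group, out[group], fam)
            continue
        out[group] = fam
    return out


# ---------------------------------------------------------------------------
# Tabular I/O (TSV dialects)
# ---------------------------------------------------------------------------

def read_essentiality_tsv(path: str | Path) -> list[EssentialityRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species_id", "accession"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return [
        EssentialityRecord(
            species_id=row.species_id,
            accession=row.accession,
            locus_tag=getattr(row, "locus_tag", ""),
            gene_name=getattr(row, "gene_name", ""),
            source=getattr(row, "source", ""),
        )
        for row in df.itertuples(index=False)
    ]


def read_ortholog_map_tsv(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "ortholog_group"} <= set(df.columns):
        raise ValueError(f"{path}: need columns accession, ortholog_group")
    dup = df["accession"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: accession(s) mapped to more than one group")
    return OrthologMap(dict(zip(df["accession"], df["ortholog_group"])))


def _normalize_scores(values: pd.Series) -> pd.Series:
    """STRING exports scores either as 0-1000 integers or 0-1 reals."""
    vals = pd.to_numeric(values, errors="raise").astype(float)
    if (vals > 1.0).any():
        return vals / 1000.0
    return vals


def read_string_edges_tsv(
    path: str | Path,
    orthologs: OrthologMap,
    species_id: str,
    gram_group: str = "",
) -> list[CandidateEdge]:
    """Read a STRING-dialect edge TSV (protein1, protein2, experimental,
    combined) at the accession level and lift it to ortholog groups.

    Scores in the 0-1000 integer dialect are auto-detected and normalized
    to [0,1].  Rows with unmappable accessions or group self-pairs are
    skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    need = {"protein1", "protein2", "combined", "experimental"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {need - set(df.columns)}")
    df["combined"] = _normalize_scores(df["combined"])
    df["experimental"] = _normalize_scores(df["experimental"])
    edges: dict[tuple[str, str], CandidateEdge] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        ga, gb = orthologs.group_of(row.protein1), orthologs.group_of(row.protein2)
        if ga is None or gb is None or ga == gb:
            skipped += 1
            continue
        edge = CandidateEdge(
            ga, gb,
            combined_score=float(row.combined),
            experimental_score=float(row.experimental),
            species_support=frozenset({species_id}),
            origin=ORIGIN_STRING,
            gram_group=gram_group,
        )
        prev = edges.get(edge.pair)
        if prev is None or edge.combined_score > prev.combined_score:
            edges[edge.pair] = edge
    if skipped:
        logger.warning("%s: skipped %d unmappable/self rows", path, skipped)
    return [edges[p] for p in sorted(edges)]


_EDGE_COLUMNS = [
    "group_a", "group_b", "combined", "experimental",
    "species_support", "origin", "gram_group",
]


def write_edges_tsv(edges: Iterable[CandidateEdge], path: str | Path) -> Path:
    rows = [
        {
            "group_a": e.group_a,
            "group_b": e.group_b,
            "combined": f"{e.combined_score:.6g}",
            "experimental": f"{e.experimental_score:.6g}",
            "species_support": ",".join(sorted(e.species_support)),
            "origin": e.origin,
            "gram_group": e.gram_group,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_edges_tsv(path: str | Path) -> list[CandidateEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        CandidateEdge(
            row.group_a, row.group_b,
            combined_score=float(row.combined),
            experimental_score=float(row.experimental),
            species_support=frozenset(
                s for s in row.species_support.split(",") if s
            ),
            origin=row.origin,
            gram_group=row.gram_group,
        )
        for row in df.itertuples(index=False)
    ]


def read_family_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "family"} <= set(df.columns):
        raise ValueError(f"{path}: need columns accession, family")
    return dict(zip(df["accession"], df["family"]))


def read_sl_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession_a", "accession_b"} <= set(df.columns):
        raise ValueError(f"{path}: need columns accession_a, accession_b")
    return [(r.accession_a, r.accession_b) for r in df.itertuples(index=False)]


def run_interactome_pipeline(
    essentiality_paths: Sequence[str | Path],
    orthologs_path: str | Path,
    string_paths_by_species: Mapping[str, str | Path],
    families_path: str | Path | None = None,
    sl_pairs_path: str | Path | None = None,
    config: EdgeFilterConfig | None = None,
    gram_group: str = "",
) -> list[CandidateEdge]:
    """End-to-end candidate-interactome assembly from TSV inputs.

    Reads the essentiality tables and ortholog map, compiles the
    consensus essential set, lifts each species' STRING edge list to
    ortholog groups, applies the score / both-essential / family filters
    per species, shortlists the multi-species consensus and finally
    merges the synthetic-lethal pairs.
    """
    config = config or EdgeFilterConfig()
    orthologs = read_ortholog_map_tsv(orthologs_path)
    records: list[EssentialityRecord] = []
    for path in essentiality_paths:
        records.extend(read_essentiality_tsv(path))
    essential = compile_essential_set(records, orthologs,
                                      config.min_essential_species)
    family_groups = (
        families_by_group(read_family_tsv(families_path), orthologs)
        if families_path else {}
    )
    per_species: dict[str, list[CandidateEdge]] = {}
    for species, path in sorted(string_paths_by_species.items()):
        edges = read_string_edges_tsv(path, orthologs, species, gram_group)
        per_species[species] = filter_string_edges(
            edges, essential, config, family_groups
        )
    consensus = consensus_edges(per_species, config.min_species_support)
    if sl_pairs_path:
        consensus = merge_synthetic_lethal(
            consensus, read_sl_pairs_tsv(sl_pairs_path), orthologs
        )
    return consensus
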