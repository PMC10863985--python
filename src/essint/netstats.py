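"""Distribution comparisons and interactome graph assembly.

The selected candidate interactions are contrasted with the random
negative set through their ipTM distributions (ECDF + two-sample
Kolmogorov-Smirnov, per-bin chi-square on the score histogram), models
are tallied per triage category, and the final interactome is assembled
as a simple undirected graph with ipTM/category edge attributes, exported
in Cytoscape-friendly edge-TSV and GraphML form.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .confidence import (
    CATEGORY_HIGH,
    CATEGORY_PLAUSIBLE,
    CATEGORY_UNLIKELY,
    ClassificationThresholds,
    classify_iptm,
)

__all__ = [
    "Ecdf",
    "ecdf",
    "ks_two_sample",
    "chisq_bins",
    "CategorySummary",
    "summarize_categories",
    "build_graph",
    "export_graph",
    "import_graph",
]


@dataclass
class Ecdf:
    """Right-continuous empirical CDF: F(x) = #{values <= x} / n."""

    support: np.ndarray  # sorted unique values
    fractions: np.ndarray  # cumulative fractions, fractions[-1] == 1

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.support, x, side="right")
        out = np.where(idx > 0, self.fractions[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if out.ndim == 0 else out


def ecdf(values: Sequence[float]) -> Ecdf:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    sorted_vals = np.sort(values)
    support, counts = np.unique(sorted_vals, return_counts=True)
    fractions = np.cumsum(counts) / values.size
    return Ecdf(support=support, fractions=fractions)


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 10_000
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with ``D = sup |F_a - F_b|``.  The exact null
    distribution is used when ``n*m <= exact_limit``, the asymptotic one
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= exact_limit else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def chisq_bins(
    counts_selected: Sequence[int],
    counts_random: Sequence[int],
    min_expected: float = 5.0,
):
    """Per-bin chi-square contrast of two binned score distributions.

    For each bin a 2x2 table (in-bin vs out-of-bin, selected vs random)
    is tested without continuity correction.  Returns a list of
    ``(statistic, p, flagged)`` with ``flagged`` set when any expected
    count falls below ``min_expected``.
    """
    sel = np.asarray(counts_selected, dtype=float)
    rnd = np.asarray(counts_random, dtype=float)
    if sel.shape != rnd.shape or sel.ndim != 1:
        raise ValueError("count vectors must be 1-D and equal length")
    n_sel, n_rnd = sel.sum(), rnd.sum()
    if n_sel == 0 or n_rnd == 0:
        raise ValueError("zero total count in one of the samples")
    out = []
    for k in range(sel.size):
        table = np.array([
            [sel[k], n_sel - sel[k]],
            [rnd[k], n_rnd - rnd[k]],
        ])
        if sel[k] == 0 and rnd[k] == 0:
            out.append((0.0, 1.0, True))
            continue
        stat, p, _, expected = stats.chi2_contingency(table, correction=False)
        out.append((float(stat), float(p), bool((expected < min_expected).any())))
    return out


@dataclass
class CategorySummary:
    n_unlikely: int
    n_plausible: int
    n_high: int
    pct_unlikely: float
    pct_plausible: float
    pct_high: float

    @property
    def total(self) -> int:
        return self.n_unlikely + self.n_plausible + self.n_high


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    raw = Decimal(count) * 100 / Decimal(total)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_categories(
    scores: Sequence[float], th: ClassificationThresholds | None = None
) -> CategorySummary:
    """Counts and half-up two-decimal percentages per triage category."""
    th = th or ClassificationThresholds()
    counts = {CATEGORY_UNLIKELY: 0, CATEGORY_PLAUSIBLE: 0, CATEGORY_HIGH: 0}
    for s in scores:
        counts[classify_iptm(float(s), th)] += 1
    total = len(scores)
    return CategorySummary(
        n_unlikely=counts[CATEGORY_UNLIKELY],
        n_plausible=counts[CATEGORY_PLAUSIBLE],
        n_high=counts[CATEGORY_HIGH],
        pct_unlikely=_pct(counts[CATEGORY_UNLIKELY], total),
        pct_plausible=_pct(counts[CATEGORY_PLAUSIBLE], total),
        pct_high=_pct(counts[CATEGORY_HIGH], total),
    )


def build_graph(edges: Iterable[dict]) -> nx.Graph:
    """Assemble the interactome graph from scored edge records.

    Each record needs ``source``, ``target`` and ``iptm``; optional keys
    (``pdockq``, ``pdockq2``, ``category``, ``gram_group``) become edge
    attributes.  Self-loops are rejected; a duplicated pair keeps the
    record with the larger ipTM (mirroring best-model selection).
    """
    graph = nx.Graph()
    for rec in edges:
        u, v = rec["source"], rec["target"]
        if u == v:
            raise ValueError(f"self-loop on {u!r} is not a valid interaction")
        attrs = {k: rec[k] for k in rec if k not in {"source", "target"}}
        if "category" not in attrs and "iptm" in attrs:
            attrs["category"] = classify_iptm(float(attrs["iptm"]))
        if graph.has_edge(u, v) and graph[u][v].get("iptm", -1) >= attrs.get("iptm", 0):
            continue
        graph.add_edge(u, v, **attrs)
    return graph


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write the interactome as GraphML or a Cytoscape edge TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        rows = [
            {"source": u, "target": v, **{k: d[k] for k in sorted(d)}}
            for u, v, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return path


def import_graph(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    """Node degree table, descending — the hub-inspection view."""
    rows = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["protein", "degree"])
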