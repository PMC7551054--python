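"""Feature-based molecular networking: modified cosine and edge filtering.

The modified cosine allows a fragment in one spectrum to match a fragment in
the other either directly or shifted by the precursor mass difference, so
that analogs differing by a single modification still align.  Peak pairs are
weighted by the product of square-root intensities and an exact one-to-one
matching maximizing the summed weight is found by linear assignment; the
score is that optimum normalized by the product of the spectra's
square-root-intensity vector norms (hence in [0, 1]).

Edges survive when the cosine exceeds ``cos_min`` and at least
``min_matched`` peak pairs align; each node then keeps only its ``topk``
strongest edges.  Connected components of the surviving graph are molecular
families.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .spectra_io import Spectrum

__all__ = [
    "EdgeScore",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "export_network",
]


@dataclass(frozen=True)
class EdgeScore:
    """Modified-cosine similarity between two spectra."""

    node_a: str
    node_b: str
    score: float
    matched: int
    precursor_delta: float  # precursor(b) - precursor(a)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-9:
            raise ValueError("cosine score must lie in [0, 1]")
        if self.matched < 0:
            raise ValueError("matched peak count must be >= 0")


def modified_cosine(a: Spectrum, b: Spectrum, frag_tol: float = 0.02) -> EdgeScore:
    """Modified cosine between two spectra with exact optimal peak matching.

    Candidate peak pairs are those within ``frag_tol`` either directly or
    after shifting by the precursor difference; the one-to-one matching
    maximizing the summed sqrt-intensity products is solved exactly by
    linear assignment.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified cosine requires non-empty spectra")
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    shift = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    candidate = (np.abs(diff) <= frag_tol) | (np.abs(diff - shift) <= frag_tol)
    weights = np.where(candidate, wa[:, None] * wb[None, :], 0.0)

    rows = np.flatnonzero(candidate.any(axis=1))
    cols = np.flatnonzero(candidate.any(axis=0))
    score_sum, matched = 0.0, 0
    if rows.size and cols.size:
        sub = weights[np.ix_(rows, cols)]
        ri, ci = linear_sum_assignment(sub, maximize=True)
        for i, j in zip(ri, ci):
            if candidate[rows[i], cols[j]] and sub[i, j] > 0:
                score_sum += sub[i, j]
                matched += 1
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    score = min(score_sum / norm, 1.0) if norm > 0 else 0.0
    return EdgeScore(a.id, b.id, score, matched, b.precursor_mz - a.precursor_mz)


@dataclass
class MolecularNetwork:
    """Scored spectral network; families are connected components."""

    graph: nx.Graph
    families: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def family_members(self, family_id: int) -> list[str]:
        return sorted(n for n, f in self.families.items() if f == family_id)

    def family_of(self, node: str) -> int:
        return self.families[node]


def build_network(
    spectra: Sequence[Spectrum],
    cos_min: float = 0.70,
    min_matched: int = 5,
    topk: int = 10,
    frag_tol: float = 0.02,
) -> MolecularNetwork:
    """Score all spectrum pairs and keep edges passing the GNPS-style rules.

    An edge requires cosine > ``cos_min`` and >= ``min_matched`` matched
    peaks ("more than 4 matched peaks" read as at least 5); afterwards an
    edge survives only if it ranks within the ``topk`` strongest of either
    endpoint.
    """
    if not spectra:
        raise ValueError("at least one spectrum required")
    g = nx.Graph()
    for s in spectra:
        g.add_node(
            s.id,
            precursor_mz=float(s.precursor_mz),
            sample=s.sample or "",
            group=s.group or "",
        )
    edges: list[EdgeScore] = []
    for i in range(len(spectra)):
        if spectra[i].n_peaks == 0:
            continue
        for j in range(i + 1, len(spectra)):
            if spectra[j].n_peaks == 0 or spectra[i].id == spectra[j].id:
                continue
            e = modified_cosine(spectra[i], spectra[j], frag_tol)
            if e.score > cos_min and e.matched >= min_matched:
                edges.append(e)

    # topk rule: an edge survives if within either endpoint's topk by score.
    per_node: dict[str, list[EdgeScore]] = {}
    for e in edges:
        per_node.setdefault(e.node_a, []).append(e)
        per_node.setdefault(e.node_b, []).append(e)
    keep: set[tuple[str, str]] = set()
    for node, node_edges in per_node.items():
        node_edges.sort(key=lambda e: (-e.score, e.node_a, e.node_b))
        for e in node_edges[:topk]:
            keep.add((e.node_a, e.node_b))
    for e in edges:
        if (e.node_a, e.node_b) in keep:
            g.add_edge(
                e.node_a,
                e.node_b,
                cosine=float(e.score),
                matched=int(e.matched),
                precursor_delta=float(e.precursor_delta),
            )

    families: dict[str, int] = {}
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for fid, comp in enumerate(components):
        for node in comp:
            families[node] = fid
    nx.set_node_attributes(g, families, "family")
    return MolecularNetwork(g, families)


def export_network(
    net: MolecularNetwork,
    prefix: str | Path,
    annotations: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write GraphML plus delimited node/edge tables.

    Returns the written paths keyed by kind (graphml, nodes, edges).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = net.graph.copy()
    if annotations:
        for node, text in annotations.items():
            if node in g:
                g.nodes[node]["annotation"] = str(text)
    for _, data in g.nodes(data=True):
        data.setdefault("annotation", "")
    graphml = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml)

    nodes = pd.DataFrame(
        [
            {"node": n, **data}
            for n, data in sorted(g.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"node_a": min(u, v), "node_b": max(u, v), **data}
            for u, v, data in g.edges(data=True)
        ]
    )
    if not edges.empty:
        edges = edges.sort_values(["node_a", "node_b"]).reset_index(drop=True)
    nodes_path = prefix.parent / (prefix.name + "_nodes.tsv")
    edges_path = prefix.parent / (prefix.name + "_edges.tsv")
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    return {"graphml": graphml, "nodes": nodes_path, "edges": edges_path}
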