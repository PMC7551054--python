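"""Dereplication, analog-hypothesis generation and b/y-based annotation.

The workflow mirrors how new natural-product analogs are called from a
molecular network: nodes are first dereplicated against a library of known
compounds by precursor m/z (protonated and sodiated adducts); network edges
from annotated to unannotated nodes are then classified against a table of
characteristic mass offsets (CH2 homologation, Br-for-H substitution, C2H2
chain extension, Na-for-H adduct exchange); finally each candidate node's
MS2 spectrum is matched against the theoretical b/y ladders of the reference
model — allowing fragment shifts by the precursor offset — and nodes with
enough fragment evidence are reported as new analogs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chemformulas import mz_protonated, mz_sodiated
from .depsipeptide import DepsipeptideModel, LibraryCompound, theoretical_spectrum
from .networking import MolecularNetwork
from .spectra_io import FeatureTable, Spectrum

__all__ = [
    "OFFSET_TABLE",
    "LibraryMatch",
    "AnalogHypothesis",
    "AnnotationResult",
    "dereplicate",
    "propose_analogs",
    "annotate_spectrum",
    "group_provenance",
]

#: Characteristic mass offsets (Da) between structural analogs, plus the
#: proton/sodium adduct exchange that bridges [M+H]+ and [M+Na]+ clusters.
OFFSET_TABLE: dict[str, float] = {
    "CH2": 14.015650,
    "C2H2": 26.015650,
    "Br-H": 77.910513,
    "Na-H": 21.981944,
}


@dataclass(frozen=True)
class LibraryMatch:
    compound: LibraryCompound
    adduct: str
    mz: float
    ppm: float


def dereplicate(
    precursor_mz: float,
    library: Sequence[LibraryCompound],
    ppm_tol: float = 5.0,
) -> list[LibraryMatch]:
    """Known compounds whose [M+H]+ or [M+Na]+ falls within ppm_tol."""
    if not library:
        raise ValueError("library must be non-empty")
    out: list[LibraryMatch] = []
    for comp in library:
        for adduct, mz in (
            ("protonated", mz_protonated(comp.formula)),
            ("sodiated", mz_sodiated(comp.formula)),
        ):
            ppm = (precursor_mz - mz) / mz * 1e6
            if abs(ppm) <= ppm_tol:
                out.append(LibraryMatch(comp, adduct, mz, ppm))
    out.sort(key=lambda m: (abs(m.ppm), m.compound.name))
    return out


@dataclass(frozen=True)
class AnalogHypothesis:
    """A candidate explanation of an unannotated node as a known-compound analog."""

    node: str
    reference: str  # compound name, or node id for propagated hypotheses
    reference_node: str | None
    offset_observed: float  # signed: node precursor - reference precursor
    offset_class: str  # key of OFFSET_TABLE, or "none"
    residual: float  # |offset| - table value (Da); offset itself for "none"


def _classify_offset(delta: float, offset_tol: float) -> tuple[str, float]:
    best_class, best_res = "none", float(delta)
    for name, value in OFFSET_TABLE.items():
        res = abs(delta) - value
        if abs(res) <= offset_tol and (best_class == "none" or abs(res) < abs(best_res)):
            best_class, best_res = name, res
    return best_class, best_res


def propose_analogs(
    net: MolecularNetwork,
    annotated: Mapping[str, str],
    offset_tol: float = 0.02,
    propagate: bool = True,
) -> list[AnalogHypothesis]:
    """Classify precursor deltas on edges from annotated to unannotated nodes.

    ``annotated`` maps node id -> reference compound name.  Every edge
    between an annotated and an unannotated node yields one hypothesis
    (class ``"none"`` when the delta matches nothing in the offset table).
    With ``propagate`` enabled, nodes that received a classified hypothesis
    act as secondary references for their still-unexplained neighbors, so
    chains such as known -> CH2 analog -> dibrominated CH2 analog are fully
    classified; the result is independent of node order within each edge.
    """
    if not annotated:
        raise ValueError("network has no annotated node")
    g = net.graph
    hypotheses: list[AnalogHypothesis] = []
    seen: set[tuple[str, str]] = set()

    def emit(ref_node: str, ref_label: str, node: str) -> AnalogHypothesis:
        delta = g.nodes[node]["precursor_mz"] - g.nodes[ref_node]["precursor_mz"]
        cls, res = _classify_offset(delta, offset_tol)
        return AnalogHypothesis(node, ref_label, ref_node, delta, cls, res)

    frontier = {n: annotated[n] for n in annotated if n in g}
    referenced = set(frontier)
    while frontier:
        next_frontier: dict[str, str] = {}
        for ref_node in sorted(frontier):
            for nb in sorted(g.neighbors(ref_node)):
                if nb in annotated or (ref_node, nb) in seen:
                    continue
                seen.add((ref_node, nb))
                hyp = emit(ref_node, frontier[ref_node], nb)
                hypotheses.append(hyp)
                if nb not in referenced and nb not in next_frontier:
                    # Classified nodes relay under a composite compound label;
                    # unclassified ones relay anonymously so that e.g. two
                    # unassigned nodes a Br-H step apart still get compared.
                    if hyp.offset_class != "none":
                        next_frontier[nb] = f"{frontier[ref_node]}+{hyp.offset_class}"
                    else:
                        next_frontier[nb] = f"node:{nb}"
        if not propagate:
            break
        referenced.update(next_frontier)
        frontier = next_frontier
    hypotheses.sort(key=lambda h: (h.node, abs(h.residual), h.reference))
    return hypotheses


@dataclass(frozen=True)
class AnnotationResult:
    """Per-node verdict after fragment-level verification."""

    node: str
    status: str  # "library-match" | "new-analog" | "unknown"
    model: str  # label of the model annotated against ("" if none)
    matched: int
    total: int
    ppm: float  # precursor ppm error vs the (offset-corrected) reference
    br_count: int | None = None
    hypothesis: AnalogHypothesis | None = None

    def __post_init__(self) -> None:
        if self.matched > self.total:
            raise ValueError("matched cannot exceed total fragments")


def annotate_spectrum(
    s: Spectrum,
    m: DepsipeptideModel,
    frag_tol: float = 0.02,
    min_fragment_matches: int = 6,
    ppm_tol: float = 5.0,
    precursor_shift: float = 0.0,
    hypothesis: AnalogHypothesis | None = None,
) -> AnnotationResult:
    """Match a spectrum against a model's theoretical b/y fragments.

    Each theoretical fragment may be satisfied by at most one observed peak
    (and vice versa), either directly or shifted by ``precursor_shift`` (the
    analog mass offset); conflicts resolve to the smallest |error|.  The
    verdict is ``library-match`` when the precursor matches the model within
    ``ppm_tol`` and enough fragments match; ``new-analog`` when fragments
    match under a shift explained by an analog hypothesis; else ``unknown``.
    """
    theo = theoretical_spectrum(m)
    total = theo.n_peaks
    candidates: list[tuple[float, int, int]] = []
    shifts = (0.0,) if precursor_shift == 0.0 else (0.0, precursor_shift)
    for ti, tmz in enumerate(theo.mz):
        for shift in shifts:
            target = tmz + shift
            for oi, omz in enumerate(s.mz):
                err = abs(omz - target)
                if err <= frag_tol:
                    candidates.append((err, ti, oi))
    candidates.sort()
    used_t: set[int] = set()
    used_o: set[int] = set()
    matched = 0
    for err, ti, oi in candidates:
        if ti in used_t or oi in used_o:
            continue
        used_t.add(ti)
        used_o.add(oi)
        matched += 1

    expected = theo.precursor_mz + precursor_shift
    ppm = (s.precursor_mz - expected) / expected * 1e6
    if matched >= min_fragment_matches and abs(ppm) <= ppm_tol:
        status = "library-match" if precursor_shift == 0.0 else "new-analog"
    else:
        status = "unknown"
    if status == "new-analog" and hypothesis is None:
        status = "unknown"
    return AnnotationResult(
        node=s.id,
        status=status,
        model=m.label or m.sequence(),
        matched=matched,
        total=total,
        ppm=ppm,
        hypothesis=hypothesis,
    )


def group_provenance(
    ft: FeatureTable,
    presence_threshold: float = 1.0,
) -> list[str]:
    """Provenance class per feature from the sample-group intensity pattern.

    A feature is present in a group when any member sample reaches the
    threshold.  Features present in the medium control are classed
    ``control``; otherwise presence in monoculture and/or interaction
    samples yields ``shared``, ``monoculture-only`` or ``interaction-only``.
    """
    if any(not grp for grp in ft.groups):
        raise ValueError("every sample needs a group label")
    kinds = []
    for grp in ft.groups:
        if grp == "monoculture":
            kinds.append("mono")
        elif grp.startswith("interaction"):
            kinds.append("inter")
        elif grp == "control":
            kinds.append("control")
        else:
            raise ValueError(f"unrecognized group label {grp!r}")
    kinds_arr = np.array(kinds)
    out: list[str] = []
    for row in ft.intensities:
        present = set(kinds_arr[np.asarray(row) >= presence_threshold])
        if "control" in present:
            out.append("control")
        elif {"mono", "inter"} <= present:
            out.append("shared")
        elif "mono" in present:
            out.append("monoculture-only")
        elif "inter" in present:
            out.append("interaction-only")
        else:
            out.append("absent")
    return out
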