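"""End-to-end workflow: read spectra, network, dereplicate, call analogs.

Stages: read MGF input (intensity floor applied) -> build the molecular
network -> dereplicate nodes against the known-compound library (protonated
and sodiated adducts) -> classify precursor offsets on edges from annotated
into unannotated territory, propagating so analog-of-analog chains resolve
-> verify candidates at the fragment level against the reference
depsipeptide model -> export GraphML, node/edge/annotation tables and a
stage-count summary.  Outputs carry no timestamps, so identical inputs and
configuration reproduce identical files.
"""
from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .annotation import (
    OFFSET_TABLE,
    AnalogHypothesis,
    AnnotationResult,
    annotate_spectrum,
    dereplicate,
    group_provenance,
    propose_analogs,
)
from .chemformulas import mz_protonated, mz_sodiated
from .depsipeptide import LibraryCompound, load_compound_library, precursor_mz
from .networking import MolecularNetwork, build_network, export_network
from .spectra_io import FeatureTable, Spectrum, read_mgf

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage threshold in one place; unknown keys are rejected."""

    ppm_tol: float = 5.0  # precursor tolerance for dereplication
    frag_tol: float = 0.02  # fragment m/z tolerance (Da)
    cos_min: float = 0.70  # minimum modified cosine for an edge
    min_matched: int = 5  # minimum matched peaks per edge (> 4)
    topk: int = 10  # strongest edges kept per node
    offset_tol: float = 0.02  # analog mass-offset tolerance (Da)
    min_fragment_matches: int = 6  # fragment evidence for a new-analog call
    ms2_intensity_floor: float = 500.0  # MS2 signal threshold on read
    presence_threshold: float = 5.0e3  # MS1 presence threshold for provenance
    seed: int = 42

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "seed"
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    spectra: list[Spectrum]
    network: MolecularNetwork | None
    annotations: dict[str, AnnotationResult]
    hypotheses: list[AnalogHypothesis]
    library_matches: dict[str, str]  # node -> compound name
    provenance: list[str] = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)

    def summary_lines(self) -> list[str]:
        statuses = [a.status for a in self.annotations.values()]
        lines = [
            f"spectra read: {len(self.spectra)}",
            f"network nodes: {self.network.n_nodes if self.network else 0}",
            f"network edges: {self.network.n_edges if self.network else 0}",
            f"molecular families: {len(set(self.network.families.values())) if self.network else 0}",
            f"library matches: {statuses.count('library-match')}",
            f"new analogs: {statuses.count('new-analog')}",
            f"unknown nodes: {statuses.count('unknown')}",
        ]
        if self.provenance:
            for cls in ("monoculture-only", "interaction-only", "shared", "control"):
                lines.append(f"provenance {cls}: {self.provenance.count(cls)}")
        return lines


def _expected_precursors(
    annotated_mz: dict[str, float],
    hypotheses: Sequence[AnalogHypothesis],
) -> dict[str, tuple[float, AnalogHypothesis]]:
    """Propagate theoretical precursor values along classified offset chains."""
    expected: dict[str, tuple[float, AnalogHypothesis]] = {}
    pending = [h for h in hypotheses if h.offset_class != "none"]
    progress = True
    while progress:
        progress = False
        for h in pending:
            if h.node in expected:
                continue
            ref = h.reference_node
            if ref in annotated_mz:
                base = annotated_mz[ref]
            elif ref in expected:
                base = expected[ref][0]
            else:
                continue
            sign = 1.0 if h.offset_observed >= 0 else -1.0
            expected[h.node] = (base + sign * OFFSET_TABLE[h.offset_class], h)
            progress = True
    return expected


def run_pipeline(
    mgf_paths: Sequence[str | Path],
    cfg: PipelineConfig | None = None,
    library: Sequence[LibraryCompound] | None = None,
    out_dir: str | Path | None = None,
    feature_table: FeatureTable | None = None,
    log=lambda msg: print(msg, file=sys.stderr),
) -> PipelineResult:
    """Run the full discovery workflow over MGF files.

    ``library`` defaults to the packaged known-compound library (records
    flagged as reference compounds).  When a feature table is supplied,
    per-feature provenance classes are computed as well.  Empty input yields
    empty outputs rather than an error.
    """
    cfg = cfg or PipelineConfig()
    if library is None:
        library = [c for c in load_compound_library() if c.known]
    spectra: list[Spectrum] = []
    for path in mgf_paths:
        try:
            spectra.extend(read_mgf(path, min_intensity=cfg.ms2_intensity_floor))
        except ValueError as err:
            raise ValueError(f"stage read: {path}: {err}") from err
    log(f"read {len(spectra)} spectra from {len(mgf_paths)} files")

    result = PipelineResult(spectra, None, {}, [], {})
    if not spectra:
        if out_dir is not None:
            _export(result, cfg, out_dir)
        return result

    by_id = {s.id: s for s in spectra}
    net = build_network(
        spectra,
        cos_min=cfg.cos_min,
        min_matched=cfg.min_matched,
        topk=cfg.topk,
        frag_tol=cfg.frag_tol,
    )
    result.network = net
    log(f"network: {net.n_nodes} nodes, {net.n_edges} edges")

    # Dereplication against the known library.
    models = {c.name: c for c in library}
    annotated: dict[str, str] = {}
    annotated_mz: dict[str, float] = {}
    for s in spectra:
        matches = dereplicate(s.precursor_mz, library, ppm_tol=cfg.ppm_tol)
        if not matches:
            continue
        best = matches[0]
        annotated[s.id] = best.compound.name
        annotated_mz[s.id] = best.mz
        result.library_matches[s.id] = best.compound.name
        if best.compound.model is not None:
            result.annotations[s.id] = annotate_spectrum(
                s,
                best.compound.model,
                frag_tol=cfg.frag_tol,
                min_fragment_matches=cfg.min_fragment_matches,
                ppm_tol=cfg.ppm_tol,
            )
        else:
            result.annotations[s.id] = AnnotationResult(
                s.id, "library-match", best.compound.name, 0, 0, best.ppm
            )
    log(f"dereplicated {len(annotated)} nodes")

    # Analog hypotheses along network edges, with propagation.
    if annotated:
        result.hypotheses = propose_analogs(net, annotated, offset_tol=cfg.offset_tol)
    expected = _expected_precursors(annotated_mz, result.hypotheses)

    for node, (exp_mz, hyp) in sorted(expected.items()):
        s = by_id[node]
        root_name = hyp.reference.split("+")[0]
        root = models.get(root_name)
        if root is not None and root.model is not None:
            shift = exp_mz - precursor_mz(root.model)
            ann = annotate_spectrum(
                s,
                root.model,
                frag_tol=cfg.frag_tol,
                min_fragment_matches=cfg.min_fragment_matches,
                ppm_tol=cfg.ppm_tol,
                precursor_shift=shift,
                hypothesis=hyp,
            )
        else:
            ppm = (s.precursor_mz - exp_mz) / exp_mz * 1e6
            status = "new-analog" if abs(ppm) <= cfg.ppm_tol else "unknown"
            ann = AnnotationResult(node, status, hyp.reference, 0, 0, ppm, hypothesis=hyp)
        result.annotations[node] = ann
    for s in spectra:
        if s.id not in result.annotations:
            result.annotations[s.id] = AnnotationResult(s.id, "unknown", "", 0, 0, 0.0)
    log(
        "annotation: "
        + ", ".join(
            f"{k}={sum(1 for a in result.annotations.values() if a.status == k)}"
            for k in ("library-match", "new-analog", "unknown")
        )
    )

    if feature_table is not None:
        result.provenance = group_provenance(feature_table, cfg.presence_threshold)

    if out_dir is not None:
        _export(result, cfg, out_dir)
    return result


def _export(result: PipelineResult, cfg: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.network is not None:
        labels = {
            node: (
                result.library_matches.get(node)
                or (ann.hypothesis.reference + "+" + ann.hypothesis.offset_class
                    if ann.hypothesis else "")
            )
            for node, ann in result.annotations.items()
        }
        result.paths.update(export_network(result.network, out / "network", labels))

    rows = []
    for node in sorted(result.annotations):
        ann = result.annotations[node]
        hyp = ann.hypothesis
        rows.append(
            {
                "node": node,
                "precursor_mz": round(
                    result.network.graph.nodes[node]["precursor_mz"], 4
                ) if result.network and node in result.network.graph else "",
                "status": ann.status,
                "reference": ann.model or (hyp.reference if hyp else ""),
                "offset_class": hyp.offset_class if hyp else "",
                "offset_observed": round(hyp.offset_observed, 4) if hyp else "",
                "matched": ann.matched,
                "total": ann.total,
                "ppm": round(ann.ppm, 2),
            }
        )
    ann_path = out / "annotations.tsv"
    pd.DataFrame(rows).to_csv(ann_path, sep="\t", index=False)
    result.paths["annotations"] = ann_path

    hyp_rows = [
        {
            "node": h.node,
            "reference": h.reference,
            "reference_node": h.reference_node or "",
            "offset_observed": round(h.offset_observed, 4),
            "offset_class": h.offset_class,
            "residual": round(h.residual, 4),
        }
        for h in result.hypotheses
    ]
    hyp_path = out / "analog_hypotheses.tsv"
    pd.DataFrame(
        hyp_rows,
        columns=["node", "reference", "reference_node", "offset_observed",
                 "offset_class", "residual"],
    ).to_csv(hyp_path, sep="\t", index=False)
    result.paths["hypotheses"] = hyp_path

    summary_path = out / "summary.log"
    summary_path.write_text("\n".join(result.summary_lines()) + "\n")
    result.paths["summary"] = summary_path
    cfg.to_yaml(out / "pipeline_config.yaml")
    result.paths["config"] = out / "pipeline_config.yaml"
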