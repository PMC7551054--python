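"""Ground-truth simulator for bromoalterochromide-style interaction studies.

Real interaction metabolomics data for these strains lives in a public raw
deposit; this module emulates its structure at desk scale so every pipeline
stage can be tested against known truth: MS2 spectra built from the
depsipeptide fragmentation model (b/y ladders from two ring openings, a
boosted aryl-polyene elimination base peak, log-normal fragment intensities,
uniform noise peaks, ppm-scale mass jitter), MS1 bromine isotope clusters,
and a sample layout of monoculture, four interaction testers and a medium
control in which the depsipeptides are produced more intensely during
interactions.

All randomness flows from ``SimulationConfig.seed``; repeated runs are
byte-identical.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .chemformulas import (
    ELECTRON_MASS,
    MolecularFormula,
    isotopologue_pattern,
    parse_formula,
)
from .depsipeptide import (
    RESIDUES,
    DepsipeptideModel,
    LibraryCompound,
    cyclic_formula,
    load_compound_library,
    precursor_mz,
    theoretical_spectrum,
)
from .spectra_io import FeatureTable, Spectrum, write_mgf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyResult",
    "generate_compound_set",
    "simulate_ms2",
    "simulate_ms1_cluster",
    "simulate_study",
]

_BASE_ACYL = {
    ("A", 1): "C15H11BrO2",
    ("A", 2): "C15H10Br2O2",
    ("B", 1): "C17H13BrO2",
    ("B", 2): "C17H12Br2O2",
}
_BASE_ELIMINATION = {
    ("A", 1): 210.9567,
    ("A", 2): 288.8672,
    ("B", 1): 236.9724,
    ("B", 2): 314.8829,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; the seed fixes every random draw."""

    seed: int = 42
    n_extra_analogs: int = 0  # random residue/acyl variants beyond the 12 library compounds
    n_decoys: int = 8  # unrelated random spectra
    position2_pool: tuple[str, ...] = ("Val", "Xle")
    br_counts: tuple[int, ...] = (1, 2)
    series: tuple[str, ...] = ("A", "B")
    intensity_log_mean: float = float(np.log(2.0e4))  # log-normal mu for b/y peaks
    intensity_log_sigma: float = 0.7
    elimination_boost: float = 8.0  # base peak = boost x strongest other peak
    noise_peaks: int = 10
    noise_intensity_scale: float = 500.0  # exponential scale, below 10x the MS2 floor
    mz_jitter_ppm: float = 3.0
    ms1_noise: float = 0.05  # multiplicative isotope-intensity noise
    samples_per_group: int = 1
    testers: tuple[str, ...] = ("C.albicans", "A.fumigatus", "S.aureus", "E.coli")
    interaction_multiplier: float = 3.0
    feature_log_mean: float = float(np.log(2.0e5))  # per-compound MS1 abundance
    feature_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.mz_jitter_ppm < 0 or self.ms1_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if self.interaction_multiplier < 1:
            raise ValueError("interaction multiplier must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth for every generated compound and spectrum."""

    compounds: dict[str, dict] = field(default_factory=dict)  # label -> facts
    spectra: dict[str, dict] = field(default_factory=dict)  # spectrum id -> facts

    def provenance(self, label: str) -> str:
        return self.compounds[label]["provenance"]


def _slug(name: str) -> str:
    return name.replace(" ", "_").replace("'", "p")


def generate_compound_set(
    cfg: SimulationConfig,
) -> tuple[list[DepsipeptideModel], GroundTruth]:
    """The 12 bromoalterochromide models plus optional random variants.

    Analog ground truth: the D-series compounds are CH2 homologs of the A
    series, and every dibrominated compound is the Br-for-H analog of its
    mono-brominated parent.
    """
    library = load_compound_library()
    truth = GroundTruth()
    models: list[DepsipeptideModel] = []
    for comp in library:
        if comp.model is None:
            continue
        models.append(comp.model)
        analog_class, reference = "", ""
        if not comp.known:
            if comp.br_count == 2:
                analog_class, reference = "Br-H", comp.name.replace("dibromo", "bromo")
            else:
                analog_class, reference = "CH2", comp.name.replace(" D", " A")
        truth.compounds[comp.name] = {
            "formula": str(comp.formula),
            "br": comp.br_count,
            "series": comp.series,
            "known": comp.known,
            "analog_class": analog_class,
            "reference": reference,
        }
    rng = np.random.default_rng(cfg.seed)
    for k in range(cfg.n_extra_analogs):
        pos2 = str(rng.choice(list(cfg.position2_pool)))
        br = int(rng.choice(list(cfg.br_counts)))
        ser = str(rng.choice(list(cfg.series)))
        label = f"variant-{k+1} ({ser}{br} {pos2})"
        model = DepsipeptideModel(
            acyl=parse_formula(_BASE_ACYL[(ser, br)]),
            residues=(
                RESIDUES["Thr"], RESIDUES[pos2], RESIDUES["Asn"],
                RESIDUES["Asn"], RESIDUES["Xle"],
            ),
            label=label,
            elimination_mz=_BASE_ELIMINATION[(ser, br)],
        )
        models.append(model)
        truth.compounds[label] = {
            "formula": str(cyclic_formula(model)),
            "br": br,
            "series": ser,
            "known": False,
            "analog_class": "",
            "reference": "",
        }
    return models, truth


def simulate_ms2(
    m: DepsipeptideModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str | None = None,
    sample: str | None = None,
    group: str | None = None,
    rt: float | None = None,
    intensity_scale: float = 1.0,
) -> Spectrum:
    """One noisy MS2 spectrum of a model.

    Theoretical fragments get log-normal intensities, the elimination ion is
    boosted to the base peak, noise peaks are added uniformly in m/z with
    exponential intensities, and every m/z (precursor included) is jittered
    by Gaussian ppm noise.
    """
    theo = theoretical_spectrum(m)
    mz = np.array(theo.mz, dtype=float)
    intensity = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sigma, mz.size)
    if m.elimination_mz is not None or m.elimination_formula is not None:
        from .depsipeptide import elimination_ion

        elim_mz = elimination_ion(m).mz
        idx = int(np.argmin(np.abs(mz - elim_mz)))
        others = np.delete(intensity, idx)
        intensity[idx] = cfg.elimination_boost * (others.max() if others.size else 1.0)
    n_noise = cfg.noise_peaks
    noise_mz = rng.uniform(100.0, theo.precursor_mz, n_noise)
    noise_int = rng.exponential(cfg.noise_intensity_scale, n_noise)
    all_mz = np.concatenate([mz, noise_mz])
    all_int = np.concatenate([intensity, noise_int]) * intensity_scale
    jitter = rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, all_mz.size + 1)
    all_mz = all_mz * (1.0 + jitter[:-1])
    prec = theo.precursor_mz * (1.0 + jitter[-1])
    return Spectrum(
        id=spectrum_id or _slug(m.label or m.sequence()),
        precursor_mz=float(prec),
        charge=1,
        rt=rt,
        mz=all_mz,
        intensity=all_int,
        sample=sample,
        group=group,
    )


def simulate_ms1_cluster(
    f: MolecularFormula,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    as_ion: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy MS1 isotope cluster of a (protonated, by default) molecule."""
    ion = f + MolecularFormula({"H": 1}) if as_ion else f
    pattern = isotopologue_pattern(ion)
    mz = np.array(pattern.mz) - (ELECTRON_MASS if as_ion else 0.0)
    intensity = np.array(pattern.intensity) * (
        1.0 + rng.normal(0.0, cfg.ms1_noise, len(pattern.mz))
    )
    intensity = np.clip(intensity, 1e-6, None)
    return mz, intensity


@dataclass
class StudyResult:
    """Everything simulate_study produced, in memory plus on disk."""

    spectra: list[Spectrum]
    feature_table: FeatureTable
    ground_truth: GroundTruth
    sample_ids: list[str]
    groups: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _sample_layout(cfg: SimulationConfig) -> list[tuple[str, str]]:
    layout: list[tuple[str, str]] = []
    for i in range(cfg.samples_per_group):
        layout.append((f"mono-{i+1:02d}", "monoculture"))
    for tester in cfg.testers:
        for i in range(cfg.samples_per_group):
            layout.append((f"inter-{tester}-{i+1:02d}", f"interaction:{tester}"))
    for i in range(cfg.samples_per_group):
        layout.append((f"control-{i+1:02d}", "control"))
    return layout


def simulate_study(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Simulate a full interaction study and (optionally) write it to disk.

    Bromoalterochromides are planted as shared between monoculture and all
    interaction testers, with interaction intensities scaled by
    ``interaction_multiplier``; decoy compounds rotate through
    interaction-only, monoculture-only and control provenances.  Outputs:
    one MGF per sample, the aligned feature table, ground-truth tables and
    the configuration as YAML.
    """
    models, truth = generate_compound_set(cfg)
    rng = np.random.default_rng(cfg.seed)
    layout = _sample_layout(cfg)
    sample_ids = [s for s, _ in layout]
    groups = [g for _, g in layout]

    compounds: list[dict] = []
    for m in models:
        compounds.append(
            {
                "label": m.label,
                "model": m,
                "mz": precursor_mz(m),
                "rt": float(rng.uniform(1.0, 12.0)),
                "abundance": float(rng.lognormal(cfg.feature_log_mean, cfg.feature_log_sigma)),
                "provenance": "shared",
                "br": truth.compounds[m.label]["br"],
            }
        )
        truth.compounds[m.label]["provenance"] = "shared"

    decoy_classes = ("interaction-only", "monoculture-only", "control")
    for k in range(cfg.n_decoys):
        prov = decoy_classes[k % len(decoy_classes)]
        label = f"decoy-{k+1:02d}"
        prec = float(rng.uniform(300.0, 1200.0))
        n_pk = int(rng.integers(18, 30))
        base_mz = np.sort(rng.uniform(100.0, prec, n_pk))
        base_int = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sigma, n_pk)
        compounds.append(
            {
                "label": label,
                "model": None,
                "mz": prec,
                "rt": float(rng.uniform(1.0, 12.0)),
                "abundance": float(rng.lognormal(cfg.feature_log_mean, cfg.feature_log_sigma)),
                "provenance": prov,
                "decoy_mz": base_mz,
                "decoy_int": base_int,
                "tester": cfg.testers[k % len(cfg.testers)],
                "br": 0,
            }
        )
        truth.compounds[label] = {
            "formula": "",
            "br": 0,
            "series": "",
            "known": False,
            "analog_class": "",
            "reference": "",
            "provenance": prov,
        }

    def present_in(comp: dict, group: str) -> bool:
        prov = comp["provenance"]
        if prov == "shared":
            return group == "monoculture" or group.startswith("interaction")
        if prov == "monoculture-only":
            return group == "monoculture"
        if prov == "interaction-only":
            return group == f"interaction:{comp['tester']}"
        if prov == "control":
            return group == "control"
        raise AssertionError(prov)

    n_feat = len(compounds)
    intensities = np.zeros((n_feat, len(layout)))
    per_sample: dict[str, list[Spectrum]] = {s: [] for s in sample_ids}
    ms2_ids: list[str | None] = [None] * n_feat

    for fi, comp in enumerate(compounds):
        best_sample, best_level = None, -1.0
        for sj, (sample, group) in enumerate(layout):
            if not present_in(comp, group):
                continue
            level = comp["abundance"] * (1.0 + rng.normal(0.0, 0.1))
            if group.startswith("interaction") and comp["provenance"] == "shared":
                level *= cfg.interaction_multiplier
            level = max(level, 0.0)
            intensities[fi, sj] = level
            sid = f"{sample}:{_slug(comp['label'])}"
            if comp["model"] is not None:
                spec = simulate_ms2(
                    comp["model"], cfg, rng,
                    spectrum_id=sid, sample=sample, group=group,
                    rt=comp["rt"] + float(rng.normal(0.0, 0.02)),
                )
                n_noise = cfg.noise_peaks
            else:
                jit = rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, comp["decoy_mz"].size + 1)
                spec = Spectrum(
                    id=sid,
                    precursor_mz=comp["mz"] * (1.0 + float(jit[-1])),
                    charge=1,
                    rt=comp["rt"] + float(rng.normal(0.0, 0.02)),
                    mz=comp["decoy_mz"] * (1.0 + jit[:-1]),
                    intensity=comp["decoy_int"]
                    * np.exp(rng.normal(0.0, 0.1, comp["decoy_int"].size)),
                    sample=sample,
                    group=group,
                )
                n_noise = 0
            per_sample[sample].append(spec)
            truth.spectra[sid] = {
                "label": comp["label"],
                "sample": sample,
                "group": group,
                "br": comp["br"],
                "n_noise_peaks": n_noise,
            }
            if level > best_level:
                best_sample, best_level = sid, level
        ms2_ids[fi] = best_sample

    table = FeatureTable(
        mz=np.array([c["mz"] for c in compounds]),
        rt=np.array([c["rt"] for c in compounds]),
        intensities=intensities,
        sample_ids=sample_ids,
        groups=groups,
        br_counts=[c["br"] for c in compounds],
        ms2_ids=ms2_ids,
    )

    spectra = [s for sample in sample_ids for s in per_sample[sample]]
    result = StudyResult(spectra, table, truth, sample_ids, groups)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample in sample_ids:
            p = out / f"{sample}.mgf"
            write_mgf(per_sample[sample], p)
            result.paths[sample] = p
        ft_path = out / "feature_table.tsv"
        table.write_tsv(ft_path)
        result.paths["feature_table"] = ft_path
        truth_path = out / "ground_truth_compounds.tsv"
        with open(truth_path, "w") as fh:
            fh.write("label\tformula\tbr\tseries\tknown\tprovenance\tanalog_class\treference\n")
            for label, facts in truth.compounds.items():
                fh.write(
                    f"{label}\t{facts['formula']}\t{facts['br']}\t{facts['series']}\t"
                    f"{int(facts['known'])}\t{facts.get('provenance', '')}\t"
                    f"{facts['analog_class']}\t{facts['reference']}\n"
                )
        result.paths["ground_truth"] = truth_path
        spectra_path = out / "ground_truth_spectra.tsv"
        with open(spectra_path, "w") as fh:
            fh.write("id\tlabel\tsample\tgroup\tbr\tn_noise_peaks\n")
            for sid, facts in truth.spectra.items():
                fh.write(
                    f"{sid}\t{facts['label']}\t{facts['sample']}\t{facts['group']}\t"
                    f"{facts['br']}\t{facts['n_noise_peaks']}\n"
                )
        result.paths["ground_truth_spectra"] = spectra_path
        cfg_path = out / "config.yaml"
        cfg_dict = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(cfg).items()
        }
        cfg_path.write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
        result.paths["config"] = cfg_path
    return result
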