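"""Spectrum/feature containers, MGF I/O, isotope grouping and join alignment.

Spectra travel as Mascot Generic Format (MGF); sample and group metadata are
carried in the TITLE line as ``key=value`` tokens so a round trip through
disk is lossless.  Isotope grouping and join alignment mirror the
MZmine-style feature processing used for feature-based molecular networking:
MS1 peaks whose spacings match 13C (+1.00336 Da) or 81Br (+1.99795 Da)
chains collapse to one monoisotopic feature, and per-sample feature lists
are aligned greedily within m/z and retention-time tolerances.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

from .chemformulas import IsotopePattern, infer_bromine_count

__all__ = [
    "Peak",
    "Spectrum",
    "Feature",
    "FeatureTable",
    "read_mgf",
    "write_mgf",
    "group_isotopes",
    "join_align",
]

#: 13C - 12C spacing of carbon isotopologues (Da).
C13_DELTA = 1.00335484
#: 81Br - 79Br spacing (Da).
BR81_DELTA = 1.99795300


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """Centroided MS2 spectrum with precursor and provenance metadata."""

    id: str
    precursor_mz: float
    charge: int = 1
    rt: float | None = None  # minutes
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    sample: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size and np.any(np.diff(self.mz) < 1e-6):
            keep = np.concatenate([[True], np.diff(self.mz) >= 1e-6])
            self.mz, self.intensity = self.mz[keep], self.intensity[keep]
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("invalid peak values")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak_mz(self) -> float:
        if not self.n_peaks:
            raise ValueError("empty spectrum has no base peak")
        return float(self.mz[int(np.argmax(self.intensity))])

    def filtered(self, min_intensity: float) -> "Spectrum":
        keep = self.intensity >= min_intensity
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])


def _title_string(s: Spectrum) -> str:
    parts = [f"id={s.id}"]
    if s.sample is not None:
        parts.append(f"sample={s.sample}")
    if s.group is not None:
        parts.append(f"group={s.group}")
    return " ".join(parts)


def _parse_title(title: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in title.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_mgf(path: str | Path, min_intensity: float = 0.0) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    Metadata is recovered from ``key=value`` tokens in TITLE; a missing
    CHARGE defaults to 1+.  Peaks below ``min_intensity`` are dropped (the
    spectra themselves are kept even if all their peaks are filtered away).
    """
    spectra: list[Spectrum] = []
    with _pymgf.read(str(path), use_index=False) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {idx}: missing PEPMASS")
            pepmass = float(params["pepmass"][0])
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = None
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            meta = _parse_title(str(params.get("title", "")))
            spec = Spectrum(
                id=meta.get("id", f"scan{idx}"),
                precursor_mz=pepmass,
                charge=charge,
                rt=rt,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                sample=meta.get("sample"),
                group=meta.get("group"),
            )
            if min_intensity > 0:
                spec = spec.filtered(min_intensity)
            spectra.append(spec)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with 4-decimal m/z and metadata in TITLE.

    The writer is deterministic byte for byte for identical inputs.
    """
    buf = io.StringIO()
    for s in spectra:
        buf.write("BEGIN IONS\n")
        buf.write(f"TITLE={_title_string(s)}\n")
        buf.write(f"PEPMASS={s.precursor_mz:.4f}\n")
        buf.write(f"CHARGE={s.charge}+\n")
        if s.rt is not None:
            buf.write(f"RTINSECONDS={s.rt * 60.0:.2f}\n")
        for m, i in zip(s.mz, s.intensity):
            buf.write(f"{m:.4f} {i:.4f}\n")
        buf.write("END IONS\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class Feature:
    """A deisotoped MS1 feature from one sample."""

    mz: float
    rt: float
    intensity: float
    br_count: int | None = None
    ms2_id: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.intensity < 0:
            raise ValueError("feature intensity must be non-negative")


@dataclass
class FeatureTable:
    """Features aligned across samples: one intensity column per sample."""

    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray  # shape (n_features, n_samples)
    sample_ids: list[str]
    groups: list[str]
    br_counts: list[int | None] = field(default_factory=list)
    ms2_ids: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        n, s = self.intensities.shape
        if len(self.sample_ids) != s or len(self.groups) != s:
            raise ValueError("sample ids/groups must match intensity columns")
        if self.mz.size != n or self.rt.size != n:
            raise ValueError("per-feature arrays must match intensity rows")
        if not self.br_counts:
            self.br_counts = [None] * n
        if not self.ms2_ids:
            self.ms2_ids = [None] * n

    @property
    def n_features(self) -> int:
        return int(self.mz.size)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": [f"F{i+1:04d}" for i in range(self.n_features)],
                "mz": np.round(self.mz, 4),
                "rt": np.round(self.rt, 3),
                "br_count": [b if b is not None else "" for b in self.br_counts],
                "ms2_id": [m if m is not None else "" for m in self.ms2_ids],
            }
        )
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.intensities[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# groups: " + "\t".join(self.groups) + "\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        with open(path) as fh:
            header = fh.readline()
            groups = header.removeprefix("# groups:").strip().split("\t")
            df = pd.read_csv(fh, sep="\t")
        meta_cols = ["feature_id", "mz", "rt", "br_count", "ms2_id"]
        sample_ids = [c for c in df.columns if c not in meta_cols]
        return cls(
            mz=df["mz"].to_numpy(),
            rt=df["rt"].to_numpy(),
            intensities=df[sample_ids].to_numpy(),
            sample_ids=sample_ids,
            groups=groups,
            br_counts=[None if pd.isna(b) or b == "" else int(b) for b in df["br_count"]],
            ms2_ids=[None if pd.isna(m) or m == "" else str(m) for m in df["ms2_id"]],
        )


# Single isotopologue steps: one or two 13C, or one 81Br.  Longer chains
# connect transitively through intermediate peaks; allowing arbitrary
# combinations would blanket near-integer spacings and over-merge.
_ISOTOPE_STEPS = (C13_DELTA, 2 * C13_DELTA, BR81_DELTA)


def _isotope_step(delta: float, mz_tol: float) -> bool:
    """Is delta consistent with a single 13C/81Br isotopologue step?"""
    return any(abs(delta - step) <= mz_tol for step in _ISOTOPE_STEPS)


def group_isotopes(
    peaks: Sequence[tuple[float, float, float]] | Sequence[Feature],
    mz_tol: float = 0.005,
    rt_tol: float = 0.20,
    max_br: int = 3,
) -> list[Feature]:
    """Collapse isotopologue peaks into monoisotopic features with Br tags.

    ``peaks`` is a sequence of ``(mz, rt, intensity)`` triples (or Feature
    objects).  Co-eluting peaks (|ΔRT| <= rt_tol) whose m/z spacings match
    13C/81Br chains within ``mz_tol`` form one feature positioned at the
    lightest member; the member intensities are summed and the bromine count
    is inferred from the cluster's intensity pattern.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    items: list[tuple[float, float, float]] = []
    for p in peaks:
        if isinstance(p, Feature):
            items.append((p.mz, p.rt, p.intensity))
        else:
            items.append((float(p[0]), float(p[1]), float(p[2])))
    n = len(items)
    order = sorted(range(n), key=lambda i: items[i][0])
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    max_span = 3 * C13_DELTA + max_br * BR81_DELTA + 1.0
    for a_pos, i in enumerate(order):
        mi, ri, _ = items[i]
        for j in order[a_pos + 1:]:
            mj, rj, _ = items[j]
            if mj - mi > max_span:
                break
            if abs(rj - ri) > rt_tol:
                continue
            if _isotope_step(mj - mi, mz_tol):
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    features: list[Feature] = []
    for members in clusters.values():
        members.sort(key=lambda i: items[i][0])
        mzs = [items[i][0] for i in members]
        ints = [items[i][2] for i in members]
        total = sum(ints)
        rt = sum(items[i][1] * items[i][2] for i in members) / total if total else items[members[0]][1]
        br = None
        if len(members) > 1 and max(ints) > 0:
            pattern = IsotopePattern(
                tuple(mzs), tuple(v / max(ints) for v in ints)
            ) if all(v > 0 for v in ints) and _strictly_increasing(mzs) else None
            if pattern is not None:
                br = infer_bromine_count(pattern, max_br=max_br)
        elif len(members) == 1:
            br = 0
        features.append(Feature(mz=mzs[0], rt=rt, intensity=total, br_count=br))
    features.sort(key=lambda f: f.mz)
    return features


def _strictly_increasing(vals: Sequence[float]) -> bool:
    return all(b > a for a, b in zip(vals, vals[1:]))


def join_align(
    sample_features: Sequence[Sequence[Feature]],
    sample_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    mz_tol: float = 0.02,
    rt_tol: float = 0.2,
) -> FeatureTable:
    """Align per-sample feature lists into one table (join aligner).

    Features are processed in a deterministic order (descending intensity,
    then ascending m/z); each joins the closest existing row within both
    tolerances whose slot for its sample is still empty, by the smallest
    combined normalized m/z + RT distance, otherwise it founds a new row.
    Unmatched slots stay at zero intensity.
    """
    if not sample_features:
        raise ValueError("at least one sample required")
    n_samples = len(sample_features)
    if sample_ids is None:
        sample_ids = [f"sample{i+1}" for i in range(n_samples)]
    if groups is None:
        groups = ["unknown"] * n_samples

    queue: list[tuple[float, float, int, Feature]] = []
    for j, feats in enumerate(sample_features):
        for f in feats:
            queue.append((-f.intensity, f.mz, j, f))
    queue.sort(key=lambda t: (t[0], t[1], t[2]))

    rows: list[dict] = []
    for _, _, j, f in queue:
        best, best_d = None, np.inf
        for row in rows:
            if row["filled"][j]:
                continue
            dm = abs(f.mz - row["mz"])
            dr = abs(f.rt - row["rt"])
            if dm > mz_tol or dr > rt_tol:
                continue
            d = np.hypot(dm / mz_tol, dr / rt_tol)
            if d < best_d:
                best, best_d = row, d
        if best is None:
            best = {
                "mz": f.mz,
                "rt": f.rt,
                "intensity": np.zeros(n_samples),
                "filled": [False] * n_samples,
                "br": f.br_count,
                "ms2": f.ms2_id,
            }
            rows.append(best)
        best["intensity"][j] = f.intensity
        best["filled"][j] = True
        if best["br"] is None:
            best["br"] = f.br_count
        if best["ms2"] is None:
            best["ms2"] = f.ms2_id

    rows.sort(key=lambda r: (r["mz"], r["rt"]))
    return FeatureTable(
        mz=np.array([r["mz"] for r in rows]),
        rt=np.array([r["rt"] for r in rows]),
        intensities=np.array([r["intensity"] for r in rows]).reshape(len(rows), n_samples),
        sample_ids=list(sample_ids),
        groups=list(groups),
        br_counts=[r["br"] for r in rows],
        ms2_ids=[r["ms2"] for r in rows],
    )
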