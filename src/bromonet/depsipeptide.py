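"""Fragmentation model for acylated cyclic depsipeptides (bromoalterochromides).

A bromoalterochromide is a pentapeptide macrolactone carrying a brominated
aryl-polyene acyl chain on the N-terminal threonine; the ring closes from
the Thr side-chain oxygen onto the C-terminal carbonyl.  Under collisional
activation the ring opens at two sites — (i) the macrolactone ester bond,
and (ii) the threonine O–C bond — and the resulting linear acyl peptide
fragments into conventional b/y ladders.  A dominant low-mass ion from
aromatic elimination of the brominated aryl-polyene typically forms the
base peak.

Mass bookkeeping
----------------
With the acyl-chain formula defined so that the neutral cyclic molecule is
``acyl + sum(residues)`` (the macrolactone has consumed the water of the
linear acid), singly protonated fragments are::

    b_k = acyl + sum(res[:k]) - H2O + delta_N + proton      (acylium)
    y_k = sum(res[n-k:]) + H2O + delta_C + proton

where ``delta_N + delta_C = 0`` for an opening that only relocates a
hydrogen.  This gives the complementarity b_k + y_{n-k} = [M+H]+ + proton
that annotators rely on.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemformulas import (
    DEFAULT_MASS_TABLE,
    ELECTRON_MASS,
    PROTON_MASS,
    ElementMassTable,
    IonSpec,
    MolecularFormula,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)
from .spectra_io import Spectrum

__all__ = [
    "RESIDUES",
    "Residue",
    "DepsipeptideModel",
    "OpeningRule",
    "ESTER_OPENING",
    "THR_OC_OPENING",
    "DEFAULT_OPENINGS",
    "FragmentIon",
    "cyclic_formula",
    "fragment_ladders",
    "elimination_ion",
    "theoretical_spectrum",
    "LibraryCompound",
    "load_compound_library",
]

_WATER = MolecularFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class Residue:
    """Amino-acid residue (amino acid minus water)."""

    name: str
    formula: MolecularFormula

    def mass(self, table: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
        return monoisotopic_mass(self.formula, table)


def _res(name: str, formula: str) -> Residue:
    return Residue(name, parse_formula(formula))


# Ile and Leu are isobaric and indistinguishable by low-energy CID; both map
# onto the composite residue Xle.
RESIDUES: dict[str, Residue] = {
    r.name: r
    for r in (
        _res("Gly", "C2H3NO"),
        _res("Ala", "C3H5NO"),
        _res("Ser", "C3H5NO2"),
        _res("Pro", "C5H7NO"),
        _res("Val", "C5H9NO"),
        _res("Thr", "C4H7NO2"),
        _res("Xle", "C6H11NO"),
        _res("Asn", "C4H6N2O2"),
        _res("Asp", "C4H5NO3"),
        _res("Gln", "C5H8N2O2"),
        _res("Glu", "C5H7NO3"),
        _res("Phe", "C9H9NO"),
        _res("Tyr", "C9H9NO2"),
    )
}
RESIDUES["Ile"] = Residue("Xle", RESIDUES["Xle"].formula)
RESIDUES["Leu"] = Residue("Xle", RESIDUES["Xle"].formula)


@dataclass(frozen=True)
class OpeningRule:
    """Terminal mass bookkeeping of one ring-opening site.

    ``n_delta``/``c_delta`` are added to every b/y fragment of the ladder
    obtained from this opening; for a homolytic opening with net hydrogen
    transfer the two deltas sum to zero.  When the deltas correspond to
    moving a whole water, the equivalent formula deltas are carried so
    fragments can also be built at the elemental-formula level.
    """

    site: str
    n_delta: float = 0.0
    c_delta: float = 0.0
    n_water_shift: int = 0  # formula-level: number of waters added N-side
    c_water_shift: int = 0

    def __post_init__(self) -> None:
        if abs(self.n_delta + self.c_delta) > 1e-9:
            raise ValueError("opening deltas must sum to zero (H-transfer opening)")


#: Opening (i): cleavage of the macrolactone ester bond (Thr side-chain O to
#: the C-terminal carbonyl); plain acid/alcohol partition, zero deltas.
ESTER_OPENING = OpeningRule("ester-bond")
#: Opening (ii): cleavage of the threonine O-C bond; modeled as dehydration
#: of the N-side (dehydro-Thr) with the water appearing on the C-side.
THR_OC_OPENING = OpeningRule(
    "thr-O-C",
    n_delta=-monoisotopic_mass(_WATER),
    c_delta=+monoisotopic_mass(_WATER),
    n_water_shift=-1,
    c_water_shift=+1,
)
DEFAULT_OPENINGS: tuple[OpeningRule, ...] = (ESTER_OPENING, THR_OC_OPENING)


@dataclass(frozen=True)
class DepsipeptideModel:
    """Acylated cyclic pentapeptide: acyl chain + ordered residues + lactone site."""

    acyl: MolecularFormula
    residues: tuple[Residue, ...]
    macrolactone_index: int = 0
    label: str = ""
    elimination_mz: float | None = None
    elimination_formula: MolecularFormula | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residue list must be non-empty")
        if not 0 <= self.macrolactone_index < len(self.residues):
            raise ValueError("macrolactone index out of range")
        if self.residues[self.macrolactone_index].name != "Thr":
            raise ValueError("macrolactone site must be a Thr residue")

    @property
    def n(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "-".join(r.name for r in self.residues)


def cyclic_formula(m: DepsipeptideModel) -> MolecularFormula:
    """Neutral elemental formula of the cyclic depsipeptide."""
    f = m.acyl
    for r in m.residues:
        f = f + r.formula
    return f


def precursor_mz(m: DepsipeptideModel, table: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
    """[M+H]+ of the cyclic molecule."""
    return ion_mz(IonSpec(cyclic_formula(m), "protonated", 1), table)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical singly charged fragment."""

    series: str  # "b" | "y" | "elimination" | "precursor"
    index: int  # ladder index; 0 for non-ladder ions
    site: str  # opening-site id; "" for non-ladder ions
    mz: float
    formula: MolecularFormula | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.series in ("b", "y") and self.index < 1:
            raise ValueError("ladder index must be >= 1")


def fragment_ladders(
    m: DepsipeptideModel,
    rule: OpeningRule,
    charge: int = 1,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> list[FragmentIon]:
    """b/y ladders (k = 1..n-1) of one ring opening, singly protonated."""
    if charge != 1:
        raise ValueError("only singly protonated fragments are modeled")
    water = monoisotopic_mass(_WATER, table)
    acyl_mass = monoisotopic_mass(m.acyl, table)
    res_masses = [r.mass(table) for r in m.residues]
    ions: list[FragmentIon] = []
    h = MolecularFormula({"H": 1})
    for k in range(1, m.n):
        b_mz = acyl_mass + sum(res_masses[:k]) - water + rule.n_delta + PROTON_MASS
        b_formula = _shift_water(
            _sum_formulas([m.acyl] + [r.formula for r in m.residues[:k]]) ,
            rule.n_water_shift - 1,
        )
        ions.append(FragmentIon("b", k, rule.site, b_mz,
                                b_formula + h if b_formula else None))
        y_mz = sum(res_masses[m.n - k:]) + water + rule.c_delta + PROTON_MASS
        y_formula = _shift_water(
            _sum_formulas([r.formula for r in m.residues[m.n - k:]]),
            rule.c_water_shift + 1,
        )
        ions.append(FragmentIon("y", k, rule.site, y_mz,
                                y_formula + h if y_formula else None))
    return ions


def _sum_formulas(formulas: Sequence[MolecularFormula]) -> MolecularFormula:
    total = formulas[0]
    for f in formulas[1:]:
        total = total + f
    return total


def _shift_water(f: MolecularFormula, n_waters: int) -> MolecularFormula | None:
    """Add/remove whole waters from a formula; None when impossible."""
    try:
        for _ in range(n_waters):
            f = f + _WATER
        for _ in range(-n_waters):
            f = f - _WATER
    except ValueError:
        return None
    return f


def elimination_ion(
    m: DepsipeptideModel, table: ElementMassTable = DEFAULT_MASS_TABLE
) -> FragmentIon:
    """The aryl-polyene elimination ion (the spectra's base peak).

    Its composition is configured on the model (formula preferred, bare m/z
    accepted); the mechanism-level formula is deliberately not asserted here.
    """
    if m.elimination_formula is not None:
        mz = ion_mz(IonSpec(m.elimination_formula, "as-is", 1), table)
        return FragmentIon("elimination", 0, "", mz, m.elimination_formula)
    if m.elimination_mz is not None:
        return FragmentIon("elimination", 0, "", m.elimination_mz)
    raise ValueError(
        f"model {m.label or m.sequence()}: configure elimination_formula or elimination_mz"
    )


def theoretical_spectrum(
    m: DepsipeptideModel,
    rules: Sequence[OpeningRule] = DEFAULT_OPENINGS,
    include_elimination: bool = True,
    include_precursor: bool = True,
    merge_tol: float = 1e-4,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> Spectrum:
    """Unit-intensity theoretical MS2 spectrum of a model.

    Union of the b/y ladders of every opening rule, plus the precursor and
    (optionally) the elimination ion; peaks within ``merge_tol`` merge.
    """
    mzs: list[float] = []
    for rule in rules:
        mzs.extend(f.mz for f in fragment_ladders(m, rule, table=table))
    if include_precursor:
        mzs.append(precursor_mz(m, table))
    if include_elimination:
        mzs.append(elimination_ion(m, table).mz)
    mzs.sort()
    merged: list[float] = []
    for v in mzs:
        if merged and v - merged[-1] <= merge_tol:
            continue
        merged.append(v)
    return Spectrum(
        id=m.label or m.sequence(),
        precursor_mz=precursor_mz(m, table),
        charge=1,
        mz=np.array(merged),
        intensity=np.ones(len(merged)),
    )


@dataclass(frozen=True)
class LibraryCompound:
    """One known-compound record of the reference library."""

    name: str
    series: str  # "A" (C15 acyl) | "B" (C17 acyl) | "" for non-depsipeptides
    br_count: int
    formula: MolecularFormula  # neutral molecule
    model: DepsipeptideModel | None = None
    known: bool = True  # part of the reference (dereplication) library


def load_compound_library(path: str | Path | None = None) -> list[LibraryCompound]:
    """Load the compound library (defaults to the packaged fixture).

    The file is tab-separated with columns: name, series, br, acyl_formula,
    residues (dash-separated, empty for non-peptides), formula (override for
    non-peptides), elimination_mz, known (1/0).
    """
    if path is None:
        source = resources.files("bromonet.data").joinpath("compound_library.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    out: list[LibraryCompound] = []
    rows = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in rows:
        residues = tuple(
            RESIDUES[r] for r in row["residues"].split("-") if r
        )
        model = None
        if residues:
            model = DepsipeptideModel(
                acyl=parse_formula(row["acyl_formula"]),
                residues=residues,
                macrolactone_index=0,
                label=row["name"],
                elimination_mz=float(row["elimination_mz"]) if row["elimination_mz"] else None,
            )
            formula = cyclic_formula(model)
        else:
            formula = parse_formula(row["formula"])
        out.append(
            LibraryCompound(
                name=row["name"],
                series=row["series"],
                br_count=int(row["br"]),
                formula=formula,
                model=model,
                known=row["known"] == "1",
            )
        )
    return out
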