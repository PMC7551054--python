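"""Elemental masses, molecular-formula arithmetic, ion m/z and isotopologue patterns.

This module is the computational substrate for high-resolution MS
interpretation: monoisotopic masses of molecular formulas, m/z of protonated
and sodiated ions (electron mass subtracted per positive charge), simulation
of isotopologue patterns by convolution of elemental isotope distributions,
inference of the bromine count of an ion from its isotope pattern (one Br
gives a near 1:1 doublet 2 Da apart, two Br a ~1:2:1 triplet), and bounded
exhaustive enumeration of candidate molecular formulas for an observed m/z.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "SODIUM_CATION_MASS",
    "ElementMassTable",
    "DEFAULT_MASS_TABLE",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "IonSpec",
    "ion_mz",
    "IsotopePattern",
    "isotopologue_pattern",
    "infer_bromine_count",
    "FormulaCandidate",
    "enumerate_formulas",
    "rdbe",
]

#: Rest mass of the electron in Da, subtracted once per positive charge.
ELECTRON_MASS = 0.000548579909
#: Mass of the proton (H atom minus one electron) in Da.
PROTON_MASS = 1.007276466
#: Mass of the sodium cation (Na atom minus one electron) in Da.
SODIUM_CATION_MASS = 22.989218

# NIST/CODATA monoisotopic isotope masses (Da) and natural abundances.
# First entry per element is the principal (most abundant) isotope.
_NIST_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)],
    "S": [(31.9720711744, 0.9499), (32.9714589098, 0.0075), (33.9678670040, 0.0425), (35.9670807100, 0.0001)],
    "Br": [(78.9183376, 0.5069), (80.9162906, 0.4931)],
    "Na": [(22.9897692820, 1.0)],
    "Cl": [(34.9688527100, 0.7576), (36.9659025800, 0.2424)],
    "P": [(30.9737616320, 1.0)],
}

# Monovalent elements for ring-plus-double-bond-equivalent accounting.
_MONOVALENT = frozenset({"H", "Br", "Cl", "F", "I", "Na"})


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic masses and isotope distributions, one entry per element.

    ``isotopes[el]`` is a list of ``(isotope mass Da, abundance fraction)``
    whose abundances sum to 1; the first entry is the principal isotope whose
    mass is used for monoisotopic-mass arithmetic.
    """

    isotopes: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: _NIST_ISOTOPES
    )

    def __post_init__(self) -> None:
        for el, iso in self.isotopes.items():
            total = sum(a for _, a in iso)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances of {el} sum to {total}, not 1")
            if any(m <= 0 for m, _ in iso):
                raise ValueError(f"non-positive isotope mass for {el}")

    def principal_mass(self, element: str) -> float:
        try:
            return self.isotopes[element][0][0]
        except KeyError:
            raise KeyError(f"element {element!r} not in mass table") from None

    def __contains__(self, element: str) -> bool:
        return element in self.isotopes


DEFAULT_MASS_TABLE = ElementMassTable()

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class MolecularFormula(Mapping[str, int]):
    """Immutable element -> count map supporting element-wise +/-.

    Counts are non-negative integers and at least one atom is required.
    Subtraction raises if any count would go negative.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        cleaned = {el: int(n) for el, n in counts.items() if int(n) != 0}
        if not cleaned:
            raise ValueError("molecular formula must contain at least one atom")
        if any(n < 0 for n in cleaned.values()):
            raise ValueError(f"negative element count in {counts!r}")
        object.__setattr__(self, "_counts", dict(sorted(cleaned.items())))

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count: {self} - {other}"
                )
        return MolecularFormula(counts)

    def __mul__(self, k: int) -> "MolecularFormula":
        if k < 1:
            raise ValueError("multiplier must be a positive integer")
        return MolecularFormula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"MolecularFormula({self!s})"

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        def key(el: str) -> tuple[int, str]:
            return ({"C": 0, "H": 1}.get(el, 2), el)

        return "".join(
            f"{el}{n if n != 1 else ''}"
            for el, n in sorted(self._counts.items(), key=lambda kv: key(kv[0]))
        )


def parse_formula(text: str, table: ElementMassTable = DEFAULT_MASS_TABLE) -> MolecularFormula:
    """Parse an element-count string such as ``"C39H53N7O10Br"``.

    A missing count defaults to 1.  Unknown element symbols and malformed
    tokens raise :class:`ValueError` naming the offending token.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula token {text[pos:match.start()]!r} in {text!r}")
        pos = match.end()
        el, num = match.group(1), match.group(2)
        if el not in table:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"malformed formula token {text[pos:]!r} in {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(
    f: MolecularFormula | Mapping[str, int],
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Sum of principal-isotope masses, count-weighted."""
    if not isinstance(f, MolecularFormula):
        f = MolecularFormula(f)
    return sum(n * table.principal_mass(el) for el, n in f.items())


@dataclass(frozen=True)
class IonSpec:
    """A (possibly adducted) positive ion.

    ``formula`` is either the neutral molecule (default) or, when
    ``formula_is_ion`` is set, the full elemental composition of the ion
    including adduct atoms.  ``adduct`` is one of ``"protonated"``,
    ``"sodiated"`` or ``"as-is"``.
    """

    formula: MolecularFormula
    adduct: str = "protonated"
    z: int = 1
    formula_is_ion: bool = False

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("charge z must be a positive integer")
        if self.adduct not in ("protonated", "sodiated", "as-is"):
            raise ValueError(f"unknown adduct {self.adduct!r}")


def ion_mz(ion: IonSpec, table: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of a positive ion, electron mass subtracted once per charge.

    For a neutral formula the adduct cation mass (+1.007276 per charge for a
    proton, +22.989218 for sodium) is applied; when the formula already
    describes the ion only the electron correction applies.
    """
    mass = monoisotopic_mass(ion.formula, table)
    if ion.formula_is_ion or ion.adduct == "as-is":
        mz = (mass - ion.z * ELECTRON_MASS) / ion.z
    elif ion.adduct == "protonated":
        mz = mass / ion.z + PROTON_MASS
    else:  # sodiated
        mz = mass / ion.z + SODIUM_CATION_MASS
    if mz <= 0:
        raise ValueError("resulting m/z is not positive")
    return mz


def mz_protonated(f: MolecularFormula, z: int = 1,
                  table: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
    """[M + zH]^z+ m/z of a neutral formula."""
    return ion_mz(IonSpec(f, "protonated", z), table)


def mz_sodiated(f: MolecularFormula, z: int = 1,
                table: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
    """[M + zNa]^z+ m/z of a neutral formula."""
    return ion_mz(IonSpec(f, "sodiated", z), table)


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotopologue pattern, base peak scaled to 1.0."""

    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity) or not self.mz:
            raise ValueError("pattern needs matching, non-empty m/z and intensity")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("pattern m/z must be strictly ascending")
        if any(not (0.0 < i <= 1.0) for i in self.intensity):
            raise ValueError("intensities must lie in (0, 1]")
        if abs(max(self.intensity) - 1.0) > 1e-12:
            raise ValueError("base peak must have intensity 1.0")

    def __len__(self) -> int:
        return len(self.mz)


def _convolve_distributions(
    a: list[tuple[float, float]],
    b: list[tuple[float, float]],
    merge_tol: float,
    prune: float = 1e-12,
) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for (ma, pa), (mb, pb) in itertools.product(a, b):
        out.append((ma + mb, pa * pb))
    return _merge_peaks(out, merge_tol, prune)


def _merge_peaks(
    peaks: list[tuple[float, float]], merge_tol: float, prune: float = 0.0
) -> list[tuple[float, float]]:
    """Merge peaks closer than merge_tol into abundance-weighted centroids."""
    peaks = sorted(peaks)
    merged: list[tuple[float, float]] = []
    for m, p in peaks:
        if merged and m - merged[-1][0] < merge_tol:
            m0, p0 = merged[-1]
            tot = p0 + p
            merged[-1] = ((m0 * p0 + m * p) / tot, tot)
        else:
            merged.append((m, p))
    if prune:
        merged = [(m, p) for m, p in merged if p > prune]
    return merged


def _element_power(
    iso: Sequence[tuple[float, float]], n: int, merge_tol: float
) -> list[tuple[float, float]]:
    """Isotope distribution of n atoms of one element (binary exponentiation)."""
    result = [(0.0, 1.0)]
    base = [tuple(x) for x in iso]
    while n:
        if n & 1:
            result = _convolve_distributions(result, base, merge_tol)
        n >>= 1
        if n:
            base = _convolve_distributions(base, base, merge_tol)
    return result


def formula_isotope_distribution(
    f: MolecularFormula,
    merge_tol: float = 0.01,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[float, float]]:
    """Un-normalized isotopologue distribution (mass, probability).

    Probabilities sum to 1 (up to pruning of < 1e-12 terms); no relative
    truncation is applied.
    """
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    dist = [(0.0, 1.0)]
    for el, n in f.items():
        if el not in table:
            raise KeyError(f"no isotope data for element {el!r}")
        dist = _convolve_distributions(
            dist, _element_power(table.isotopes[el], n, merge_tol), merge_tol
        )
    return dist


def isotopologue_pattern(
    f: MolecularFormula,
    merge_tol: float = 0.01,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
    truncate: float = 1e-4,
) -> IsotopePattern:
    """Theoretical isotopologue pattern of a neutral or ionic composition.

    The elemental isotope distributions are convolved atom by atom, centroids
    closer than ``merge_tol`` are summed, peaks below ``truncate`` of the base
    peak are dropped and the base peak is scaled to 1.
    """
    dist = formula_isotope_distribution(f, merge_tol, table)
    base = max(p for _, p in dist)
    kept = [(m, p / base) for m, p in dist if p / base >= truncate]
    return IsotopePattern(tuple(m for m, _ in kept), tuple(i for _, i in kept))


def _nominal_bins(mz: Sequence[float], intensity: Sequence[float]) -> dict[int, float]:
    """Collapse a pattern onto integer-Da offsets from its lightest peak."""
    m0 = mz[0]
    bins: dict[int, float] = {}
    for m, i in zip(mz, intensity):
        k = round(m - m0)
        bins[k] = bins.get(k, 0.0) + i
    top = max(bins.values())
    return {k: v / top for k, v in bins.items()}

_CH2_MASS = 14.01565006
_BR_MASS = 78.9183376


def infer_bromine_count(
    p: IsotopePattern,
    max_br: int = 3,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> int:
    """Number of bromine atoms most consistent with an isotope pattern.

    For each candidate count b the pattern of a hydrocarbon surrogate
    CcH2cBr_b matched to the pattern's monoisotopic mass is computed, both
    patterns are collapsed onto integer-Da offsets, and the candidate with
    the smallest L2 intensity distance wins; ties go to the smaller b.
    """
    if max_br < 0:
        raise ValueError("max_br must be >= 0")
    obs = _nominal_bins(p.mz, p.intensity)
    mono = p.mz[0]
    best_b, best_d = 0, np.inf
    for b in range(max_br + 1):
        remaining = mono - b * _BR_MASS
        if remaining < 0:
            continue
        c = max(1, round(remaining / _CH2_MASS))
        surrogate = MolecularFormula({"C": c, "H": 2 * c, "Br": b} if b else {"C": c, "H": 2 * c})
        theo_pat = isotopologue_pattern(surrogate, table=table)
        theo = _nominal_bins(theo_pat.mz, theo_pat.intensity)
        offsets = set(obs) | set(theo)
        d = sum((obs.get(k, 0.0) - theo.get(k, 0.0)) ** 2 for k in offsets)
        if d < best_d - 1e-12:
            best_b, best_d = b, d
    return best_b


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents (monovalent: H, halogens, Na)."""
    c = f.get("C", 0)
    n = f.get("N", 0) + f.get("P", 0)
    mono = sum(f.get(el, 0) for el in _MONOVALENT)
    return c + 1.0 + n / 2.0 - mono / 2.0


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate assignment from formula enumeration."""

    neutral: MolecularFormula
    ion: MolecularFormula
    mz: float
    ppm: float
    rdbe: float

    @property
    def heteroatoms(self) -> int:
        return sum(n for el, n in self.neutral.items() if el not in ("C", "H"))


# Default search bounds: generous enough for all bromoalterochromides and
# bisucaberin while keeping the exhaustive search instantaneous.
DEFAULT_BOUNDS: dict[str, int] = {"C": 60, "H": 100, "N": 15, "O": 20, "Br": 3}


def enumerate_formulas(
    target_mz: float,
    adduct: str = "protonated",
    tol_ppm: float = 5.0,
    bounds: Mapping[str, int] | None = None,
    fixed_br: int | None = None,
    require_rdbe_nonneg: bool = True,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> list[FormulaCandidate]:
    """Bounded exhaustive molecular-formula search for an observed ion m/z.

    All element-count combinations within ``bounds`` are examined (the H count
    is solved from the mass residual, so the search is linear in the product
    of the other bounds).  Candidates within ``tol_ppm``, with the required Br
    count and (optionally) non-negative RDBE, are returned sorted by |ppm|
    then by fewer heteroatoms.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = dict(bounds) if bounds is not None else dict(DEFAULT_BOUNDS)
    if not bounds:
        raise ValueError("element bounds must be non-empty")
    if adduct == "protonated":
        neutral_target = target_mz + ELECTRON_MASS - table.principal_mass("H")
    elif adduct == "sodiated":
        neutral_target = target_mz + ELECTRON_MASS - table.principal_mass("Na")
    elif adduct == "as-is":
        neutral_target = target_mz + ELECTRON_MASS
    else:
        raise ValueError(f"unknown adduct {adduct!r}")

    h_max = bounds.pop("H", 0)
    h_mass = table.principal_mass("H")
    if fixed_br is not None:
        bounds["Br"] = fixed_br
    heavy = sorted(bounds)
    ranges = []
    for el in heavy:
        if el == "Br" and fixed_br is not None:
            ranges.append(np.array([fixed_br]))
        else:
            ranges.append(np.arange(bounds[el] + 1))
    abs_tol = abs(target_mz) * tol_ppm * 1e-6

    # Vectorized grid over the non-hydrogen counts; H solved from the residual.
    grids = np.meshgrid(*ranges, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)  # (n_combos, n_heavy)
    heavy_masses = np.array([table.principal_mass(el) for el in heavy])
    mass_grid = counts @ heavy_masses
    h_guess = np.round((neutral_target - mass_grid) / h_mass).astype(int)

    out: list[FormulaCandidate] = []
    for h_off in (-1, 0, 1):
        h = h_guess + h_off
        neutral_mass = mass_grid + h * h_mass
        if adduct == "protonated":
            mz = neutral_mass + PROTON_MASS
        elif adduct == "sodiated":
            mz = neutral_mass + SODIUM_CATION_MASS
        else:
            mz = neutral_mass - ELECTRON_MASS
        ok = (h >= 0) & (h <= h_max) & (np.abs(mz - target_mz) <= abs_tol) & (mz > 0)
        for idx in np.flatnonzero(ok):
            combo = {el: int(n) for el, n in zip(heavy, counts[idx]) if n}
            if h[idx]:
                combo["H"] = int(h[idx])
            if not combo:
                continue
            neutral = MolecularFormula(combo)
            if require_rdbe_nonneg and rdbe(neutral) < 0:
                continue
            if adduct == "protonated":
                ionf = neutral + MolecularFormula({"H": 1})
            elif adduct == "sodiated":
                ionf = neutral + MolecularFormula({"Na": 1})
            else:
                ionf = neutral
            ppm = (target_mz - mz[idx]) / mz[idx] * 1e6  # observed vs calculated
            out.append(FormulaCandidate(neutral, ionf, float(mz[idx]), float(ppm), rdbe(neutral)))
    out.sort(key=lambda c: (abs(c.ppm), c.heteroatoms, str(c.neutral)))
    return out
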