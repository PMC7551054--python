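"""Formula arithmetic, ion masses, isotope patterns and formula search."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bromonet.chemformulas import (
    DEFAULT_MASS_TABLE,
    ELECTRON_MASS,
    PROTON_MASS,
    FormulaCandidate,
    IonSpec,
    IsotopePattern,
    MolecularFormula,
    enumerate_formulas,
    formula_isotope_distribution,
    infer_bromine_count,
    ion_mz,
    isotopologue_pattern,
    monoisotopic_mass,
    parse_formula,
    rdbe,
)

# --------------------------------------------------------------------------
# parsing and arithmetic


@pytest.mark.parametrize(
    "text,expected",
    [
        ("H2O", {"H": 2, "O": 1}),
        ("C39H53N7O10Br", {"C": 39, "H": 53, "N": 7, "O": 10, "Br": 1}),
        ("C39H52N7O10Br2", {"C": 39, "H": 52, "N": 7, "O": 10, "Br": 2}),
        ("CH4", {"C": 1, "H": 4}),
        ("NaCl", {"Na": 1, "Cl": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text)) == expected


@pytest.mark.parametrize("bad", ["C39Xx2", "c2h4", "H2O!", ""])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


def test_formula_arithmetic():
    water = parse_formula("H2O")
    peroxide = parse_formula("H2O2")
    assert water + water == parse_formula("H4O2")
    assert peroxide - water == MolecularFormula({"O": 1})
    with pytest.raises(ValueError):
        water - peroxide  # would go negative
    with pytest.raises(ValueError):
        MolecularFormula({})


@settings(deadline=None, max_examples=50)
@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "Br", "Na"]),
        st.integers(min_value=0, max_value=60),
        min_size=1,
    ).filter(lambda d: any(v > 0 for v in d.values()))
)
def test_formula_string_round_trip(counts):
    f = MolecularFormula(counts)
    assert parse_formula(str(f)) == f


# --------------------------------------------------------------------------
# masses


def test_monoisotopic_mass_reference_values():
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.010565, abs=1e-6)
    assert monoisotopic_mass(MolecularFormula({"C": 1})) == 12.0


def test_protonated_ion_masses_of_new_compounds():
    """The printed calcd values for the mono- and di-brominated analogs."""
    mono = ion_mz(IonSpec(parse_formula("C39H53N7O10Br"), "as-is"))
    di = ion_mz(IonSpec(parse_formula("C39H52N7O10Br2"), "as-is"))
    assert round(mono, 4) == pytest.approx(858.3032, abs=2e-4)
    assert round(di, 4) == pytest.approx(936.2137, abs=2e-4)
    # Br-for-H substitution mass difference
    assert di - mono == pytest.approx(77.9105, abs=2e-4)


def test_neutral_plus_proton():
    mz = ion_mz(IonSpec(parse_formula("H2O"), "protonated"))
    assert mz == pytest.approx(18.010565 + 1.007276, abs=1e-5)


def test_ion_mz_rejects_zero_charge():
    with pytest.raises(ValueError):
        IonSpec(parse_formula("H2O"), "protonated", z=0)


@settings(deadline=None, max_examples=30)
@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "Br"]),
        st.integers(min_value=1, max_value=40),
        min_size=1,
    ),
    st.integers(min_value=1, max_value=3),
)
def test_adduct_linearity(counts, z):
    """Protonating a composition shifts m/z by one H atom vs the bare ion.

    The proton delta (+1.007276 per charge) plus the electron correction that
    the as-is route applies amounts to exactly one hydrogen-atom mass.
    """
    f = MolecularFormula(counts)
    prot = ion_mz(IonSpec(f, "protonated", z))
    bare = ion_mz(IonSpec(f, "as-is", z))
    assert prot - bare == pytest.approx(PROTON_MASS + ELECTRON_MASS, abs=1e-9)


# --------------------------------------------------------------------------
# isotope patterns


def test_bromine_doublet():
    p = isotopologue_pattern(MolecularFormula({"Br": 1}))
    assert len(p) == 2
    assert p.mz[1] - p.mz[0] == pytest.approx(1.99796, abs=1e-5)
    assert p.intensity[1] / p.intensity[0] == pytest.approx(0.9728, abs=1e-3)


def test_dibromine_triplet():
    p = isotopologue_pattern(MolecularFormula({"Br": 2}))
    assert len(p) == 3
    rel = np.array(p.intensity)
    assert rel[1] == 1.0
    assert rel[0] == pytest.approx(0.514, abs=2e-3)
    assert rel[2] == pytest.approx(0.486, abs=2e-3)


def test_hydrogen_is_effectively_monoisotopic():
    p = isotopologue_pattern(MolecularFormula({"H": 1}))
    assert p.intensity[0] == 1.0
    assert all(i < 2e-4 for i in p.intensity[1:])  # deuterium is negligible


@pytest.mark.parametrize("text", ["C39H53N7O10Br", "C18H32N4O6", "C6H12O6", "Br2"])
def test_distribution_total_probability(text):
    dist = formula_isotope_distribution(parse_formula(text))
    assert sum(p for _, p in dist) == pytest.approx(1.0, abs=1e-6)


def test_isotope_pattern_validation():
    with pytest.raises(ValueError):
        IsotopePattern((100.0, 99.0), (1.0, 0.5))  # not ascending
    with pytest.raises(ValueError):
        IsotopePattern((100.0, 101.0), (0.5, 0.9))  # no base peak at 1.0


# --------------------------------------------------------------------------
# bromine-count inference


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C39H53N7O10Br", 1),
        ("C39H52N7O10Br2", 2),
        ("C10H20", 0),
        ("C18H32N4O6", 0),
    ],
)
def test_infer_bromine_count_from_clean_patterns(formula, expected):
    p = isotopologue_pattern(parse_formula(formula))
    assert infer_bromine_count(p, max_br=3) == expected


def test_infer_bromine_count_under_noise(rng):
    """>= 99% correct over noisy simulated clusters per Br count."""
    from bromonet.synthetic_data import SimulationConfig, simulate_ms1_cluster

    cfg = SimulationConfig(ms1_noise=0.05)
    formulas = {
        0: parse_formula("C40H60N6O8"),
        1: parse_formula("C39H52N7O10Br"),
        2: parse_formula("C39H51N7O10Br2"),
    }
    for true_br, f in formulas.items():
        hits = 0
        n = 60
        for _ in range(n):
            mz, inten = simulate_ms1_cluster(f, cfg, rng)
            order = np.argsort(mz)
            inten = inten[order] / inten.max()
            pattern = IsotopePattern(tuple(mz[order]), tuple(inten))
            hits += infer_bromine_count(pattern, max_br=3) == true_br
        assert hits / n >= 0.99


# --------------------------------------------------------------------------
# formula enumeration


def test_enumeration_recovers_new_compound_formulas():
    cands = enumerate_formulas(858.3024, "protonated", 5.0, fixed_br=1)
    ions = {str(c.ion): c for c in cands}
    assert "C39H53BrN7O10" in ions
    assert abs(ions["C39H53BrN7O10"].ppm) < 2.0
    cands2 = enumerate_formulas(936.2168, "protonated", 5.0, fixed_br=2)
    assert any(str(c.ion) == "C39H52Br2N7O10" for c in cands2)
    assert all(c.neutral.get("Br") == 2 for c in cands2)


def test_enumeration_tiny_bounds():
    cands = enumerate_formulas(
        19.017841, "protonated", 5.0, {"C": 1, "H": 4, "O": 1}, fixed_br=0
    )
    assert cands and str(cands[0].neutral) == "H2O"


def test_enumeration_sorted_and_within_tolerance():
    cands = enumerate_formulas(858.3024, "protonated", 5.0, fixed_br=1)
    ppms = [abs(c.ppm) for c in cands]
    assert ppms == sorted(ppms)
    assert all(p <= 5.0 for p in ppms)
    assert all(c.rdbe >= 0 for c in cands)


def test_enumeration_empty_result_is_not_an_error():
    assert enumerate_formulas(858.3024, "protonated", 0.01, {"C": 2, "H": 4}) == []
    with pytest.raises(ValueError):
        enumerate_formulas(858.3024, "protonated", 5.0, {})


def test_enumeration_recall_on_random_formulas(rng):
    """The generating formula is always recovered when jitter < tolerance."""
    bounds = {"C": 45, "H": 80, "N": 10, "O": 14, "Br": 2}
    n_found = attempted = 0
    while attempted < 100:
        counts = {
            "C": int(rng.integers(5, 40)),
            "H": int(rng.integers(10, 60)),
            "N": int(rng.integers(0, 8)),
            "O": int(rng.integers(0, 10)),
            "Br": int(rng.integers(0, 3)),
        }
        f = MolecularFormula({k: v for k, v in counts.items() if v})
        if rdbe(f) < 0:
            continue
        attempted += 1
        true_mz = ion_mz(IonSpec(f, "protonated"))
        jitter_ppm = float(rng.uniform(-4.0, 4.0))
        observed = true_mz * (1 + jitter_ppm * 1e-6)
        cands = enumerate_formulas(observed, "protonated", 5.0, bounds,
                                   fixed_br=counts["Br"])
        n_found += any(c.neutral == f for c in cands)
    assert n_found == attempted
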