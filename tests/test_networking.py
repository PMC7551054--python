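"""Modified-cosine correctness (vs brute force and matchms) and network rules."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bromonet.networking import build_network, export_network, modified_cosine
from bromonet.spectra_io import Spectrum


def spec(sid, precursor, mz, intensity, **kw):
    return Spectrum(sid, precursor, mz=np.asarray(mz, float),
                    intensity=np.asarray(intensity, float), **kw)


def brute_force_modified_cosine(a, b, frag_tol=0.02):
    """Exhaustive search over every one-to-one matching of candidate pairs."""
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    shift = a.precursor_mz - b.precursor_mz
    pairs = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
        or abs(a.mz[i] - b.mz[j] - shift) <= frag_tol
    ]
    best = [0.0, 0]

    def recurse(k, used_a, used_b, total, count):
        if total > best[0]:
            best[0], best[1] = total, count
        for idx in range(k, len(pairs)):
            i, j = pairs[idx]
            if i in used_a or j in used_b:
                continue
            recurse(idx + 1, used_a | {i}, used_b | {j}, total + wa[i] * wb[j], count + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    return (best[0] / norm if norm else 0.0), best[1]


def random_small_spectrum(rng, sid):
    n = int(rng.integers(2, 7))
    mz = np.sort(rng.uniform(100.0, 110.0, n))  # tight range forces collisions
    intensity = rng.uniform(0.5, 100.0, n)
    return spec(sid, float(rng.uniform(200.0, 210.0)), mz, intensity)


def test_self_similarity_is_one():
    s = spec("a", 500.0, [100.0, 200.0, 300.0], [1.0, 5.0, 2.0])
    e = modified_cosine(s, s)
    assert e.score == pytest.approx(1.0, abs=1e-12)
    assert e.matched == 3


def test_disjoint_spectra_score_zero():
    a = spec("a", 500.0, [100.0, 200.0], [1.0, 1.0])
    b = spec("b", 500.0, [150.0, 250.0], [1.0, 1.0])
    e = modified_cosine(a, b)
    assert e.score == 0.0 and e.matched == 0


def test_empty_spectrum_is_an_error():
    a = spec("a", 500.0, [100.0], [1.0])
    b = spec("b", 500.0, [], [])
    with pytest.raises(ValueError):
        modified_cosine(a, b)


def test_shifted_peaks_match_via_precursor_delta():
    """Analog peaks displaced by the precursor difference still align."""
    a = spec("a", 500.0, [100.0, 200.0, 300.0, 400.0], [1.0, 1.0, 1.0, 1.0])
    b = spec("b", 514.0, [100.0, 214.0, 314.0, 414.0], [1.0, 1.0, 1.0, 1.0])
    e = modified_cosine(a, b)
    assert e.matched == 4
    assert e.score == pytest.approx(1.0, abs=1e-12)


def test_matches_brute_force_on_500_random_pairs():
    rng = np.random.default_rng(2024)
    for _ in range(500):
        a = random_small_spectrum(rng, "a")
        b = random_small_spectrum(rng, "b")
        e = modified_cosine(a, b)
        oracle_score, _ = brute_force_modified_cosine(a, b)
        assert math.isclose(e.score, oracle_score, rel_tol=0, abs_tol=1e-10)


def test_symmetry_and_bounds():
    rng = np.random.default_rng(7)
    for _ in range(200):
        a = random_small_spectrum(rng, "a")
        b = random_small_spectrum(rng, "b")
        e_ab = modified_cosine(a, b)
        e_ba = modified_cosine(b, a)
        assert e_ab.score == pytest.approx(e_ba.score, abs=1e-12)
        assert e_ab.matched == e_ba.matched
        assert 0.0 <= e_ab.score <= 1.0


@settings(deadline=None, max_examples=60)
@given(st.integers(min_value=0, max_value=10_000))
def test_oracle_equivalence_property(seed):
    rng = np.random.default_rng(seed)
    a = random_small_spectrum(rng, "a")
    b = random_small_spectrum(rng, "b")
    oracle_score, _ = brute_force_modified_cosine(a, b)
    assert math.isclose(modified_cosine(a, b).score, oracle_score,
                        rel_tol=0, abs_tol=1e-10)


def test_cross_check_against_matchms():
    """Independent implementation check on unambiguous, well-separated peaks.

    matchms scores intensity products directly, so feeding it sqrt
    intensities reproduces the sqrt-weighted convention used here.
    """
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(11)
    for _ in range(20):
        n = 8
        mz_a = np.sort(rng.uniform(100, 900, n))
        keep = np.concatenate([[True], np.diff(mz_a) > 1.0])
        mz_a = mz_a[keep]
        ints_a = rng.uniform(10, 100, mz_a.size)
        delta = float(rng.uniform(10, 50))
        shifted = rng.random(mz_a.size) < 0.5
        mz_b = mz_a + np.where(shifted, delta, 0.0)
        ints_b = rng.uniform(10, 100, mz_a.size)
        a = spec("a", 500.0, mz_a, ints_a)
        b = spec("b", 500.0 + delta, mz_b, ints_b)
        ours = modified_cosine(a, b, frag_tol=0.02)
        sa = matchms.Spectrum(mz=a.mz, intensities=np.sqrt(a.intensity),
                              metadata={"precursor_mz": a.precursor_mz})
        sb = matchms.Spectrum(mz=b.mz, intensities=np.sqrt(b.intensity),
                              metadata={"precursor_mz": b.precursor_mz})
        ref = ModifiedCosine(tolerance=0.02).pair(sa, sb)
        assert ours.score == pytest.approx(float(ref["score"]), abs=1e-6)
        assert ours.matched == int(ref["matches"])


# --------------------------------------------------------------------------
# network construction


def ladder_family(rng, n_members=5, n_unrelated=4):
    base = np.sort(rng.uniform(120, 480, 9))
    spectra = []
    for k in range(n_members):
        offset = 14.01565 * k
        mz = base + np.where(np.arange(base.size) % 2 == 0, offset, 0.0)
        spectra.append(spec(f"fam{k}", 500.0 + offset, mz, rng.uniform(50, 100, base.size)))
    for k in range(n_unrelated):
        spectra.append(
            spec(f"rand{k}", float(rng.uniform(600, 900)),
                 np.sort(rng.uniform(100, 550, 9)), rng.uniform(50, 100, 9))
        )
    return spectra


def test_build_network_separates_family_from_noise():
    rng = np.random.default_rng(3)
    spectra = ladder_family(rng)
    net = build_network(spectra, cos_min=0.7, min_matched=5)
    fam_ids = {net.family_of(f"fam{k}") for k in range(5)}
    assert len(fam_ids) == 1
    members = set(net.family_members(fam_ids.pop()))
    assert members == {f"fam{k}" for k in range(5)}


def test_single_and_duplicate_spectra():
    s = spec("only", 500.0, [100.0, 200.0, 300.0, 400.0, 450.0], [1.0] * 5)
    net = build_network([s])
    assert net.n_nodes == 1 and net.n_edges == 0
    twin = spec("twin", 500.0, s.mz, s.intensity)
    net2 = build_network([s, twin])
    assert net2.n_edges == 1
    assert net2.graph["only"]["twin"]["cosine"] == pytest.approx(1.0)


def test_raising_thresholds_never_adds_edges():
    rng = np.random.default_rng(5)
    spectra = ladder_family(rng, n_members=6, n_unrelated=4)
    loose = build_network(spectra, cos_min=0.5, min_matched=3)
    tight_cos = build_network(spectra, cos_min=0.8, min_matched=3)
    tight_matched = build_network(spectra, cos_min=0.5, min_matched=6)
    assert set(tight_cos.graph.edges) <= set(loose.graph.edges)
    assert set(tight_matched.graph.edges) <= set(loose.graph.edges)


def test_export_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    spectra = ladder_family(rng)
    net = build_network(spectra, cos_min=0.5, min_matched=3)
    paths = export_network(net, tmp_path / "net", {"fam0": "reference compound"})
    import networkx as nx

    back = nx.read_graphml(paths["graphml"])
    assert back.number_of_nodes() == net.n_nodes
    assert back.number_of_edges() == net.n_edges
    assert back.nodes["fam0"]["annotation"] == "reference compound"
    assert back.nodes["fam1"]["precursor_mz"] == pytest.approx(514.01565)
    edges = paths["edges"].read_text().splitlines()
    assert len(edges) - 1 == net.n_edges


def test_export_empty_network(tmp_path):
    s = spec("solo", 500.0, [100.0, 200.0], [1.0, 1.0])
    net = build_network([s])
    paths = export_network(net, tmp_path / "empty")
    assert paths["graphml"].exists()
    assert paths["edges"].read_text().strip() != "" or net.n_edges == 0
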