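"""Dereplication, analog-offset classification and fragment-level annotation."""
import numpy as np
import pytest

from bromonet.annotation import (
    OFFSET_TABLE,
    annotate_spectrum,
    dereplicate,
    group_provenance,
    propose_analogs,
)
from bromonet.chemformulas import mz_protonated, mz_sodiated
from bromonet.networking import build_network
from bromonet.spectra_io import Feature, Spectrum, join_align
from bromonet.synthetic_data import SimulationConfig, simulate_ms2


def test_dereplicate_matches_new_compound_mass(library):
    """The observed precursor 858.3024 hits the C39H52N7O10Br model at ~-0.9 ppm."""
    matches = dereplicate(858.3024, library, ppm_tol=5.0)
    names = [m.compound.name for m in matches]
    assert "bromoalterochromide D" in names
    best = matches[0]
    assert best.adduct == "protonated"
    assert best.ppm == pytest.approx(-0.93, abs=0.05)


def test_dereplicate_no_match(library):
    assert dereplicate(500.0, library, ppm_tol=5.0) == []
    with pytest.raises(ValueError):
        dereplicate(500.0, [], ppm_tol=5.0)


def test_dereplicate_sodiated_adduct(library):
    comp = next(c for c in library if c.name == "bromoalterochromide A")
    matches = dereplicate(mz_sodiated(comp.formula), library, ppm_tol=5.0)
    assert matches and matches[0].adduct == "sodiated"
    assert matches[0].compound.name == comp.name


# --------------------------------------------------------------------------
# analog offsets


def toy_network(nodes):
    """Chain network over (id, precursor) pairs, in the order given."""
    spectra = []
    base = np.array([100.0, 150.0, 200.0, 250.0, 300.0])
    for sid, prec in nodes:
        spectra.append(
            Spectrum(sid, prec, mz=base + (prec - nodes[0][1]),
                     intensity=np.ones(base.size))
        )
    return build_network(spectra, cos_min=0.5, min_matched=5)


def test_offset_classification_of_observed_node_pair():
    """860.3027 vs 938.2117: a 77.909 Da step classed as Br-for-H."""
    net = toy_network([("known", 844.2876), ("n860", 860.3027), ("n938", 938.2117)])
    hyps = propose_analogs(net, {"known": "bromoalterochromide A"}, offset_tol=0.02)
    by_node = {}
    for h in hyps:
        by_node.setdefault(h.node, []).append(h)
    # 860.3027 - 844.2876 = 16.015: not in the table -> none for the direct edge
    assert any(h.offset_class == "Br-H" and abs(h.residual) < 0.002
               for h in by_node["n938"])


def test_ch2_offset_from_reference():
    net = toy_network([("known", 844.2876), ("analog", 844.2876 + 14.0160)])
    hyps = propose_analogs(net, {"known": "bromoalterochromide A"})
    h = next(h for h in hyps if h.node == "analog")
    assert h.offset_class == "CH2"
    assert h.residual == pytest.approx(14.0160 - OFFSET_TABLE["CH2"], abs=1e-6)


def test_unclassifiable_offset_reports_none():
    net = toy_network([("known", 844.2876), ("odd", 894.2876)])
    hyps = propose_analogs(net, {"known": "bromoalterochromide A"})
    assert [h.offset_class for h in hyps if h.node == "odd"] == ["none"]


def test_propose_analogs_requires_annotated_node():
    net = toy_network([("a", 500.0), ("b", 514.0157)])
    with pytest.raises(ValueError):
        propose_analogs(net, {})


def test_propagation_resolves_analog_chains():
    """known -> +CH2 -> +Br-H is classified through the intermediate node."""
    net = toy_network(
        [("known", 844.2876),
         ("mid", 844.2876 + 14.0157),
         ("far", 844.2876 + 14.0157 + 77.9105)]
    )
    hyps = propose_analogs(net, {"known": "bromoalterochromide A"})
    far = [h for h in hyps if h.node == "far"]
    assert any(h.offset_class == "Br-H" and h.reference.endswith("+CH2") for h in far)


def test_hypotheses_are_edge_symmetric():
    nodes = [("known", 844.2876), ("x", 858.3033), ("y", 922.1981)]
    net = toy_network(nodes)
    h1 = propose_analogs(net, {"known": "bromoalterochromide A"})
    net2 = toy_network(list(reversed(nodes)))
    h2 = propose_analogs(net2, {"known": "bromoalterochromide A"})
    key = lambda hs: sorted((h.node, h.offset_class, round(h.offset_observed, 4)) for h in hs)
    assert key(h1) == key(h2)


# --------------------------------------------------------------------------
# fragment-level annotation


def test_annotate_own_simulation_is_library_match(model, rng):
    m = model("bromoalterochromide D")
    cfg = SimulationConfig()
    s = simulate_ms2(m, cfg, rng)
    res = annotate_spectrum(s, m)
    assert res.status == "library-match"
    assert res.matched == res.total
    assert abs(res.ppm) < 10


def test_annotation_against_wrong_model_loses_fragments(model, rng):
    """Compound-D spectrum vs the A model: position-2 fragments break."""
    d_model = model("bromoalterochromide D")
    a_model = model("bromoalterochromide A")
    cfg = SimulationConfig()
    s = simulate_ms2(d_model, cfg, rng)
    right = annotate_spectrum(s, d_model)
    wrong = annotate_spectrum(s, a_model)
    assert wrong.matched < right.matched
    assert wrong.status == "unknown"


def test_shifted_annotation_recovers_analog(model, rng):
    """With the CH2 shift supplied, the D spectrum matches the A model fully."""
    d_model = model("bromoalterochromide D")
    a_model = model("bromoalterochromide A")
    cfg = SimulationConfig()
    s = simulate_ms2(d_model, cfg, rng)
    from bromonet.annotation import AnalogHypothesis

    hyp = AnalogHypothesis(s.id, "bromoalterochromide A", None, 14.0157, "CH2", 0.0)
    res = annotate_spectrum(s, a_model, precursor_shift=OFFSET_TABLE["CH2"],
                            hypothesis=hyp)
    assert res.status == "new-analog"
    assert res.matched >= res.total - 2


def test_empty_spectrum_is_unknown(model):
    s = Spectrum("empty", 858.3024, mz=[], intensity=[])
    res = annotate_spectrum(s, model("bromoalterochromide D"))
    assert res.status == "unknown" and res.matched == 0


# --------------------------------------------------------------------------
# provenance


def provenance_table():
    feats = {
        "inter_only": [0.0, 5e4, 0.0, 0.0],
        "shared": [8e4, 2e5, 0.0, 0.0],
        "mono_only": [9e4, 0.0, 0.0, 0.0],
        "in_control": [1e4, 1e4, 1e4, 5e4],
    }
    samples = [
        [Feature(mz=400.0 + i, rt=5.0, intensity=v[j]) for i, v in enumerate(feats.values()) if v[j] > 0]
        for j in range(4)
    ]
    table = join_align(
        samples,
        ["mono-1", "int-1", "int-2", "ctrl-1"],
        ["monoculture", "interaction:C.albicans", "interaction:E.coli", "control"],
    )
    order = np.argsort(table.mz)
    return table, [list(feats)[i] for i in order]


def test_group_provenance_classes():
    table, names = provenance_table()
    classes = group_provenance(table, presence_threshold=5e3)
    expected = {
        "inter_only": "interaction-only",
        "shared": "shared",
        "mono_only": "monoculture-only",
        "in_control": "control",
    }
    assert classes == [expected[n] for n in names]


def test_group_provenance_requires_labels():
    table, _ = provenance_table()
    table.groups[0] = ""
    with pytest.raises(ValueError):
        group_provenance(table)
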