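"""Panel I/O, label binarization, merging and the synthetic generator."""

import numpy as np
import pytest

from mcbead.drug_data import (ChannelAssay, DrugPanel, DrugRecord,
                              PanelFormatError, PanelValidationError,
                              RiskLabel, apply_overrides, binarize_labels,
                              generate_synthetic_panel, merge_panels,
                              read_panel, write_panel)
from mcbead.pharm import block_profile, herg_ratio


def _panel():
    return DrugPanel(drugs=[
        DrugRecord(name="alpha",
                   assays=(ChannelAssay("IKr", 1000.0, 1.0),
                           ChannelAssay("ICaV", 5000.0, 1.3)),
                   eftpc=20.0,
                   labels=RiskLabel(crediblemeds="CM1", label_warning=True),
                   trapping=1.5),
        DrugRecord(name="beta",
                   assays=(ChannelAssay("IKr", 300.0, 0.8),),
                   eftpc=3.0,
                   labels=RiskLabel(redfern="R5", cipa="CP3")),
    ])


def test_round_trip_is_identical(tmp_path):
    panel = _panel()
    path = tmp_path / "panel.csv"
    write_panel(panel, path, provenance_path=tmp_path / "prov.json")
    back = read_panel(path)
    assert back.names() == panel.names()
    for orig, rec in zip(panel, back):
        assert rec.eftpc == pytest.approx(orig.eftpc)
        assert rec.trapping == orig.trapping or (
            orig.trapping is None and rec.trapping is None)
        assert rec.labels == orig.labels
        for ch in ("IKr", "ICaV"):
            a, b = orig.assay(ch), rec.assay(ch)
            assert (a is None) == (b is None)
            if a is not None:
                assert b.ic50 == pytest.approx(a.ic50)
                assert b.hill == pytest.approx(a.hill)


def test_missing_channel_is_zero_block_with_provenance(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("drug,IKr_ic50,eftpc\nsolo,1000,5\n")
    panel = read_panel(path)
    d = panel.get("solo")
    assert "assumed-zero:INaL" in d.provenance
    assert block_profile(d, 1e9)["INaL"] == 0.0


def test_missing_hill_defaults_to_one(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("drug,IKr_ic50,IKr_hill\na,1000,\nb,2000,2.0\n")
    panel = read_panel(path)
    assert panel.get("a").assay("IKr").hill == 1.0
    assert panel.get("b").assay("IKr").hill == 2.0


def test_unit_conversion_via_schema(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("compound,herg,plasma\nx,3.5,0.1\n")
    schema = {"name": "compound", "unit": "uM",
              "channels": {"IKr": {"ic50": "herg"}},
              "eftpc": "plasma"}
    panel = read_panel(path, schema=schema)
    assert panel.get("x").assay("IKr").ic50 == pytest.approx(3500.0)
    assert panel.get("x").eftpc == pytest.approx(100.0)


def test_empty_file_gives_empty_panel(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    assert len(read_panel(path)) == 0


def test_format_and_validation_errors(tmp_path):
    no_name = tmp_path / "a.csv"
    no_name.write_text("IKr_ic50\n100\n")
    with pytest.raises(PanelFormatError):
        read_panel(no_name)
    no_ikr = tmp_path / "b.csv"
    no_ikr.write_text("drug,ICaV_ic50\nx,100\n")
    with pytest.raises(PanelFormatError):
        read_panel(no_ikr)
    bad_ic50 = tmp_path / "c.csv"
    bad_ic50.write_text("drug,IKr_ic50\nx,100\ny,-5\n")
    with pytest.raises(PanelValidationError, match="row 1"):
        read_panel(bad_ic50)


@pytest.mark.parametrize("labels, definition, expected", [
    (RiskLabel(crediblemeds="CM1"), "target1", True),
    (RiskLabel(redfern="R4"), "target1", False),
    (RiskLabel(champeroux="CH1"), "target1", True),
    (RiskLabel(redfern="R5", label_warning=True), "target1", True),
    (RiskLabel(cipa="CP3"), "cipa_binary", False),
    (RiskLabel(cipa="CP2"), "cipa_binary", True),
    (RiskLabel(crediblemeds="CM3"), "target2", False),
    (RiskLabel(crediblemeds="CM2"), "target2", True),
    (RiskLabel(crediblemeds="CM3"), "target4", True),
])
def test_binarize_definitions(labels, definition, expected):
    panel = DrugPanel(drugs=[DrugRecord(
        name="d", assays=(ChannelAssay("IKr", 100.0),), labels=labels)])
    assert binarize_labels(panel, definition) == {"d": expected}


def test_binarize_excludes_unusable_and_is_idempotent():
    panel = DrugPanel(drugs=[
        DrugRecord(name="labeled", assays=(ChannelAssay("IKr", 1.0),),
                   labels=RiskLabel(crediblemeds="CM2")),
        DrugRecord(name="cipa_only", assays=(ChannelAssay("IKr", 1.0),),
                   labels=RiskLabel(cipa="CP1")),
    ])
    out = binarize_labels(panel, "target2")
    assert out == {"labeled": True}
    assert binarize_labels(panel, "target2") == out


def test_merge_averages_ic50_and_unions_labels():
    p1 = DrugPanel(drugs=[DrugRecord(
        name="Drug", assays=(ChannelAssay("IKr", 100.0),), eftpc=1.0,
        labels=RiskLabel(crediblemeds="CM3"))])
    p2 = DrugPanel(drugs=[DrugRecord(
        name="drug", assays=(ChannelAssay("IKr", 300.0),), eftpc=3.0,
        labels=RiskLabel(redfern="R2", crediblemeds="CM1"))])
    merged = merge_panels([p1, p2])
    assert len(merged) == 1
    d = merged.get("Drug")
    assert d.assay("IKr").ic50 == pytest.approx(200.0)
    assert d.eftpc == pytest.approx(2.0)
    assert d.labels.redfern == "R2"
    # CM1 vs CM3 conflict resolves to the higher-risk category
    assert d.labels.crediblemeds == "CM1"


def test_merge_passthrough_and_order_invariance():
    p1 = DrugPanel(drugs=[
        DrugRecord(name="only", assays=(ChannelAssay("IKr", 50.0, 1.2),),
                   eftpc=7.0),
        DrugRecord(name="both", assays=(ChannelAssay("IKr", 100.0),)),
    ])
    p2 = DrugPanel(drugs=[
        DrugRecord(name="both", assays=(ChannelAssay("IKr", 400.0),)),
    ])
    m12 = merge_panels([p1, p2])
    m21 = merge_panels([p2, p1])
    assert m12.get("only").assay("IKr").ic50 == 50.0
    assert m12.get("both").assay("IKr").ic50 == pytest.approx(250.0)
    for name in m12.names():
        a = m12.get(name).assay("IKr")
        b = m21.get(name).assay("IKr")
        assert a.ic50 == pytest.approx(b.ic50)


def test_label_overrides():
    panel = DrugPanel(drugs=[DrugRecord(
        name="Paroxetine-like", assays=(ChannelAssay("IKr", 1.0),),
        labels=RiskLabel(label_warning=True))])
    out = apply_overrides(panel, {"paroxetine-like": {
        "label_warning": False}})
    assert out.get("Paroxetine-like").labels.label_warning is False
    assert any("label-override" in p
               for p in out.get("Paroxetine-like").provenance)


def test_synthetic_panel_deterministic_and_separable():
    p1 = generate_synthetic_panel(50, 100, 30, 0.0, seed=11)
    p2 = generate_synthetic_panel(50, 100, 30, 0.0, seed=11)
    for a, b in zip(p1, p2):
        assert a == b
    labels = binarize_labels(p1, "target3")
    # noise 0: the generative rule itself classifies perfectly
    for d in p1:
        ratio = herg_ratio(d)
        cav = block_profile(
            d, ratio * d.eftpc)["ICaV"]  # block at IC60 = ratio*EFTPC
        assert labels[d.name] == (ratio < 100 and cav < 30)


def test_synthetic_panel_validation():
    with pytest.raises(ValueError):
        generate_synthetic_panel(3, 100, 30)
    with pytest.raises(ValueError):
        generate_synthetic_panel(10, 75, 30)
    with pytest.raises(ValueError):
        generate_synthetic_panel(10, 100, 130)
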