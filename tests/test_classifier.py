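"""Two-step classifier, one-step baseline, LOO and the ternary extension."""

import numpy as np
import pytest

from mcbead.classifier import (OneStepModel, TernaryModel, fit_one_step,
                               fit_ternary, fit_two_step, loo_accuracy)
from mcbead.drug_data import (ChannelAssay, DrugPanel, DrugRecord, RiskLabel,
                              binarize_labels, generate_synthetic_panel)
from mcbead.pharm import concentration_at_block, herg_ratio


@pytest.fixture(scope="module")
def recovery_panel():
    panel = generate_synthetic_panel(200, ratio_threshold=100,
                                     cav_cutoff=30, noise_sd=0.0, seed=42)
    return panel, binarize_labels(panel, "target3")


def test_two_step_recovers_generative_rule(recovery_panel):
    panel, labels = recovery_panel
    model = fit_two_step(panel, labels, features=("ICaV",))
    assert model.ratio_threshold == 100.0
    assert model.training_accuracy == 100.0
    boundary = -model.intercept / model.coefficients[0]
    assert boundary == pytest.approx(30.0, abs=5.0)


def test_gated_drug_predicted_negative(recovery_panel):
    panel, labels = recovery_panel
    model = fit_two_step(panel, labels, features=("ICaV",))
    a = ChannelAssay("IKr", 1000.0)
    drug = DrugRecord(name="faraway", assays=(a,),
                      eftpc=concentration_at_block(a, 0.6) / 500.0)
    assert herg_ratio(drug) == pytest.approx(500.0)
    assert model.predict_drug(drug) is False


def test_step1_separable_panel_perfect_at_smallest_gate():
    # TdP+ all with ratio < 50 and zero non-hERG block; TdP- all > 200
    drugs, labels = [], {}
    a = ChannelAssay("IKr", 1000.0)
    ic60 = concentration_at_block(a, 0.6)
    for i in range(10):
        pos = i % 2 == 0
        ratio = 10.0 if pos else 400.0
        drugs.append(DrugRecord(name=f"d{i}", assays=(a,),
                                eftpc=ic60 / ratio))
        labels[f"d{i}"] = pos
    model = fit_two_step(DrugPanel(drugs=drugs), labels, features=("ICaV",))
    assert model.training_accuracy == 100.0
    assert model.ratio_threshold == 50.0  # tie-break: smallest gate


def test_one_step_trivial_cases():
    a = ChannelAssay("IKr", 1000.0)
    drugs = [DrugRecord(name=f"d{i}", assays=(
        a, ChannelAssay("ICaV", 100.0 * (i + 1))), eftpc=100.0)
        for i in range(8)]
    panel = DrugPanel(drugs=drugs)
    # separable on the ICaV feature
    labels = {f"d{i}": i < 4 for i in range(8)}
    m = fit_one_step(panel, labels, features=("ICaV",))
    assert m.training_accuracy == 100.0
    # identical features: intercept-only majority prediction
    same = DrugPanel(drugs=[DrugRecord(
        name=f"s{i}", assays=(a, ChannelAssay("ICaV", 500.0)), eftpc=100.0)
        for i in range(9)])
    labels2 = {f"s{i}": i < 6 for i in range(9)}
    m2 = fit_one_step(same, labels2, features=("ICaV",))
    preds = [m2.predict_drug(d) for d in same]
    assert all(preds)  # majority class is positive
    assert m2.training_accuracy == pytest.approx(100.0 * 6 / 9)


def test_one_step_never_beats_two_step_on_generative_family():
    diffs = []
    for seed in range(50):
        panel = generate_synthetic_panel(60, 100, 30, 0.0, seed=seed)
        labels = binarize_labels(panel, "target3")
        two = fit_two_step(panel, labels, features=("ICaV",))
        one = fit_one_step(panel, labels, features=("IKr", "ICaV"))
        diffs.append(two.training_accuracy - one.training_accuracy)
    assert np.mean(diffs) >= 0.0


def test_loo_perfect_on_separable_panel(recovery_panel):
    panel, labels = recovery_panel
    sub = DrugPanel(drugs=list(panel)[:40], source="sub")
    sub_labels = {d.name: labels[d.name] for d in sub}
    acc = loo_accuracy(sub, sub_labels,
                       lambda p, l: fit_two_step(p, l, features=("ICaV",)))
    assert acc == 100.0


def test_loo_recovers_rule_at_n100(recovery_panel):
    panel, labels = recovery_panel
    sub = DrugPanel(drugs=list(panel)[:100], source="sub")
    sub_labels = {d.name: labels[d.name] for d in sub}
    acc = loo_accuracy(sub, sub_labels,
                       lambda p, l: fit_two_step(p, l, features=("ICaV",)))
    assert acc == 100.0
    model = fit_two_step(sub, sub_labels, features=("ICaV",))
    assert model.ratio_threshold == 100.0
    assert -model.intercept / model.coefficients[0] == pytest.approx(
        30.0, abs=10.0)


def test_loo_random_balanced_labels_near_chance(recovery_panel):
    # with class-balanced random labels the features carry no signal, so
    # LOO accuracy must fall inside the binomial null band around 50%
    panel, _ = recovery_panel
    rng = np.random.default_rng(123)
    names = panel.names()
    values = rng.permutation([i % 2 == 0 for i in range(len(names))])
    permuted = dict(zip(names, map(bool, values)))
    acc = loo_accuracy(panel, permuted,
                       lambda p, l: fit_two_step(p, l, features=("ICaV",)))
    # binomial 95% band around 0.5 at n=200 is roughly +-7 points
    assert 40.0 <= acc <= 60.0


def test_loo_minimal_panel_quantization():
    a = ChannelAssay("IKr", 1000.0)
    ic60 = concentration_at_block(a, 0.6)
    drugs = [
        DrugRecord(name="p1", assays=(a, ChannelAssay("ICaV", 1e7)),
                   eftpc=ic60 / 10),
        DrugRecord(name="p2", assays=(a, ChannelAssay("ICaV", 1e7)),
                   eftpc=ic60 / 20),
        DrugRecord(name="n1", assays=(a, ChannelAssay("ICaV", 1.0)),
                   eftpc=ic60 / 400),
    ]
    labels = {"p1": True, "p2": True, "n1": False}
    acc = loo_accuracy(DrugPanel(drugs=drugs), labels,
                       lambda p, l: fit_two_step(p, l, features=("ICaV",)))
    assert acc in (0.0, pytest.approx(100 / 3), pytest.approx(200 / 3),
                   100.0)


def test_step2_invariant_to_eftpc_perturbation(recovery_panel):
    panel, labels = recovery_panel
    model = fit_two_step(panel, labels, features=("ICaV",))
    from dataclasses import replace
    for d in list(panel)[:20]:
        ratio = herg_ratio(d)
        factor = 1.2 if (ratio * 1.2 < model.ratio_threshold
                         or ratio >= model.ratio_threshold * 1.2) else 1.01
        perturbed = replace(d, eftpc=d.eftpc / factor)
        same_side = ((herg_ratio(perturbed) >= model.ratio_threshold)
                     == (ratio >= model.ratio_threshold))
        if same_side:
            assert model.predict_drug(perturbed) == model.predict_drug(d)


def _ternary_panel():
    """Three-tier panel constructed from the region definitions."""
    a = ChannelAssay("IKr", 1000.0)
    ic60 = concentration_at_block(a, 0.6)

    def drug(name, ratio, fsum, tier):
        # feature sum realized entirely through the trapping scalar so the
        # geometry is exact
        return DrugRecord(name=name, assays=(a,), eftpc=ic60 / ratio,
                          trapping=fsum, labels=RiskLabel(cipa=tier))

    drugs = [
        drug("h1", 5, 2.0, "CP1"), drug("h2", 10, 5.0, "CP1"),
        drug("h3", 3, 8.0, "CP1"),
        drug("i1", 60, 30.0, "CP2"), drug("i2", 100, 28.0, "CP2"),
        drug("i3", 40, 35.0, "CP2"),
        drug("l1", 500, 1.0, "CP3"), drug("l2", 90, 80.0, "CP3"),
        drug("l3", 1000, 90.0, "CP3"),
    ]
    return DrugPanel(drugs=drugs)


def test_ternary_regions_and_recovery():
    panel = _ternary_panel()
    model = fit_ternary(panel, features=("ICaV", "INaL", "trapping"))
    assert model.y_high <= model.y_low
    tiers = {"CP1": "high", "CP2": "intermediate", "CP3": "low"}
    for d in panel:
        assert model.predict_drug(d) == tiers[d.labels.cipa]
    # fixed x cuts: ratio above 150 is always low risk
    assert model.predict(500.0, 0.0) == "low"
    # ratio below 25 with a tiny feature sum is high risk
    assert model.predict(10.0, model.y_high - 1.0) == "high"


def test_two_step_json_round_trip(recovery_panel):
    from mcbead.classifier import TwoStepModel
    panel, labels = recovery_panel
    model = fit_two_step(panel, labels, features=("ICaV",))
    back = TwoStepModel.from_json(model.to_json())
    assert back.ratio_threshold == model.ratio_threshold
    assert np.allclose(back.coefficients, model.coefficients)
    for d in list(panel)[:10]:
        assert back.predict_drug(d) == model.predict_drug(d)
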