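"""Derived-feature pipeline: tensor contract, caching, heatmaps.

Trains are shortened drastically (a handful of beats) -- the contracts
under test (shapes, caching, EFTPC-independence, heatmap logic) do not
depend on reaching the true periodic steady state.
"""

import numpy as np
import pytest

from mcbead.biomarkers import METRIC_NAMES
from mcbead.derived_pipeline import (BiomarkerCache, feature_accuracy_heatmap,
                                     run_manifest)
from mcbead.drug_data import ChannelAssay, DrugPanel, DrugRecord, RiskLabel
from mcbead.myocyte import IntegratorConfig
from mcbead.pharm import concentration_at_block

FAST = IntegratorConfig(method="hybrid_rapid")


def tiny_panel():
    a1 = ChannelAssay("IKr", 1000.0)
    a2 = ChannelAssay("IKr", 5000.0)
    return DrugPanel(drugs=[
        DrugRecord(name="blocker",
                   assays=(a1, ChannelAssay("ICaV", 8000.0)), eftpc=50.0,
                   labels=RiskLabel(crediblemeds="CM1")),
        DrugRecord(name="weak",
                   assays=(a2,), eftpc=5.0,
                   labels=RiskLabel(crediblemeds="CM3")),
    ])


@pytest.fixture(scope="module")
def small_tensor():
    panel = tiny_panel()
    cache = BiomarkerCache()
    tensor, manifest = run_manifest(panel, "IC60_hERG", "OHR", n_beats=3,
                                    config=FAST, cache=cache)
    return panel, cache, tensor, manifest


def test_tensor_shape_contract(small_tensor):
    panel, _, tensor, manifest = small_tensor
    assert tensor.shape == (2, 3, 3, 13)
    assert list(tensor.metric.values) == list(METRIC_NAMES)
    assert manifest.n_failed == 0
    assert np.isfinite(tensor.values).all()


def test_rerun_is_pure_cache_hit(small_tensor):
    panel, cache, tensor, _ = small_tensor
    misses_before = cache.misses
    tensor2, _ = run_manifest(panel, "IC60_hERG", "OHR", n_beats=3,
                              config=FAST, cache=cache)
    assert cache.misses == misses_before     # zero new simulations
    assert np.array_equal(tensor.values, tensor2.values)


def test_placebo_drug_equals_drug_free_baseline():
    placebo = DrugPanel(drugs=[
        DrugRecord(name="placebo",
                   assays=(ChannelAssay("IKr", 1e12),), eftpc=1e-3),
        DrugRecord(name="none",
                   assays=(ChannelAssay("IKr", 1e12),), eftpc=1e-6),
    ])
    tensor, _ = run_manifest(placebo, "EFTPC", "OHR", n_beats=2, config=FAST,
                             cell_types=("mid",), cycle_lengths=(500.0,))
    a = tensor.sel(drug="placebo").values
    b = tensor.sel(drug="none").values
    assert np.allclose(a, b, rtol=1e-9)


def test_ic60_rule_independent_of_eftpc():
    from dataclasses import replace
    panel = tiny_panel()
    shifted = DrugPanel(drugs=[replace(d, eftpc=d.eftpc * 13.0)
                               for d in panel])
    kw = dict(n_beats=2, config=FAST, cell_types=("mid",),
              cycle_lengths=(500.0,))
    t1, _ = run_manifest(panel, "IC60_hERG", "OHR", **kw)
    t2, _ = run_manifest(shifted, "IC60_hERG", "OHR", **kw)
    assert np.allclose(t1.values, t2.values, rtol=1e-12)
    # whereas at the EFTPC rule the tensor moves with EFTPC
    e1, _ = run_manifest(panel, "EFTPC", "OHR", **kw)
    e2, _ = run_manifest(shifted, "EFTPC", "OHR", **kw)
    assert not np.allclose(e1.values, e2.values, rtol=1e-6)


def test_channel_restriction():
    panel = tiny_panel()
    kw = dict(n_beats=2, config=FAST, cell_types=("mid",),
              cycle_lengths=(500.0,))
    full, _ = run_manifest(panel, "IC60_hERG", "OHR", **kw)
    minimal, _ = run_manifest(panel, "IC60_hERG", "OHR",
                              channels=("IKr",), **kw)
    # "blocker" has an ICaV assay: restricting channels changes its run
    assert not np.allclose(full.sel(drug="blocker").values,
                           minimal.sel(drug="blocker").values)
    # "weak" has only IKr: identical either way
    assert np.allclose(full.sel(drug="weak").values,
                       minimal.sel(drug="weak").values)


def _fake_tensor(values_by_drug, rule="IC60_hERG"):
    import xarray as xr
    drugs = list(values_by_drug)
    data = np.zeros((len(drugs), 1, 1, len(METRIC_NAMES)))
    for i, d in enumerate(drugs):
        data[i, 0, 0, :] = values_by_drug[d]
    return xr.DataArray(
        data, dims=("drug", "cell_type", "cycle_length", "metric"),
        coords={"drug": drugs, "cell_type": ["mid"],
                "cycle_length": [500.0], "metric": list(METRIC_NAMES)},
        attrs={"concentration_rule": rule})


def _labeled_panel(n=16, seed=0):
    rng = np.random.default_rng(seed)
    a = ChannelAssay("IKr", 1000.0)
    ic60 = concentration_at_block(a, 0.6)
    drugs = []
    for i in range(n):
        ratio = 10.0 ** rng.uniform(0, 1.5)   # everything below any gate
        drugs.append(DrugRecord(name=f"d{i}", assays=(a,),
                                eftpc=ic60 / ratio))
    return DrugPanel(drugs=drugs)


def test_heatmap_apd_determined_risk():
    # risk is exactly "apd90 above cutoff": the apd90 cell must hit 100%,
    # an uninformative feature stays near the majority rate
    panel = _labeled_panel()
    rng = np.random.default_rng(1)
    apd = {d.name: 250.0 + 100.0 * (i % 2) + rng.normal(0, 1)
           for i, d in enumerate(panel)}
    labels = {n: apd[n] > 300.0 for n in apd}
    vals = {}
    i_apd = METRIC_NAMES.index("apd90")
    i_rest = METRIC_NAMES.index("resting_voltage")
    for n in apd:
        row = np.zeros(len(METRIC_NAMES))
        row[i_apd] = apd[n]
        row[i_rest] = -88.0 + rng.normal(0, 0.1)  # noise, no signal
        vals[n] = row
    tensor = _fake_tensor(vals)
    heat = feature_accuracy_heatmap(tensor, panel, labels)
    assert float(heat.sel(metric="apd90").squeeze()) == 100.0
    assert float(heat.sel(metric="resting_voltage").squeeze()) <= 70.0


def test_heatmap_identical_labels_report_majority_rate():
    panel = _labeled_panel(8)
    labels = {d.name: True for d in panel}
    vals = {d.name: np.arange(13.0) + i for i, d in enumerate(panel)}
    heat = feature_accuracy_heatmap(_fake_tensor(vals), panel, labels)
    # all-positive labels: every cell scores the majority rate, 100%
    assert np.allclose(heat.values, 100.0)


def test_heatmap_deterministic():
    panel = _labeled_panel(10, seed=3)
    rng = np.random.default_rng(2)
    vals = {d.name: rng.normal(size=13) for d in panel}
    labels = {d.name: i % 2 == 0 for i, d in enumerate(panel)}
    t = _fake_tensor(vals)
    h1 = feature_accuracy_heatmap(t, panel, labels)
    h2 = feature_accuracy_heatmap(t, panel, labels)
    assert np.array_equal(h1.values, h2.values)
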