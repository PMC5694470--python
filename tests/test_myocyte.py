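"""Myocyte model construction, pacing protocols and integrator behavior.

Simulation tests use short trains so the whole module stays inside a few
minutes; the acceptance suite exercises the full published protocols.
"""

import numpy as np
import pytest

from mcbead import _ord
from mcbead.biomarkers import compute_biomarkers
from mcbead.myocyte import (CellModelSpec, IntegratorConfig, build_model,
                            pace_to_steady, pause_protocol)

EULER = IntegratorConfig(method="forward_euler_fixed", dt=0.001)


def test_build_model_rejects_bad_specs():
    with pytest.raises(ValueError):
        CellModelSpec(variant="nonsense").params()
    with pytest.raises(ValueError):
        CellModelSpec(cell_type="apex").params()
    with pytest.raises(ValueError):
        CellModelSpec(conductance_scaling={"IKr": 1.5}).params()
    with pytest.raises(ValueError):
        CellModelSpec(conductance_scaling={"IXyz": 0.5}).params()


def test_drug_scaling_multiplies_conductances():
    base = CellModelSpec(variant="OHR", cell_type="mid").params()
    blocked = CellModelSpec(variant="OHR", cell_type="mid",
                            conductance_scaling={"IKr": 0.4}).params()
    assert blocked[_ord.PGKR] == pytest.approx(0.4 * base[_ord.PGKR])
    assert blocked[_ord.PPCA] == base[_ord.PPCA]


def test_variant_rescaling_and_lqt3():
    ohr = CellModelSpec(variant="OHR", cell_type="mid").params()
    mv = CellModelSpec(variant="OHRmv", cell_type="mid").params()
    for name, factor in _ord.DUTTA_SCALE.items():
        i = _ord.PARAM_NAMES.index(name)
        assert mv[i] == pytest.approx(factor * ohr[i])
    lqt3 = CellModelSpec(variant="OHRmv", cell_type="mid",
                         gnal_scale=2.0).params()
    assert lqt3[_ord.PGNAL] == pytest.approx(2.0 * mv[_ord.PGNAL])


def test_single_beat_advances_state():
    m = build_model(CellModelSpec())
    s0 = m.state.copy()
    trace = pace_to_steady(m, 1000.0, n_beats=1, config=EULER)
    assert not np.allclose(m.state, s0)
    assert trace.vm.max() > 0.0          # captured beat
    assert len(trace.time) == len(trace.vm) == len(trace.cai)
    assert np.all(np.diff(trace.time) > 0)


def test_resting_potential_matches_published_model():
    m = build_model(CellModelSpec(variant="OHR", cell_type="endo"))
    trace = pace_to_steady(m, 1000.0, n_beats=5, config=EULER)
    # diastolic value just before the final stimulus
    assert trace.vm[0] == pytest.approx(-88.0, abs=1.0)


def test_determinism_bit_identical():
    def run():
        m = build_model(CellModelSpec(cell_type="mid",
                                      conductance_scaling={"IKr": 0.5}))
        return pace_to_steady(m, 500.0, n_beats=3, config=EULER)

    a, b = run(), run()
    assert np.array_equal(a.vm, b.vm)
    assert np.array_equal(a.cai, b.cai)


def test_halving_dt_changes_apd90_below_half_ms():
    apd = {}
    for dt in (0.001, 0.0005):
        m = build_model(CellModelSpec(variant="OHR", cell_type="endo"))
        cfg = IntegratorConfig(method="forward_euler_fixed", dt=dt)
        trace = pace_to_steady(m, 500.0, n_beats=10, config=cfg)
        apd[dt] = compute_biomarkers(trace, -1).apd90
    assert abs(apd[0.001] - apd[0.0005]) < 0.5


def test_hybrid_matches_euler_on_short_train():
    res = {}
    for method in ("forward_euler_fixed", "hybrid_rapid"):
        m = build_model(CellModelSpec(variant="OHR", cell_type="mid"))
        trace = pace_to_steady(m, 500.0, n_beats=20,
                               config=IntegratorConfig(method=method))
        res[method] = compute_biomarkers(trace, -1)
    assert res["hybrid_rapid"].apd90 == pytest.approx(
        res["forward_euler_fixed"].apd90, abs=1.0)
    assert res["hybrid_rapid"].cat_amplitude == pytest.approx(
        res["forward_euler_fixed"].cat_amplitude, rel=0.05)


def test_pause_zero_degenerates_to_steady_pacing():
    m1 = build_model(CellModelSpec(cell_type="mid"))
    tr_pause = pause_protocol(m1, 500.0, n_stimuli=20, pause=0.0,
                              config=EULER)
    m2 = build_model(CellModelSpec(cell_type="mid"))
    tr_steady = pace_to_steady(m2, 500.0, n_beats=21, config=EULER)
    apd_pause = compute_biomarkers(tr_pause, -1).apd90
    apd_steady = compute_biomarkers(tr_steady, -1).apd90
    assert apd_pause == pytest.approx(apd_steady, abs=2.0)


def test_pause_protocol_trace_layout():
    m = build_model(CellModelSpec(cell_type="mid"))
    trace = pause_protocol(m, 500.0, n_stimuli=5, pause=800.0, config=EULER,
                           post_window=400.0, pause_reference="stimulus")
    assert trace.n_beats == 2
    s1, s2 = trace.beat_markers
    assert s2 - s1 == pytest.approx(800.0)
    assert trace.time[-1] == pytest.approx(s2 + 400.0)
    with pytest.raises(ValueError):
        pause_protocol(m, 500.0, n_stimuli=5, pause=-1.0, config=EULER)


def test_vtable_matches_exact_expressions():
    vmin, inv_dv, table = _ord.default_vtable()
    out = np.empty(_ord.N_VDEP)
    rng = np.random.default_rng(0)
    for v in rng.uniform(-110.0, 60.0, size=200):
        _ord._vdep(v, out)
        i = (v - vmin) * inv_dv
        lo = int(i)
        w = i - lo
        interp = table[lo] * (1 - w) + table[lo + 1] * w
        # the stiffest expression (phase-1 recovery development time, with
        # a 0.2 mV length scale) dominates the interpolation error
        assert np.allclose(interp, out, rtol=1e-4, atol=1e-12)


def test_trace_export_round_trip(tmp_path):
    m = build_model(CellModelSpec())
    trace = pace_to_steady(m, 500.0, n_beats=1, config=EULER)
    out = tmp_path / "trace.tsv"
    meta = tmp_path / "trace.json"
    trace.export(out, metadata_path=meta)
    data = np.loadtxt(out, skiprows=1)
    assert data.shape[0] == len(trace.time)
    assert np.allclose(data[:, 1], trace.vm)
    import json
    md = json.loads(meta.read_text())
    assert md["cycle_length"] == 500.0
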