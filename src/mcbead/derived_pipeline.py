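"""Derived-feature study orchestration.

Every drug is simulated to steady state in 3 cell types x 3 pacing rates
(0.5, 1 and 2 Hz -> cycle lengths 2000, 1000, 500 ms), at one of two
concentration rules (EFTPC or the 60%-hERG-block concentration), and the 13
AP/Ca biomarkers are extracted per simulation, giving a
(drug x cell x rate x 13) tensor.  Single-feature logistic classifiers per
(feature, cell, rate) cell produce the accuracy heatmaps that compare
derived features against the direct-feature classifier.

Steady-state runs use the hybrid rapid integrator; any EAD decision made in
this pipeline comes from ``eadspace`` (fixed-step Euler), never from the
hybrid traces.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .biomarkers import METRIC_NAMES, compute_biomarkers
from .classifier import RATIO_THRESHOLDS, _fit_logit, _Logit
from .drug_data import DrugPanel, DrugRecord
from .myocyte import (CellModelSpec, IntegratorConfig, SimulationFailure,
                      build_model, pace_to_steady)
from .pharm import block_profile, concentration_at_block, herg_ratio

logger = logging.getLogger("mcbead")

__all__ = ["SimulationManifest", "BiomarkerCache", "run_manifest",
           "feature_accuracy_heatmap", "CELL_TYPES", "CYCLE_LENGTHS"]

CELL_TYPES = ("endo", "mid", "epi")
CYCLE_LENGTHS = (500.0, 1000.0, 2000.0)


class BiomarkerCache:
    """Content-addressed biomarker cache: job-input hash -> metric vector.

    Completed jobs are immutable; reruns with unchanged inputs are cache
    hits and cost nothing.
    """

    def __init__(self):
        self._store: dict[str, np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def key(variant: str, cell_type: str, cycle_length: float,
            scaling: dict[str, float], n_beats: int, method: str) -> str:
        payload = json.dumps({
            "variant": variant, "cell": cell_type, "cl": cycle_length,
            "scaling": {k: round(v, 12) for k, v in sorted(scaling.items())},
            "n_beats": n_beats, "method": method}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def get(self, key: str):
        v = self._store.get(key)
        if v is not None:
            self.hits += 1
        return v

    def put(self, key: str, value: np.ndarray):
        if key in self._store:
            return
        self.misses += 1
        self._store[key] = value.copy()


@dataclass
class SimulationManifest:
    """Job grid for one panel/rule/variant run, with per-job status."""

    concentration_rule: str
    variant: str
    jobs: list = field(default_factory=list)     # (drug, cell, cl)
    status: dict = field(default_factory=dict)   # job -> "done"/"failed"/...

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.status.values() if s == "failed")


def _job_biomarkers(drug: DrugRecord, rule: str, variant: str,
                    cell_type: str, cycle_length: float,
                    n_beats: int, config: IntegratorConfig,
                    cache: BiomarkerCache) -> np.ndarray:
    if rule == "IC60_hERG":
        a = drug.assay("IKr")
        if a is None:
            raise ValueError(f"{drug.name}: no IKr assay")
        c = concentration_at_block(a, 0.6)
    elif rule == "EFTPC":
        if drug.eftpc is None:
            raise ValueError(f"{drug.name}: no EFTPC")
        c = drug.eftpc
    else:
        raise ValueError(f"unknown concentration rule {rule!r}")
    prof = block_profile(drug, c)
    scaling = {ch: 1.0 - b / 100.0 for ch, b in prof.block.items()}
    key = cache.key(variant, cell_type, cycle_length, scaling, n_beats,
                    config.method)
    hit = cache.get(key)
    if hit is not None:
        return hit
    model = build_model(CellModelSpec(variant=variant, cell_type=cell_type,
                                      conductance_scaling=scaling))
    trace = pace_to_steady(model, cycle_length, n_beats=n_beats,
                           config=config)
    vec = compute_biomarkers(trace, beat=-1).metrics_vector()
    cache.put(key, vec)
    return vec


def run_manifest(panel: DrugPanel, concentration_rule: str = "IC60_hERG",
                 variant: str = "OHR", n_beats: int = 1000,
                 config: IntegratorConfig | None = None,
                 cache: BiomarkerCache | None = None,
                 cell_types=CELL_TYPES, cycle_lengths=CYCLE_LENGTHS,
                 channels: tuple | None = None):
    """Simulate the full job grid and return the biomarker tensor.

    Returns (DataArray with dims drug/cell_type/cycle_length/metric,
    SimulationManifest).  Per-job failures are recorded and leave NaNs for
    that drug; they never abort the run.  ``channels`` optionally restricts
    which blocked channels are applied (e.g. ("IKr", "ICaV") for the
    minimal set); None applies every assayed channel.
    """
    config = config or IntegratorConfig(method="hybrid_rapid")
    cache = cache if cache is not None else BiomarkerCache()
    if channels is not None:
        panel = DrugPanel(
            drugs=[_restrict_channels(d, channels) for d in panel],
            source=panel.source)
    manifest = SimulationManifest(concentration_rule=concentration_rule,
                                  variant=variant)
    data = np.full((len(panel), len(cell_types), len(cycle_lengths),
                    len(METRIC_NAMES)), np.nan)
    for i, drug in enumerate(panel):
        for j, ct in enumerate(cell_types):
            for k, cl in enumerate(cycle_lengths):
                job = (drug.name, ct, cl)
                manifest.jobs.append(job)
                try:
                    data[i, j, k] = _job_biomarkers(
                        drug, concentration_rule, variant, ct, cl,
                        n_beats, config, cache)
                    manifest.status[job] = "done"
                except (SimulationFailure, ValueError) as exc:
                    logger.warning("job %s failed: %s", job, exc)
                    manifest.status[job] = "failed"
    tensor = xr.DataArray(
        data,
        dims=("drug", "cell_type", "cycle_length", "metric"),
        coords={"drug": panel.names(), "cell_type": list(cell_types),
                "cycle_length": list(cycle_lengths),
                "metric": list(METRIC_NAMES)},
        attrs={"concentration_rule": concentration_rule, "variant": variant,
               "n_beats": n_beats, "integrator": config.method})
    return tensor, manifest


def _restrict_channels(drug: DrugRecord, channels) -> DrugRecord:
    from dataclasses import replace
    kept = tuple(a for a in drug.assays if a.channel in channels)
    return replace(drug, assays=kept,
                   provenance=drug.provenance + ("channel-restricted",))


# ---------------------------------------------------------------------------
# Per-feature accuracy heatmap
# ---------------------------------------------------------------------------

class _FeatureTwoStep:
    """Two-step classifier whose step-2 feature is a per-drug scalar from
    the biomarker tensor (gate re-selected per fit, as in the direct case).
    """

    def __init__(self, values: dict[str, float], thresholds=RATIO_THRESHOLDS):
        self.values = values
        self.thresholds = thresholds
        self.ratio_threshold = None
        self._logit = None

    def fit(self, panel: DrugPanel, labels: dict[str, bool]):
        drugs = [d for d in panel if d.name in labels]
        y = np.array([labels[d.name] for d in drugs])
        ratios = [herg_ratio(d) for d in drugs]
        X = np.array([[self.values[d.name]] for d in drugs])
        best = None
        for thr in self.thresholds:
            below = np.array([(r is None) or (r < thr) for r in ratios])
            logit = _fit_logit(X[below], y[below]) if below.sum() else \
                _Logit(-37.0, np.zeros(1))
            pred = np.zeros(len(drugs), dtype=bool)
            pred[below] = logit.predict(X[below])
            acc = float(np.mean(pred == y))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, thr, logit)
        _, self.ratio_threshold, self._logit = best
        return self

    def predict_drug(self, drug: DrugRecord) -> bool:
        r = herg_ratio(drug)
        if r is not None and r >= self.ratio_threshold:
            return False
        return bool(self._logit.predict(
            np.array([[self.values[drug.name]]]))[0])


class _FeatureOneStep:
    def __init__(self, values: dict[str, float]):
        self.values = values
        self._logit = None

    def fit(self, panel: DrugPanel, labels: dict[str, bool]):
        drugs = [d for d in panel if d.name in labels]
        y = np.array([labels[d.name] for d in drugs])
        X = np.array([[self.values[d.name]] for d in drugs])
        self._logit = _fit_logit(X, y)
        return self

    def predict_drug(self, drug: DrugRecord) -> bool:
        return bool(self._logit.predict(
            np.array([[self.values[drug.name]]]))[0])


def feature_accuracy_heatmap(tensor: xr.DataArray, panel: DrugPanel,
                             labels: dict[str, bool]) -> xr.DataArray:
    """LOO accuracy of a single-feature classifier per (metric, cell, rate).

    ``labels`` may be TdP labels or EAD-classification outputs.  When the
    tensor was computed at the 60%-hERG-block rule the classifier is the
    two-step model (gate + single-feature logistic); at EFTPC it is the
    plain one-step logistic, mirroring how each rule is meant to be used.
    Constant feature columns yield the majority-class rate and are flagged.
    """
    from .classifier import loo_accuracy

    rule = tensor.attrs.get("concentration_rule", "IC60_hERG")
    two_step = rule == "IC60_hERG"
    drugs = [d for d in panel if d.name in labels
             and not np.isnan(tensor.sel(drug=d.name)).any()]
    sub = DrugPanel(drugs=drugs, source=panel.source)
    sub_labels = {d.name: labels[d.name] for d in drugs}
    out = np.full((len(METRIC_NAMES), len(tensor.cell_type),
                   len(tensor.cycle_length)), np.nan)
    for im, metric in enumerate(METRIC_NAMES):
        for jc, ct in enumerate(tensor.cell_type.values):
            for kr, cl in enumerate(tensor.cycle_length.values):
                vals = {str(n): float(tensor.sel(
                    drug=n, cell_type=ct, cycle_length=cl, metric=metric))
                    for n in sub.names()}
                if len(set(vals.values())) <= 1:
                    maj = max((sum(1 for v in sub_labels.values() if v is b)
                               for b in (True, False)))
                    out[im, jc, kr] = 100.0 * maj / len(sub_labels)
                    logger.warning("constant feature %s at (%s, %s); "
                                   "majority rate reported", metric, ct, cl)
                    continue

                def fitter(p, l, _vals=vals):
                    cls = (_FeatureTwoStep(_vals) if two_step
                           else _FeatureOneStep(_vals))
                    return cls.fit(p, l)

                out[im, jc, kr] = loo_accuracy(sub, sub_labels, fitter)
    return xr.DataArray(
        out, dims=("metric", "cell_type", "cycle_length"),
        coords={"metric": list(METRIC_NAMES),
                "cell_type": tensor.cell_type.values,
                "cycle_length": tensor.cycle_length.values},
        attrs={"concentration_rule": rule,
               "classifier": "two_step" if two_step else "one_step"})
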