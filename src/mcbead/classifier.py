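"""Two-step TdP risk classifier (MCB@EAD), one-step baseline, LOO, ternary.

Step 1 gates on the hERG ratio (IC60_hERG / EFTPC): drugs at or above the
selected threshold are called non-torsadogenic outright.  Step 2 fits a
logistic regression

    P(TdP+) = 1 / (1 + exp(-(b0 + sum_i b_i * feature_i)))

on the remaining drugs, with features evaluated at the 60%-hERG-block
concentration (so step 2 is independent of the drug's plasma level).  Four
candidate ratio thresholds (50, 100, 150, 200) are tried and the one with
the best overall training accuracy -- counting gated drugs as TdP-
predictions -- is kept, ties resolving to the smallest (most conservative)
gate.

The one-step baseline is the same logistic model on features at EFTPC with
no gate.  Predictive performance is assessed with leave-one-out cross
validation; threshold selection runs inside the LOO loop by default.

The ternary extension for the three-tier CiPA categories uses an
equal-weight feature sum (% ICaV block + % INaL block + trapping scalar)
with two fitted y-thresholds (-b0/bf) and two fixed hERG-ratio cuts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .drug_data import DrugPanel, DrugRecord
from .pharm import CHANNELS, block_profile, concentration_at_block, herg_ratio

logger = logging.getLogger("mcbead")

__all__ = [
    "FeatureMatrix", "TwoStepModel", "OneStepModel", "TernaryModel",
    "RATIO_THRESHOLDS", "build_direct_features", "fit_two_step",
    "fit_one_step", "loo_accuracy", "fit_ternary",
]

#: candidate step-1 gates
RATIO_THRESHOLDS = (50.0, 100.0, 150.0, 200.0)

#: very weak ridge (1e-6 relative) to stabilize separable fits
_RIDGE_C = 1.0e6


@dataclass
class FeatureMatrix:
    """Per-drug feature values with provenance of the concentration rule."""

    drug_names: list[str]
    feature_names: list[str]
    X: np.ndarray
    concentration_rule: str  # "IC60_hERG" or "EFTPC"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.drug_names), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    def row(self, name: str) -> np.ndarray:
        return self.X[self.drug_names.index(name)]


def _drug_concentration(drug: DrugRecord, rule: str) -> float | None:
    if rule == "IC60_hERG":
        a = drug.assay("IKr")
        return None if a is None else concentration_at_block(a, 0.6)
    if rule == "EFTPC":
        return drug.eftpc
    raise ValueError(f"unknown concentration rule {rule!r}")


def drug_features(drug: DrugRecord, features, rule: str) -> np.ndarray | None:
    """Feature vector for one drug, or None when the rule's concentration
    is unavailable.  Feature names are channel names (percent block at the
    rule concentration) or "trapping" (0 when absent)."""
    c = _drug_concentration(drug, rule)
    if c is None:
        return None
    prof = block_profile(drug, c)
    vals = []
    for f in features:
        if f == "trapping":
            vals.append(drug.trapping if drug.trapping is not None else 0.0)
        elif f in CHANNELS:
            vals.append(prof[f])
        else:
            raise ValueError(f"unknown feature {f!r}")
    return np.array(vals, dtype=float)


def build_direct_features(panel: DrugPanel, features=("ICaV",),
                          rule: str = "IC60_hERG") -> FeatureMatrix:
    """Direct features (percent block, optional trapping) for a panel.

    Drugs for which the rule concentration cannot be computed (no IKr assay
    under IC60_hERG; no EFTPC under EFTPC) are skipped with a warning.
    """
    names, rows = [], []
    for d in panel:
        x = drug_features(d, features, rule)
        if x is None:
            logger.warning("drug %s lacks data for rule %s; skipped",
                           d.name, rule)
            continue
        names.append(d.name)
        rows.append(x)
    X = np.array(rows) if rows else np.zeros((0, len(features)))
    return FeatureMatrix(names, list(features), X, rule)


# ---------------------------------------------------------------------------
# Logistic building block
# ---------------------------------------------------------------------------

@dataclass
class _Logit:
    intercept: float
    coef: np.ndarray

    def prob(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))

    def predict(self, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
        return self.prob(X) >= cutoff


def _fit_logit(X: np.ndarray, y: np.ndarray) -> _Logit:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        # single-class training set: constant predictor
        z = 37.0 if y.all() else -37.0
        return _Logit(z, np.zeros(X.shape[1]))
    lr = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=10000)
    lr.fit(X, y.astype(int))
    return _Logit(float(lr.intercept_[0]), lr.coef_[0].astype(float))


# ---------------------------------------------------------------------------
# Two-step model
# ---------------------------------------------------------------------------

@dataclass
class TwoStepModel:
    """Fitted gate threshold + step-2 logistic coefficients."""

    ratio_threshold: float
    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    concentration_rule: str = "IC60_hERG"
    cutoff: float = 0.5
    definition: str | None = None
    training_accuracy: float | None = None

    def predict(self, ratio: float | None, x: np.ndarray) -> bool:
        """Predict TdP+ from a hERG ratio and a step-2 feature vector.

        A drug at/above the gate is TdP-; a drug without a ratio (missing
        EFTPC or IKr) is routed directly to step 2.
        """
        if ratio is not None and ratio >= self.ratio_threshold:
            return False
        z = self.intercept + float(np.dot(self.coefficients, x))
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))) >= self.cutoff

    def predict_drug(self, drug: DrugRecord) -> bool:
        x = drug_features(drug, self.feature_names, self.concentration_rule)
        if x is None:
            raise ValueError(f"cannot compute features for {drug.name}")
        return self.predict(herg_ratio(drug), x)

    def to_json(self) -> str:
        return json.dumps({
            "model": "two_step",
            "ratio_threshold": self.ratio_threshold,
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "feature_names": self.feature_names,
            "concentration_rule": self.concentration_rule,
            "cutoff": self.cutoff,
            "definition": self.definition,
            "training_accuracy": self.training_accuracy,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TwoStepModel":
        d = json.loads(text)
        d.pop("model", None)
        d["coefficients"] = np.asarray(d["coefficients"], dtype=float)
        return cls(**d)


def fit_two_step(panel: DrugPanel, labels: dict[str, bool],
                 features=("ICaV",),
                 thresholds=RATIO_THRESHOLDS,
                 definition: str | None = None) -> TwoStepModel:
    """Fit the two-step classifier on a labeled panel.

    For each candidate gate, drugs at/above it are predicted TdP- and a
    logistic regression is fitted on the below-gate drugs using features at
    the 60%-hERG-block concentration; the gate with the best overall
    training accuracy (over all labeled drugs) wins, ties going to the
    smallest gate.
    """
    drugs = [d for d in panel if d.name in labels]
    if not drugs:
        raise ValueError("no labeled drugs in panel")
    y_all = np.array([labels[d.name] for d in drugs])
    ratios = [herg_ratio(d) for d in drugs]
    feats = []
    for d in drugs:
        x = drug_features(d, features, "IC60_hERG")
        if x is None:
            raise ValueError(f"drug {d.name} lacks an IKr assay; cannot "
                             "evaluate features at IC60_hERG")
        feats.append(x)
    X_all = np.array(feats)
    for d, r in zip(drugs, ratios):
        if r is None:
            logger.warning("drug %s has no hERG ratio; bypasses step-1 gate",
                           d.name)

    best = None
    any_fittable = False
    for thr in thresholds:
        below = np.array([(r is None) or (r < thr) for r in ratios])
        y_below = y_all[below]
        if below.sum() > 0 and len(np.unique(y_below)) == 2:
            any_fittable = True
        logit = _fit_logit(X_all[below], y_below) if below.sum() else \
            _Logit(-37.0, np.zeros(X_all.shape[1]))
        pred = np.zeros(len(drugs), dtype=bool)
        pred[below] = logit.predict(X_all[below])
        acc = float(np.mean(pred == y_all)) * 100.0
        if best is None or acc > best[0] + 1e-12:
            best = (acc, thr, logit)
    if not any_fittable and len(np.unique(y_all)) == 2:
        logger.warning("no candidate gate leaves both classes below it; "
                       "step 2 degenerates to a constant predictor")
    acc, thr, logit = best
    return TwoStepModel(
        ratio_threshold=thr, intercept=logit.intercept,
        coefficients=logit.coef, feature_names=list(features),
        definition=definition, training_accuracy=acc)


# ---------------------------------------------------------------------------
# One-step baseline
# ---------------------------------------------------------------------------

@dataclass
class OneStepModel:
    """Plain logistic classifier on features at EFTPC (no hERG-ratio gate)."""

    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    concentration_rule: str = "EFTPC"
    cutoff: float = 0.5
    training_accuracy: float | None = None

    def predict(self, x: np.ndarray) -> bool:
        z = self.intercept + float(np.dot(self.coefficients, x))
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))) >= self.cutoff

    def predict_drug(self, drug: DrugRecord) -> bool:
        x = drug_features(drug, self.feature_names, self.concentration_rule)
        if x is None:
            raise ValueError(f"cannot compute features for {drug.name}")
        return self.predict(x)


def fit_one_step(panel: DrugPanel, labels: dict[str, bool],
                 features=("IKr", "ICaV"),
                 rule: str = "EFTPC") -> OneStepModel:
    """Fit the one-step baseline (no gate, features at EFTPC)."""
    drugs = [d for d in panel if d.name in labels]
    if not drugs:
        raise ValueError("no labeled drugs in panel")
    rows, y = [], []
    for d in drugs:
        x = drug_features(d, features, rule)
        if x is None:
            logger.warning("drug %s lacks data for rule %s; skipped",
                           d.name, rule)
            continue
        rows.append(x)
        y.append(labels[d.name])
    X = np.array(rows)
    y = np.array(y)
    logit = _fit_logit(X, y)
    acc = float(np.mean(logit.predict(X) == y)) * 100.0
    return OneStepModel(intercept=logit.intercept, coefficients=logit.coef,
                        feature_names=list(features),
                        concentration_rule=rule, training_accuracy=acc)


# ---------------------------------------------------------------------------
# Leave-one-out cross validation
# ---------------------------------------------------------------------------

def loo_accuracy(panel: DrugPanel, labels: dict[str, bool], fitter) -> float:
    """Leave-one-out accuracy (percent) of a fitting procedure.

    ``fitter(panel, labels) -> model`` must return an object with
    ``predict_drug(DrugRecord) -> bool``; for the two-step model this means
    the gate threshold is re-selected inside every fold.  Folds whose
    training set collapses to one class are scored with the majority-class
    prediction (logged).
    """
    drugs = [d for d in panel if d.name in labels]
    if len(drugs) < 3:
        raise ValueError("need at least 3 labeled drugs for LOO")
    correct = 0
    for i, held in enumerate(drugs):
        rest = [d for d in drugs if d.name != held.name]
        sub_labels = {d.name: labels[d.name] for d in rest}
        vals = set(sub_labels.values())
        if len(vals) < 2:
            maj = vals.pop()
            logger.warning("LOO fold %d: single-class training set; "
                           "majority prediction used", i)
            pred = maj
        else:
            model = fitter(DrugPanel(drugs=rest, source=panel.source),
                           sub_labels)
            pred = model.predict_drug(held)
        if pred == labels[held.name]:
            correct += 1
    return 100.0 * correct / len(drugs)


# ---------------------------------------------------------------------------
# Ternary (three-tier) extension
# ---------------------------------------------------------------------------

@dataclass
class TernaryModel:
    """Equal-weight feature-sum model for high/intermediate/low risk.

    The y axis is % ICaV block + % INaL block + trapping (missing entries
    0); ``y_high`` separates high from intermediate risk and ``y_low``
    intermediate from low (both fitted as -b0/bf of an equal-weight
    logistic).  On the x axis, drugs with hERG ratio above ``x_high`` are
    low risk; only drugs below ``x_low`` can be high risk.
    """

    y_high: float
    y_low: float
    x_low: float = 25.0
    x_high: float = 150.0
    feature_names: tuple[str, ...] = ("ICaV", "INaL", "trapping")

    def feature_sum(self, drug: DrugRecord) -> float:
        x = drug_features(drug, self.feature_names, "IC60_hERG")
        if x is None:
            raise ValueError(f"cannot compute feature sum for {drug.name}")
        return float(x.sum())

    def predict(self, ratio: float | None, fsum: float) -> str:
        if ratio is not None and ratio >= self.x_high:
            return "low"
        if fsum >= self.y_low:
            return "low"
        if (ratio is None or ratio < self.x_low) and fsum < self.y_high:
            return "high"
        return "intermediate"

    def predict_drug(self, drug: DrugRecord) -> str:
        return self.predict(herg_ratio(drug), self.feature_sum(drug))


_CP_TO_TIER = {"CP1": "high", "CP2": "intermediate", "CP3": "low"}


def fit_ternary(panel: DrugPanel, features=("ICaV", "INaL", "trapping"),
                x_low: float = 25.0, x_high: float = 150.0) -> TernaryModel:
    """Fit the ternary feature-sum model on CiPA-labeled drugs.

    Two equal-weight logistic fits on the feature sum give the two y
    thresholds: high vs (intermediate + low), and (high + intermediate) vs
    low.  The x thresholds are fixed constants (configurable).
    """
    tiers, fsums = [], []
    for d in panel:
        if d.labels.cipa is None:
            continue
        x = drug_features(d, features, "IC60_hERG")
        if x is None:
            logger.warning("drug %s lacks IKr assay; skipped", d.name)
            continue
        tiers.append(_CP_TO_TIER[d.labels.cipa])
        fsums.append(float(x.sum()))
    if len(set(tiers)) < 2:
        raise ValueError("need at least two CiPA tiers represented")
    F = np.array(fsums).reshape(-1, 1)
    tiers = np.array(tiers)

    def threshold(y: np.ndarray) -> float:
        logit = _fit_logit(F, y)
        if logit.coef[0] == 0.0:
            raise ValueError("degenerate feature-sum fit (single class)")
        return -logit.intercept / logit.coef[0]

    # positive class = riskier side (low feature sum), so thresholds are the
    # 0.5-probability crossings of the fitted curves
    y_high = threshold(tiers == "high")
    y_low = threshold((tiers == "high") | (tiers == "intermediate"))
    if y_high > y_low:
        logger.warning("ternary thresholds unordered (y_high %.2f > y_low "
                       "%.2f); regions may overlap", y_high, y_low)
    return TernaryModel(y_high=float(y_high), y_low=float(y_low),
                        x_low=x_low, x_high=x_high,
                        feature_names=tuple(features))
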