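"""Two-dimensional TdP risk maps.

A fitted two-step model is rendered as a plane with the hERG ratio
(IC60_hERG / EFTPC, log scale) on x and a normalized feature combination on
y.  The step-2 hyperplane

    b_ICaV*block_ICaV + b_INaL*block_INaL + ... + b0 = 0

is divided by b_ICaV so the y axis reads

    block_ICaV + (b_INaL/b_ICaV)*block_INaL + ...   with threshold -b0/b_ICaV.

Map-region classification is algebraically identical to the generating
model's predictions; that identity is the tested contract.  Ternary models
map to three regions with two x and two y thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import TernaryModel, TwoStepModel, drug_features
from .drug_data import DrugPanel
from .pharm import herg_ratio

logger = logging.getLogger("mcbead")

__all__ = ["RiskMapSpec", "build_risk_map", "plot_risk_map"]


@dataclass
class RiskMapSpec:
    """Geometry of a 2D risk map.

    ``y_definition`` lists (feature, coefficient/b_ICaV) pairs; the ICaV
    entry is 1 after normalization.  ``risk_below_y`` records the sign
    convention: True when the risky side is below the y threshold (the
    usual case -- more ICaV block is protective).  For ternary maps the
    second thresholds are set and regions are high/intermediate/low instead
    of TdP+/TdP-.
    """

    x_threshold: float
    y_definition: list[tuple[str, float]]
    y_threshold: float
    risk_below_y: bool = True
    normalized: bool = True
    kind: str = "binary"               # or "ternary"
    x_threshold_low: float | None = None   # ternary: high-risk x cut
    y_threshold_high: float | None = None  # ternary: high vs intermediate
    region_labels: tuple[str, ...] = ("TdP+", "TdP-")

    def y_value(self, drug) -> float:
        feats = [f for f, _ in self.y_definition]
        x = drug_features(drug, feats, "IC60_hERG")
        if x is None:
            raise ValueError(f"cannot place {drug.name} on the map")
        return float(sum(c * v for (_, c), v in zip(self.y_definition, x)))

    def region(self, ratio: float | None, y: float) -> str:
        if self.kind == "ternary":
            if ratio is not None and ratio >= self.x_threshold:
                return "low"
            if y >= self.y_threshold:
                return "low"
            if ((ratio is None or ratio < self.x_threshold_low)
                    and y < self.y_threshold_high):
                return "high"
            return "intermediate"
        if ratio is not None and ratio >= self.x_threshold:
            return "TdP-"
        risky = (y <= self.y_threshold) if self.risk_below_y \
            else (y >= self.y_threshold)
        return "TdP+" if risky else "TdP-"

    def classify_drug(self, drug) -> str:
        return self.region(herg_ratio(drug), self.y_value(drug))


def build_risk_map(model) -> RiskMapSpec:
    """Risk-map geometry from a fitted TwoStepModel or TernaryModel.

    For the two-step model the step-2 coefficients are normalized to the
    ICaV coefficient; classification by map regions is then exactly the
    model's prediction.  A zero ICaV coefficient cannot be normalized; the
    map falls back to raw coefficients with a warning.
    """
    if isinstance(model, TernaryModel):
        return RiskMapSpec(
            x_threshold=model.x_high,
            y_definition=[(f, 1.0) for f in model.feature_names],
            y_threshold=model.y_low, risk_below_y=True, kind="ternary",
            x_threshold_low=model.x_low, y_threshold_high=model.y_high,
            region_labels=("high", "intermediate", "low"))
    if not isinstance(model, TwoStepModel):
        raise TypeError("expected a TwoStepModel or TernaryModel")
    feats = list(model.feature_names)
    if "ICaV" not in feats:
        raise ValueError("risk map requires an ICaV feature in step 2")
    i_cav = feats.index("ICaV")
    b_cav = float(model.coefficients[i_cav])
    if b_cav == 0.0:
        logger.warning("ICaV coefficient is zero; map uses raw coefficients")
        return RiskMapSpec(
            x_threshold=model.ratio_threshold,
            y_definition=list(zip(feats, map(float, model.coefficients))),
            y_threshold=-model.intercept, risk_below_y=False,
            normalized=False)
    y_def = [(f, float(c) / b_cav)
             for f, c in zip(feats, model.coefficients)]
    # model predicts TdP+ iff b0 + sum(b_i x_i) >= 0, i.e.
    # b_cav * (y - y_thr) >= 0: the risky side is below the threshold
    # exactly when b_cav < 0 (ICaV block protective).
    return RiskMapSpec(
        x_threshold=model.ratio_threshold,
        y_definition=y_def,
        y_threshold=-model.intercept / b_cav,
        risk_below_y=b_cav < 0.0)


def map_coordinates(spec: RiskMapSpec, panel: DrugPanel,
                    labels: dict | None = None) -> pd.DataFrame:
    """Coordinates table (drug, x, y, region, label) -- the canonical,
    headlessly testable artifact behind the rendered figure.

    Drugs without a hERG ratio get a sentinel x (NaN) and a warning; their
    region is still computed (they bypass the x gate).
    """
    rows = []
    for d in panel:
        ratio = herg_ratio(d)
        try:
            y = spec.y_value(d)
        except ValueError:
            logger.warning("drug %s cannot be placed on the map; skipped",
                           d.name)
            continue
        if ratio is None:
            logger.warning("drug %s has no hERG ratio; plotted in sentinel "
                           "band", d.name)
        rows.append({
            "drug": d.name,
            "x": ratio if ratio is not None else float("nan"),
            "y": y,
            "region": spec.region(ratio, y),
            "label": None if labels is None else labels.get(d.name),
        })
    return pd.DataFrame(rows)


def plot_risk_map(spec: RiskMapSpec, panel: DrugPanel,
                  labels: dict | None = None, path=None,
                  ead_boundary: float | None = None,
                  coords_path=None):
    """Render the risk map and return (figure, coordinates table).

    x is log-scaled; regions are green (low risk), red (high risk) and, for
    ternary maps, yellow (intermediate).  ``ead_boundary`` draws the
    EAD+/EAD- separation (e.g. the ~30% ICaV block line at 60% hERG block)
    as a blue rectangle outline.  The rendered image is a convenience; the
    coordinates table is the tested artifact.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = map_coordinates(spec, panel, labels)
    finite_x = coords["x"].dropna()
    x_max = max(1e4, (finite_x.max() * 10) if len(finite_x) else 1e4)
    x_min = min(0.1, (finite_x.min() / 10) if len(finite_x) else 0.1)
    ys = coords["y"]
    y_lo = min(0.0, ys.min() if len(ys) else 0.0) - 5
    y_hi = max(100.0, ys.max() if len(ys) else 100.0) + 5

    fig, ax = plt.subplots(figsize=(6, 4.5))
    if spec.kind == "ternary":
        ax.axvspan(spec.x_threshold, x_max, color="#caf0ca")
        ax.fill_between([x_min, spec.x_threshold], spec.y_threshold, y_hi,
                        color="#caf0ca")
        ax.fill_between([x_min, spec.x_threshold_low], y_lo,
                        spec.y_threshold_high, color="#f4c7c3")
        ax.fill_between([x_min, spec.x_threshold_low],
                        spec.y_threshold_high, spec.y_threshold,
                        color="#fdf3c0")
        ax.fill_between([spec.x_threshold_low, spec.x_threshold], y_lo,
                        spec.y_threshold, color="#fdf3c0")
    else:
        risky_lo, risky_hi = ((y_lo, spec.y_threshold) if spec.risk_below_y
                              else (spec.y_threshold, y_hi))
        safe_lo, safe_hi = ((spec.y_threshold, y_hi) if spec.risk_below_y
                            else (y_lo, spec.y_threshold))
        ax.axvspan(spec.x_threshold, x_max, color="#caf0ca")
        ax.fill_between([x_min, spec.x_threshold], risky_lo, risky_hi,
                        color="#f4c7c3")
        ax.fill_between([x_min, spec.x_threshold], safe_lo, safe_hi,
                        color="#caf0ca")
    if ead_boundary is not None:
        ax.plot([x_min, spec.x_threshold, spec.x_threshold],
                [ead_boundary, ead_boundary, y_lo],
                color="tab:blue", lw=2)
    color_map = {"TdP+": "red", "high": "red", "TdP-": "green",
                 "low": "green", "intermediate": "orange",
                 True: "red", False: "green", None: "gray"}
    sentinel_x = x_max * 0.9
    for _, row in coords.iterrows():
        x = row["x"] if np.isfinite(row["x"]) else sentinel_x
        ax.plot(x, row["y"], "o", ms=5,
                color=color_map.get(row["label"], "gray"),
                mec="black", mew=0.3)
    ax.set_xscale("log")
    ax.set_xlim(x_min, x_max)
    ax.set_ylim(y_lo, y_hi)
    ax.set_xlabel("hERG ratio (IC60,hERG / EFTPC)")
    ax.set_ylabel(" + ".join(
        f"{c:g} x {f}" if c != 1.0 else f
        for f, c in spec.y_definition))
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    if coords_path is not None:
        coords.to_csv(coords_path, index=False)
    return fig, coords
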