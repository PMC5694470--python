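"""Drug panel data model, I/O, merging and synthetic panel generation.

A panel is an ordered collection of drugs, each carrying per-channel IC50
assays (nM internally), an optional effective free therapeutic plasma
concentration (EFTPC), torsadogenic risk labels from up to four published
categorization schemes (Redfern R1-R5, CredibleMeds CM1-CM3, Champeroux
CH1-CH3, CiPA CP1-CP3) plus a package-label TdP warning flag, and an
optional drug-trapping scalar (open-bound/closed-bound hERG occupancy
ratio).

Missing channel assays are treated as zero block everywhere and recorded
with an ``assumed-zero`` provenance flag.  Readers accept uM or nM columns
through a schema mapping; everything is normalized to nM in memory.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pharm import CHANNELS, concentration_at_block, fractional_block

logger = logging.getLogger("mcbead")

__all__ = [
    "ChannelAssay", "RiskLabel", "DrugRecord", "DrugPanel",
    "PanelFormatError", "PanelValidationError",
    "read_panel", "write_panel", "read_label_overrides", "apply_overrides",
    "binarize_labels", "merge_panels", "generate_synthetic_panel",
    "DEFAULT_SCHEMA", "LABEL_DEFINITIONS",
]


class PanelFormatError(ValueError):
    """The input file cannot be interpreted as a drug panel."""


class PanelValidationError(ValueError):
    """A row holds an invalid value (e.g. non-positive IC50)."""


_UNIT_TO_NM = {"nM": 1.0, "nm": 1.0, "uM": 1000.0, "um": 1000.0,
               "μM": 1000.0, "mM": 1.0e6, "pM": 1.0e-3}


def _to_nm(value: float, unit: str) -> float:
    try:
        return value * _UNIT_TO_NM[unit]
    except KeyError:
        raise PanelFormatError(f"unknown concentration unit {unit!r}") from None


@dataclass(frozen=True)
class ChannelAssay:
    """One channel's dose-response parameters: IC50 (nM) and Hill slope."""

    channel: str
    ic50: float
    hill: float = 1.0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not (self.ic50 > 0 and math.isfinite(self.ic50)):
            raise ValueError(f"IC50 must be positive, got {self.ic50}")
        if not (self.hill > 0 and math.isfinite(self.hill)):
            raise ValueError(f"Hill coefficient must be positive, "
                             f"got {self.hill}")


_LABEL_VALUES = {
    "redfern": ("R1", "R2", "R3", "R4", "R5"),
    "crediblemeds": ("CM1", "CM2", "CM3"),
    "champeroux": ("CH1", "CH2", "CH3"),
    "cipa": ("CP1", "CP2", "CP3"),
}


@dataclass(frozen=True)
class RiskLabel:
    """Risk-category assignments across the published labeling schemes."""

    redfern: str | None = None
    crediblemeds: str | None = None
    champeroux: str | None = None
    cipa: str | None = None
    label_warning: bool = False

    def __post_init__(self):
        for scheme, allowed in _LABEL_VALUES.items():
            v = getattr(self, scheme)
            if v is not None and v not in allowed:
                raise ValueError(f"invalid {scheme} category {v!r}")

    @property
    def any_populated(self) -> bool:
        return (self.redfern is not None or self.crediblemeds is not None
                or self.champeroux is not None or self.cipa is not None
                or self.label_warning)


@dataclass(frozen=True)
class DrugRecord:
    """One drug: assays, EFTPC (nM), risk labels, optional trapping scalar."""

    name: str
    assays: tuple[ChannelAssay, ...] = ()
    eftpc: float | None = None
    labels: RiskLabel = field(default_factory=RiskLabel)
    trapping: float | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise ValueError("drug name must be non-empty")
        seen = set()
        for a in self.assays:
            if a.channel in seen:
                raise ValueError(f"duplicate assay for {a.channel} "
                                 f"in {self.name}")
            seen.add(a.channel)
        if self.eftpc is not None and not self.eftpc > 0:
            raise ValueError(f"EFTPC must be positive, got {self.eftpc}")
        if self.trapping is not None and self.trapping < 0:
            raise ValueError("trapping scalar must be >= 0")

    def assay(self, channel: str) -> ChannelAssay | None:
        for a in self.assays:
            if a.channel == channel:
                return a
        return None

    @property
    def assumed_zero(self) -> tuple[str, ...]:
        present = {a.channel for a in self.assays}
        return tuple(ch for ch in CHANNELS if ch not in present)


@dataclass
class DrugPanel:
    """Ordered collection of drugs; concentrations are nM internally."""

    drugs: list[DrugRecord] = field(default_factory=list)
    source: str = ""
    concentration_unit: str = "nM"

    def __post_init__(self):
        names = [d.name.lower() for d in self.drugs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate drug names in panel: {dupes}")

    def __len__(self):
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    def get(self, name: str) -> DrugRecord | None:
        low = name.lower()
        for d in self.drugs:
            if d.name.lower() == low:
                return d
        return None

    def names(self) -> list[str]:
        return [d.name for d in self.drugs]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: column layout produced by :func:`write_panel` and accepted by default.
DEFAULT_SCHEMA: dict = {
    "name": "drug",
    "unit": "nM",
    "eftpc": "eftpc",
    "trapping": "trapping",
    "channels": {ch: {"ic50": f"{ch}_ic50", "hill": f"{ch}_hill"}
                 for ch in CHANNELS},
    "labels": {"redfern": "redfern", "crediblemeds": "crediblemeds",
               "champeroux": "champeroux", "cipa": "cipa",
               "label_warning": "label_warning"},
}


def _load_schema(schema) -> dict:
    if schema is None:
        return DEFAULT_SCHEMA
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    merged = {**DEFAULT_SCHEMA, **schema}
    return merged


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def read_panel(path, schema=None, overrides=None, sep=None) -> DrugPanel:
    """Read a delimited drug-panel file.

    ``schema`` may be a mapping or a YAML file path; it declares the
    drug-name column, per-channel IC50/Hill columns and their units, EFTPC
    and label columns (see DEFAULT_SCHEMA).  Missing channel columns or
    empty cells mean "no assay" (block treated as 0 downstream, flagged
    ``assumed-zero:<channel>``); empty Hill cells default to 1.  All
    concentrations are converted to nM.
    """
    path = Path(path)
    schema = _load_schema(schema)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return DrugPanel(drugs=[], source=str(path))
    if len(df) == 0:
        return DrugPanel(drugs=[], source=str(path))

    name_col = schema["name"]
    if name_col not in df.columns:
        raise PanelFormatError(f"missing drug-name column {name_col!r}")
    ikr_cfg = schema["channels"].get("IKr", {})
    if ikr_cfg.get("ic50") not in df.columns:
        raise PanelFormatError("missing hERG (IKr) IC50 column "
                               f"{ikr_cfg.get('ic50')!r}")
    default_unit = schema.get("unit", "nM")

    drugs = []
    for idx, row in df.iterrows():
        name = row[name_col]
        if _is_missing(name):
            raise PanelValidationError(f"row {idx}: empty drug name")
        assays = []
        prov = []
        for ch, cfg in schema["channels"].items():
            col = cfg.get("ic50")
            if col is None or col not in df.columns:
                continue
            v = row[col]
            if _is_missing(v):
                continue
            v = float(v)
            if not v > 0:
                raise PanelValidationError(
                    f"row {idx} ({name}): non-positive IC50 for {ch}: {v}")
            ic50 = _to_nm(v, cfg.get("unit", default_unit))
            hill = 1.0
            hcol = cfg.get("hill")
            if hcol and hcol in df.columns and not _is_missing(row[hcol]):
                hill = float(row[hcol])
            assays.append(ChannelAssay(ch, ic50, hill))
        eftpc = None
        ecol = schema.get("eftpc")
        if ecol and ecol in df.columns and not _is_missing(row[ecol]):
            v = float(row[ecol])
            if not v > 0:
                raise PanelValidationError(
                    f"row {idx} ({name}): non-positive EFTPC: {v}")
            eftpc = _to_nm(v, schema.get("eftpc_unit", default_unit))
        trapping = None
        tcol = schema.get("trapping")
        if tcol and tcol in df.columns and not _is_missing(row[tcol]):
            trapping = float(row[tcol])
        lab_kwargs = {}
        for field_name, col in schema.get("labels", {}).items():
            if col in df.columns and not _is_missing(row[col]):
                v = row[col]
                if field_name == "label_warning":
                    v = str(v).strip().lower() in ("1", "true", "yes", "y",
                                                   "1.0")
                else:
                    v = str(v).strip()
                lab_kwargs[field_name] = v
        record = DrugRecord(
            name=str(name), assays=tuple(assays), eftpc=eftpc,
            labels=RiskLabel(**lab_kwargs), trapping=trapping)
        prov.extend(f"assumed-zero:{ch}" for ch in record.assumed_zero)
        drugs.append(replace(record, provenance=tuple(prov)))
    panel = DrugPanel(drugs=drugs, source=str(path))
    if overrides:
        panel = apply_overrides(panel, overrides)
    return panel


def write_panel(panel: DrugPanel, path, provenance_path=None) -> None:
    """Write a panel in the default column layout (nM), plus an optional
    JSON provenance sidecar (assumed-zero channels, overrides)."""
    rows = []
    for d in panel:
        row = {"drug": d.name, "eftpc": d.eftpc, "trapping": d.trapping}
        for ch in CHANNELS:
            a = d.assay(ch)
            row[f"{ch}_ic50"] = a.ic50 if a else None
            row[f"{ch}_hill"] = a.hill if a else None
        row.update({
            "redfern": d.labels.redfern,
            "crediblemeds": d.labels.crediblemeds,
            "champeroux": d.labels.champeroux,
            "cipa": d.labels.cipa,
            "label_warning": d.labels.label_warning,
        })
        rows.append(row)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    if provenance_path is not None:
        prov = {d.name: list(d.provenance) for d in panel}
        with open(provenance_path, "w") as fh:
            json.dump({"source": panel.source, "provenance": prov}, fh,
                      indent=2)


def read_label_overrides(path) -> dict:
    """Load a per-drug label-override file (YAML: name -> label fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PanelFormatError("override file must map drug names to labels")
    return data


def apply_overrides(panel: DrugPanel, overrides: dict) -> DrugPanel:
    """Return a panel with per-drug label fields replaced.

    Override keys are matched case-insensitively; each value is a mapping of
    RiskLabel fields.  Used for the explicit re-assignments some studies
    apply (e.g. moving CYP-interaction drugs out of the TdP+ class).
    """
    omap = {k.lower(): v for k, v in overrides.items()}
    out = []
    for d in panel:
        if d.name.lower() in omap:
            fields = omap[d.name.lower()]
            new_labels = replace(d.labels, **fields)
            out.append(replace(
                d, labels=new_labels,
                provenance=d.provenance + (f"label-override:{fields}",)))
            logger.info("label override applied to %s: %s", d.name, fields)
        else:
            out.append(d)
    return DrugPanel(drugs=out, source=panel.source,
                     concentration_unit=panel.concentration_unit)


# ---------------------------------------------------------------------------
# Label binarization
# ---------------------------------------------------------------------------

def _target1(lab: RiskLabel):
    usable = (lab.redfern is not None or lab.crediblemeds is not None
              or lab.champeroux is not None or lab.label_warning)
    if not usable:
        return None
    return (lab.redfern in ("R1", "R2", "R3")
            or lab.crediblemeds == "CM1"
            or lab.champeroux == "CH1"
            or lab.label_warning)


def _cm_rule(positive):
    def rule(lab: RiskLabel):
        if lab.crediblemeds is None:
            return None
        return lab.crediblemeds in positive
    return rule


def _cipa_binary(lab: RiskLabel):
    if lab.cipa is None:
        return None
    return lab.cipa in ("CP1", "CP2")


#: torsadogenicity definitions: name -> rule(RiskLabel) -> bool | None
LABEL_DEFINITIONS = {
    "target1": _target1,
    "target2": _cm_rule(("CM1", "CM2")),
    "target3": _cm_rule(("CM1",)),
    "target4": _cm_rule(("CM1", "CM3")),
    "cipa_binary": _cipa_binary,
}


def binarize_labels(panel: DrugPanel, definition="target1") -> dict[str, bool]:
    """Deterministic TdP+/TdP- assignment under a named definition.

    ``definition`` is one of LABEL_DEFINITIONS or a callable
    RiskLabel -> bool | None.  Drugs whose labels are unusable under the
    chosen definition are excluded with a logged warning (they must not
    enter training).
    """
    rule = (definition if callable(definition)
            else LABEL_DEFINITIONS[definition])
    out: dict[str, bool] = {}
    for d in panel:
        r = rule(d.labels)
        if r is None:
            logger.warning("drug %s unlabeled under definition %s; excluded",
                           d.name, definition)
            continue
        out[d.name] = bool(r)
    return out


# ---------------------------------------------------------------------------
# Panel merging
# ---------------------------------------------------------------------------

def _merge_labels(labels: list[RiskLabel], name: str) -> RiskLabel:
    merged = {}
    for scheme in _LABEL_VALUES:
        vals = sorted({getattr(lab, scheme) for lab in labels
                       if getattr(lab, scheme) is not None})
        if not vals:
            merged[scheme] = None
        elif len(vals) == 1:
            merged[scheme] = vals[0]
        else:
            # conflict: keep the highest-risk (lowest-numbered) category
            keep = min(vals, key=lambda v: int(v[-1]))
            logger.warning("label conflict for %s in %s scheme: %s; "
                           "keeping %s", name, scheme, vals, keep)
            merged[scheme] = keep
    merged["label_warning"] = any(lab.label_warning for lab in labels)
    return RiskLabel(**merged)


def merge_panels(panels: list[DrugPanel], source="merged") -> DrugPanel:
    """Collapse duplicate drugs (case-insensitive name) across panels.

    Numeric fields (per-channel IC50, Hill, EFTPC, trapping) are averaged
    arithmetically on the concentration scale; labels are unioned with
    conflicts resolved toward the higher-risk category (logged).  The
    result is invariant to panel ordering for numeric fields.
    """
    if not panels:
        raise ValueError("need at least one panel")
    order: list[str] = []
    groups: dict[str, list[DrugRecord]] = {}
    for panel in panels:
        for d in panel:
            key = d.name.lower()
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(d)
    merged = []
    for key in sorted(order):
        records = groups[key]
        if len(records) == 1:
            merged.append(records[0])
            continue
        assays = []
        for ch in CHANNELS:
            have = [r.assay(ch) for r in records if r.assay(ch) is not None]
            if have:
                assays.append(ChannelAssay(
                    ch, float(np.mean([a.ic50 for a in have])),
                    float(np.mean([a.hill for a in have]))))
        eftpcs = [r.eftpc for r in records if r.eftpc is not None]
        traps = [r.trapping for r in records if r.trapping is not None]
        rec = DrugRecord(
            name=records[0].name,
            assays=tuple(assays),
            eftpc=float(np.mean(eftpcs)) if eftpcs else None,
            labels=_merge_labels([r.labels for r in records],
                                 records[0].name),
            trapping=float(np.mean(traps)) if traps else None,
            provenance=(f"merged-from:{len(records)}",))
        rec = replace(rec, provenance=rec.provenance
                      + tuple(f"assumed-zero:{c}" for c in rec.assumed_zero))
        merged.append(rec)
    return DrugPanel(drugs=merged, source=source)


# ---------------------------------------------------------------------------
# Synthetic panel generator
# ---------------------------------------------------------------------------

def generate_synthetic_panel(n: int, ratio_threshold: float = 100.0,
                             cav_cutoff: float = 30.0,
                             noise_sd: float = 0.0,
                             seed: int | None = None,
                             margin: float = 0.04) -> DrugPanel:
    """Generate a panel whose risk labels follow a known two-step rule.

    Per drug, the hERG IC50 is drawn log-uniformly (10 nM - 100 uM), the
    hERG ratio log-uniformly over ~1-1e4 (EFTPC derived from it), and the
    ICaV block at the 60%-hERG-block concentration uniformly over (0, 100)
    (the ICaV IC50 is back-solved from it).  Ground truth: a drug is TdP+
    iff hERG ratio < ``ratio_threshold`` AND its ICaV block at IC60_hERG is
    below ``cav_cutoff``.  ``noise_sd`` is a label-flip probability; with 0
    the panel is exactly separable in (ratio, ICaV-block) space, with an
    exclusion zone of ``margin`` (fraction of a decade on the ratio axis,
    ``100 * margin`` percentage points on the block axis) around the rule
    boundaries so that separability survives resampling of the panel --
    real panels do not place compounds adversarially on a cutoff.  Labels
    are encoded as CredibleMeds CM1 (TdP+) / CM3 (TdP-) plus a matching
    package-label warning flag, so all binary definitions resolve.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if ratio_threshold not in (50, 100, 150, 200):
        raise ValueError("ratio_threshold must be one of 50, 100, 150, 200")
    if not 0.0 < cav_cutoff < 100.0:
        raise ValueError("cav_cutoff must lie in (0, 100)")
    if not 0.0 <= noise_sd < 1.0:
        raise ValueError("noise_sd (label-flip probability) must be in [0,1)")
    rng = np.random.default_rng(seed)
    drugs = []
    for i in range(n):
        ic50_herg = 10.0 ** rng.uniform(1.0, 5.0)
        herg = ChannelAssay("IKr", ic50_herg, 1.0)
        ic60 = concentration_at_block(herg, 0.6)
        log_thr = math.log10(ratio_threshold)
        while True:  # rejection-sample outside the ratio margin
            log_ratio = rng.uniform(0.0, 4.0)
            if abs(log_ratio - log_thr) > margin:
                break
        ratio = 10.0 ** log_ratio
        eftpc = ic60 / ratio
        while True:  # rejection-sample outside the block margin
            cav_block = rng.uniform(0.5, 99.5)
            if abs(cav_block - cav_cutoff) > 100.0 * margin:
                break
        # back-solve the ICaV IC50 giving this block at c = IC60_hERG
        ic50_cav = ic60 * (100.0 - cav_block) / cav_block
        assays = [herg, ChannelAssay("ICaV", ic50_cav, 1.0)]
        # an uninformative extra channel, present for ~half the drugs
        if rng.random() < 0.5:
            assays.append(ChannelAssay(
                "INa_fast", 10.0 ** rng.uniform(2.0, 6.0), 1.0))
        tdp = (ratio < ratio_threshold) and (cav_block < cav_cutoff)
        if noise_sd > 0 and rng.random() < noise_sd:
            tdp = not tdp
        labels = RiskLabel(crediblemeds="CM1" if tdp else "CM3",
                           label_warning=tdp)
        drugs.append(DrugRecord(
            name=f"synthdrug{i:04d}", assays=tuple(assays), eftpc=eftpc,
            labels=labels, trapping=0.0))
    return DrugPanel(
        drugs=drugs,
        source=(f"synthetic(n={n},ratio_threshold={ratio_threshold},"
                f"cav_cutoff={cav_cutoff},noise={noise_sd},seed={seed})"))
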