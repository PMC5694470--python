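"""Derived action-potential and calcium-transient biomarkers.

Thirteen metrics are extracted per beat: upstroke velocity, peak voltage,
APD30/50/90, duration above -60 mV, resting voltage, AP triangulation
(APD90 - APD30), diastolic/peak intracellular Ca, Ca-transient amplitude,
CaTD30/50/90 and CaT triangulation (CaTD90 - CaTD30) -- plus a boolean EAD
flag from a secondary-depolarization detector.

Conventions: the per-beat baseline is the pre-stimulus diastolic value and
the per-beat peak, so metrics are robust to slow drift; repolarization
fraction crossings are linearly interpolated between samples; durations are
measured from the activation time (maximum dV/dt of the primary upstroke).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .myocyte import SimulationTrace

__all__ = ["BiomarkerSet", "EADConfig", "compute_biomarkers", "detect_ead",
           "METRIC_NAMES"]

#: the 13 scalar metrics, in canonical order
METRIC_NAMES = (
    "upstroke_velocity", "peak_voltage", "apd50", "apd_at_minus60", "apd90",
    "resting_voltage", "ap_triangulation", "diastolic_cai", "cat_amplitude",
    "peak_cai", "catd50", "catd90", "cat_triangulation",
)

CAPTURE_THRESHOLD_MV = 10.0


@dataclass(frozen=True)
class EADConfig:
    """Secondary-depolarization criterion (tunable, defaults validated
    against the model's known block thresholds).

    An EAD is a positive dV/dt exceeding ``dvdt_threshold`` sustained for
    at least ``sustain_ms``, occurring after the primary upstroke has ended
    (dV/dt fallen below zero) and taking off from a membrane potential in
    (``vm_floor``, ``takeoff_ceiling``).  The ceiling excludes the normal
    early-plateau rise (phase-1 notch recovery, slow dome drift), which is
    not an afterdepolarization; genuine pause-induced EADs in these models
    take off during phase 3, well below -10 mV.
    """

    dvdt_threshold: float = 0.01   # mV/ms
    sustain_ms: float = 1.0
    vm_floor: float = -60.0
    takeoff_ceiling: float = -10.0


@dataclass
class BiomarkerSet:
    upstroke_velocity: float
    peak_voltage: float
    apd30: float
    apd50: float
    apd90: float
    apd_at_minus60: float
    resting_voltage: float
    ap_triangulation: float
    diastolic_cai: float
    cat_amplitude: float
    peak_cai: float
    catd30: float
    catd50: float
    catd90: float
    cat_triangulation: float
    ead: bool
    captured: bool = True

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["ead"] = self.ead
        d["captured"] = self.captured
        return d

    def metrics_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])


def _beat_arrays(trace: SimulationTrace, beat: int):
    start, end = trace.beat_window(beat)
    sel = (trace.time >= start - 1e-9) & (trace.time <= end + 1e-9)
    t = trace.time[sel]
    v = trace.vm[sel]
    c = trace.cai[sel]
    if len(t) < 4:
        raise ValueError("beat window too short for biomarker extraction")
    return t, v, c


def _crossing_time(t, y, level, i, upward):
    """Linear interpolation of a level crossing between samples i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return t[i]
    frac = (level - y0) / (y1 - y0)
    return t[i] + frac * (t[i + 1] - t[i])


def _duration_at_level(t, y, level):
    """Total time the signal spends above ``level`` (interpolated)."""
    above = y > level
    if not above.any():
        return 0.0
    total = 0.0
    entry = None
    for i in range(len(y) - 1):
        if not above[i] and above[i + 1]:
            entry = _crossing_time(t, y, level, i, True)
        elif above[i] and not above[i + 1]:
            start = entry if entry is not None else t[0]
            total += _crossing_time(t, y, level, i, False) - start
            entry = None
    if above[-1]:
        start = entry if entry is not None else t[0]
        total += t[-1] - start
    elif above[0] and entry is None:
        pass
    return total


def _final_decay_crossing(t, y, level, i_peak):
    """Time of the last downward crossing of ``level`` after the peak.

    Using the final crossing makes durations well defined for beats with
    afterdepolarization bumps that re-cross the level.
    """
    idx = None
    for i in range(i_peak, len(y) - 1):
        if y[i] >= level > y[i + 1]:
            idx = i
    if idx is None:
        return None
    return _crossing_time(t, y, level, idx, False)


def _ead_from_arrays(t, v, config: EADConfig) -> bool:
    dv = np.diff(v) / np.diff(t)
    i_peak = int(np.argmax(v))
    # end of the primary upstroke: first negative dV/dt at/after the peak
    start = None
    for i in range(max(i_peak, 1), len(dv)):
        if dv[i] < 0.0:
            start = i
            break
    if start is None:
        return False
    run = 0.0
    in_run = False
    for i in range(start, len(dv)):
        rising = v[i] > config.vm_floor and dv[i] > config.dvdt_threshold
        if rising and (in_run or v[i] < config.takeoff_ceiling):
            # a run may only *start* below the takeoff ceiling; once a
            # secondary depolarization is underway it may rise past it
            in_run = True
            run += t[i + 1] - t[i]
            if run >= config.sustain_ms - 1e-9:
                return True
        else:
            run = 0.0
            in_run = False
    return False


def detect_ead(trace: SimulationTrace, beat: int = -1,
               config: EADConfig | None = None) -> bool:
    """True if the indexed beat shows a secondary depolarization.

    Returns False for a non-captured beat (no depolarization above the
    capture threshold).
    """
    config = config or EADConfig()
    t, v, _ = _beat_arrays(trace, beat)
    if v.max() - v[0] < CAPTURE_THRESHOLD_MV:
        return False
    return _ead_from_arrays(t, v, config)


def compute_biomarkers(trace: SimulationTrace, beat: int = -1,
                       ead_config: EADConfig | None = None) -> BiomarkerSet:
    """Extract the 13 AP/Ca metrics (plus the EAD flag) for one beat."""
    t, v, c = _beat_arrays(trace, beat)
    rest = float(v[0])
    peak = float(v.max())
    i_peak = int(np.argmax(v))
    if peak - rest < CAPTURE_THRESHOLD_MV:
        nan = float("nan")
        return BiomarkerSet(*([nan] * 15), ead=False, captured=False)

    dv = np.diff(v) / np.diff(t)
    # activation: maximum upstroke slope at/before the peak
    i_act = int(np.argmax(dv[:max(i_peak, 1)])) if i_peak > 0 else 0
    t_act = t[i_act]
    upstroke = float(dv[:max(i_peak, 1)].max()) if i_peak > 0 else 0.0

    amp_v = peak - rest

    def apd(frac):
        level = rest + (1.0 - frac / 100.0) * amp_v
        t_cross = _final_decay_crossing(t, v, level, i_peak)
        if t_cross is None:
            return float(t[-1] - t_act)
        return float(t_cross - t_act)

    apd30 = apd(30.0)
    apd50 = apd(50.0)
    apd90 = apd(90.0)
    apd60mv = float(_duration_at_level(t, v, -60.0))

    dia_ca = float(c[0])
    peak_ca = float(c.max())
    i_cpeak = int(np.argmax(c))
    amp_ca = peak_ca - dia_ca
    dc = np.diff(c) / np.diff(t)
    i_cact = int(np.argmax(dc[:max(i_cpeak, 1)])) if i_cpeak > 0 else 0
    t_cact = t[i_cact]

    def catd(frac):
        if amp_ca <= 0:
            return float("nan")
        level = dia_ca + (1.0 - frac / 100.0) * amp_ca
        t_cross = _final_decay_crossing(t, c, level, i_cpeak)
        if t_cross is None:
            return float(t[-1] - t_cact)
        return float(t_cross - t_cact)

    catd30 = catd(30.0)
    catd50 = catd(50.0)
    catd90 = catd(90.0)

    ead = _ead_from_arrays(t, v, ead_config or EADConfig())

    return BiomarkerSet(
        upstroke_velocity=upstroke,
        peak_voltage=peak,
        apd30=apd30,
        apd50=apd50,
        apd90=apd90,
        apd_at_minus60=apd60mv,
        resting_voltage=rest,
        ap_triangulation=apd90 - apd30,
        diastolic_cai=dia_ca,
        cat_amplitude=amp_ca,
        peak_cai=peak_ca,
        catd30=catd30,
        catd50=catd50,
        catd90=catd90,
        cat_triangulation=catd90 - catd30,
        ead=ead,
    )
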