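"""Ventricular myocyte simulation layer.

Wraps the O'Hara-Rudy model core (``_ord``) with the two protocols used
throughout the package:

* steady-state pacing (``pace_to_steady``) -- long trains at a fixed cycle
  length, returning the final beat;
* the pause protocol (``pause_protocol``) -- a train of stimuli at a short
  cycle length followed by a quiescent pause and one further stimulus, the
  classic trigger for pause-induced early afterdepolarizations.

Simulations are deterministic: identical specs and integrator settings give
bit-identical traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _ord

__all__ = [
    "CellModelSpec", "IntegratorConfig", "SimulationTrace", "Myocyte",
    "SimulationFailure", "build_model", "pace_to_steady", "pause_protocol",
]


class SimulationFailure(RuntimeError):
    """Numerical blow-up (non-finite state or |Vm| > 500 mV)."""

    def __init__(self, t: float, beat: int | None = None):
        self.t = t
        self.beat = beat
        msg = f"simulation diverged at t = {t:.3f} ms"
        if beat is not None:
            msg += f" (beat {beat})"
        super().__init__(msg)


@dataclass(frozen=True)
class CellModelSpec:
    """Which myocyte model to build.

    ``conductance_scaling`` maps channel names (IKr, ICaV, INaL, INa_fast,
    IKs, IK1, Ito) to multipliers in [0, 1] (1 - block/100).  ``gnal_scale``
    rescales the late sodium conductance before drug scaling; 2.0 emulates
    the LQT3 gain-of-function condition.
    """

    variant: str = "OHR"
    cell_type: str = "endo"
    gnal_scale: float = 1.0
    conductance_scaling: Mapping[str, float] = field(default_factory=dict)

    def params(self) -> np.ndarray:
        return _ord.build_params(self.cell_type, self.variant,
                                 self.gnal_scale,
                                 dict(self.conductance_scaling))


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration settings.

    ``forward_euler_fixed`` is mandatory for any run feeding an EAD
    decision; ``hybrid_rapid`` (Rush-Larsen gates, two-level adaptive step)
    is acceptable for plain steady-state biomarkers only.
    """

    method: str = "forward_euler_fixed"
    dt: float = 0.001            # ms, fixed-step method
    dt_fast: float = 0.002       # ms, hybrid during repolarization/Ca cycling
    dt_slow: float = 0.02        # ms, hybrid during diastole
    record_dt: float = 0.1       # ms, trace sampling interval
    stim_amplitude: float = -80.0  # uA/uF
    stim_duration: float = 0.5     # ms

    def __post_init__(self):
        if self.method not in ("forward_euler_fixed", "hybrid_rapid"):
            raise ValueError(f"unknown integrator method {self.method!r}")
        if self.dt <= 0 or self.record_dt <= 0:
            raise ValueError("time steps must be positive")


@dataclass
class SimulationTrace:
    """Recorded time course of membrane potential and intracellular Ca."""

    time: np.ndarray          # ms, strictly increasing
    vm: np.ndarray            # mV
    cai: np.ndarray           # mM
    beat_markers: np.ndarray  # stimulus onset times inside the window (ms)
    cycle_length: float
    pause: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.time) != len(self.vm) or len(self.time) != len(self.cai):
            raise ValueError("time, vm and cai must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.beat_markers)

    def beat_window(self, beat: int) -> tuple[float, float]:
        """[start, end) time of the indexed beat (negative indices allowed)."""
        markers = np.asarray(self.beat_markers, dtype=float)
        beat = int(beat)
        if beat < 0:
            beat += len(markers)
        if not 0 <= beat < len(markers):
            raise IndexError("beat index out of range")
        start = markers[beat]
        end = markers[beat + 1] if beat + 1 < len(markers) else self.time[-1]
        return float(start), float(end)

    def export(self, path, metadata_path=None) -> None:
        """Write the trace as delimited text plus a JSON protocol sidecar."""
        arr = np.column_stack([self.time, self.vm, self.cai])
        np.savetxt(path, arr, header="time_ms\tvm_mV\tcai_mM",
                   delimiter="\t", comments="")
        if metadata_path is not None:
            meta = dict(self.metadata)
            meta.update({
                "cycle_length": self.cycle_length,
                "pause": self.pause,
                "beat_markers": list(map(float, self.beat_markers)),
            })
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)


class Myocyte:
    """Stateful model instance: spec, parameter vector and current state."""

    def __init__(self, spec: CellModelSpec):
        self.spec = spec
        self.params = spec.params()
        self.state = _ord.initial_state()
        self.t = 0.0

    def copy(self) -> "Myocyte":
        other = Myocyte(self.spec)
        other.state = self.state.copy()
        other.t = self.t
        return other

    # -- low-level segment runner ------------------------------------------
    def _run(self, duration: float, stim_times: np.ndarray,
             config: IntegratorConfig, record: bool):
        vmin, inv_dv, table = _ord.default_vtable()
        if config.method == "forward_euler_fixed":
            stride = max(1, int(round(config.record_dt / config.dt)))
            n_steps = int(round(duration / config.dt))
            if not record:
                stride = n_steps + 1
            n_alloc = n_steps // stride + 2
            rec_t = np.empty(n_alloc)
            rec_v = np.empty(n_alloc)
            rec_c = np.empty(n_alloc)
            status, n_rec, t_fail = _ord.integrate_euler(
                self.state, self.params, table, vmin, inv_dv, True,
                config.dt, duration, self.t, stim_times,
                config.stim_duration, config.stim_amplitude,
                stride, rec_t, rec_v, rec_c)
        else:
            n_alloc = int(duration / config.record_dt) + 2
            if not record:
                rec_dt = duration
                n_alloc = 3
            else:
                rec_dt = config.record_dt
            rec_t = np.empty(n_alloc)
            rec_v = np.empty(n_alloc)
            rec_c = np.empty(n_alloc)
            status, n_rec, t_fail = _ord.integrate_hybrid(
                self.state, self.params, table, vmin, inv_dv,
                config.dt_fast, config.dt_slow, duration, self.t,
                stim_times, config.stim_duration, config.stim_amplitude,
                rec_dt, rec_t, rec_v, rec_c, _ord._RL_GATES)
        if status != 0:
            raise SimulationFailure(t_fail)
        self.t += duration
        return rec_t[:n_rec], rec_v[:n_rec], rec_c[:n_rec]


def build_model(spec: CellModelSpec) -> Myocyte:
    """Instantiate a myocyte at the published resting initial conditions."""
    return Myocyte(spec)


def pace_to_steady(model: Myocyte, cycle_length: float,
                   n_beats: int = 1000,
                   config: IntegratorConfig | None = None) -> SimulationTrace:
    """Pace at a constant cycle length and return the final beat.

    The model state is advanced in place, so the returned trace reflects the
    quasi-steady state after ``n_beats`` stimuli (1000 by default).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    config = config or IntegratorConfig(method="hybrid_rapid")
    t0 = model.t
    if n_beats > 1:
        pre = (n_beats - 1) * cycle_length
        stim = t0 + cycle_length * np.arange(n_beats - 1, dtype=float)
        try:
            model._run(pre, stim, config, record=False)
        except SimulationFailure as exc:
            raise SimulationFailure(exc.t, beat=int((exc.t - t0)
                                                    // cycle_length)) from None
    start = model.t
    stim = np.array([start])
    rec_t, rec_v, rec_c = model._run(cycle_length, stim, config, record=True)
    return SimulationTrace(
        time=rec_t, vm=rec_v, cai=rec_c, beat_markers=np.array([start]),
        cycle_length=cycle_length,
        metadata={"protocol": "steady_pacing", "n_beats": n_beats,
                  "variant": model.spec.variant,
                  "cell_type": model.spec.cell_type,
                  "integrator": config.method})


def pause_protocol(model: Myocyte, cycle_length: float = 500.0,
                   n_stimuli: int = 200, pause: float = 1000.0,
                   config: IntegratorConfig | None = None,
                   post_window: float = 1000.0,
                   pause_reference: str = "cycle") -> SimulationTrace:
    """Pacing train, quiescent pause, then one further stimulus.

    ``n_stimuli`` beats are delivered at ``cycle_length``.  With
    ``pause_reference="cycle"`` the extra stimulus follows at
    ``n_stimuli * cycle_length + pause`` (a zero pause degenerates to
    regular pacing).  With ``pause_reference="stimulus"`` the pause is the
    S1-S2 interval: the extra stimulus comes ``pause`` ms after the last
    train stimulus, the convention of the classic short-long EAD protocol.
    The returned trace covers the final paced beat, the pause and
    ``post_window`` ms after the post-pause stimulus, which is the segment
    inspected for EADs.
    """
    if pause_reference not in ("cycle", "stimulus"):
        raise ValueError(f"unknown pause_reference {pause_reference!r}")
    if pause < 0:
        raise ValueError("pause must be >= 0")
    if pause_reference == "stimulus" and pause <= 0:
        raise ValueError("S1-S2 interval must be positive")
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    config = config or IntegratorConfig(method="forward_euler_fixed")
    t0 = model.t
    pre = (n_stimuli - 1) * cycle_length
    if n_stimuli > 1:
        stim = t0 + cycle_length * np.arange(n_stimuli - 1, dtype=float)
        try:
            model._run(pre, stim, config, record=False)
        except SimulationFailure as exc:
            raise SimulationFailure(exc.t, beat=int((exc.t - t0)
                                                    // cycle_length)) from None
    last_paced = t0 + pre
    if pause_reference == "cycle":
        post_stim = t0 + n_stimuli * cycle_length + pause
    else:
        post_stim = last_paced + pause
    duration = (post_stim - last_paced) + post_window
    stim = np.array([last_paced, post_stim])
    rec_t, rec_v, rec_c = model._run(duration, stim, config, record=True)
    return SimulationTrace(
        time=rec_t, vm=rec_v, cai=rec_c, beat_markers=stim.copy(),
        cycle_length=cycle_length, pause=pause,
        metadata={"protocol": "pause", "n_stimuli": n_stimuli,
                  "post_window": post_window,
                  "pause_reference": pause_reference,
                  "variant": model.spec.variant,
                  "cell_type": model.spec.cell_type,
                  "integrator": config.method})
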