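"""Parametric EAD scans over (ICaV, INaL, IKs) block space.

At a fixed hERG block (typically the 60% level the two-step classifier is
anchored to), the pause protocol is run for every combination of ICaV,
INaL and IKs block on a percentage grid; each point is scored EAD+/EAD-.
The EAD+/EAD- boundary along the ICaV axis defines a decision surface that
can classify drugs by their block profile at the 60%-hERG-block
concentration, either by surface interpolation or by direct simulation of
the drug's full profile (the authoritative mode).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import EADConfig, detect_ead
from .drug_data import DrugRecord
from .myocyte import (CellModelSpec, IntegratorConfig, Myocyte,
                      SimulationFailure, build_model, pause_protocol)
from .pharm import block_profile, concentration_at_block, herg_ratio

logger = logging.getLogger("mcbead")

__all__ = ["EADGrid", "DecisionSurface", "PauseProtocolSpec", "scan_grid",
           "ead_for_scaling", "classify_by_ead", "extract_surface"]


#: drug-free steady states, keyed (variant, cell_type, gnal_scale, CL, n)
_SS_CACHE: dict[tuple, np.ndarray] = {}


def drug_free_steady_state(variant: str, cell_type: str = "mid",
                           gnal_scale: float = 1.0,
                           cycle_length: float = 1000.0,
                           n_beats: int = 1000) -> np.ndarray:
    """State vector of the drug-free model paced to steady state (1 Hz by
    default), memoized.  This is the launch state for the pause protocol:
    the drug is applied acutely to a cell in its normal working rhythm.
    The run is a plain steady-state simulation, so the rapid hybrid
    integrator is appropriate.
    """
    key = (variant, cell_type, round(gnal_scale, 12), cycle_length, n_beats)
    if key not in _SS_CACHE:
        from .myocyte import pace_to_steady
        model = build_model(CellModelSpec(variant=variant,
                                          cell_type=cell_type,
                                          gnal_scale=gnal_scale))
        pace_to_steady(model, cycle_length, n_beats=n_beats,
                       config=IntegratorConfig(method="hybrid_rapid"))
        _SS_CACHE[key] = model.state.copy()
    return _SS_CACHE[key]


@dataclass(frozen=True)
class PauseProtocolSpec:
    """Pause-protocol settings used for every grid point.

    ``pause`` is the S1-S2 quiescent interval (ms) measured from the last
    train stimulus, the convention of the short-long EAD protocol.  With
    ``initialize="steady_1hz"`` (default) the drug-bound train starts from
    the drug-free model's 1 Hz steady state; ``"published"`` starts from
    the published (approximate) initial conditions.
    """

    cycle_length: float = 500.0
    n_stimuli: int = 200
    pause: float = 1000.0
    cell_type: str = "mid"
    gnal_scale: float = 1.0
    dt: float = 0.001
    post_window: float = 1000.0
    initialize: str = "steady_1hz"

    def _train_key(self, variant: str, scaling: dict[str, float]) -> tuple:
        return (variant, self.cell_type, round(self.gnal_scale, 12),
                self.initialize, self.n_stimuli, self.cycle_length, self.dt,
                tuple(sorted((k, round(v, 14)) for k, v in scaling.items())))

    def _fresh_model(self, variant: str, scaling: dict[str, float]):
        spec = CellModelSpec(variant=variant, cell_type=self.cell_type,
                             gnal_scale=self.gnal_scale,
                             conductance_scaling=scaling)
        model = build_model(spec)
        if self.initialize == "steady_1hz":
            model.state = drug_free_steady_state(
                variant, self.cell_type, self.gnal_scale).copy()
        elif self.initialize != "published":
            raise ValueError(f"unknown initialization {self.initialize!r}")
        return model

    def run(self, variant: str, scaling: dict[str, float],
            ead_config: EADConfig | None = None) -> bool:
        """One pause-protocol simulation; True if the post-pause beat EADs.

        The state at the end of the stimulus train is memoized per
        (variant, scaling, protocol) -- it does not depend on the pause --
        so probing several pause durations for the same block combination
        only integrates the train once.  The numerical trajectory is
        identical to an uncached run.
        """
        cfg = IntegratorConfig(method="forward_euler_fixed", dt=self.dt)
        key = self._train_key(variant, scaling)
        cached = _TRAIN_CACHE.get(key)
        if cached is None:
            model = self._fresh_model(variant, scaling)
            pre = (self.n_stimuli - 1) * self.cycle_length
            if self.n_stimuli > 1:
                stim = model.t + self.cycle_length * np.arange(
                    self.n_stimuli - 1, dtype=float)
                model._run(pre, stim, cfg, record=False)
            _TRAIN_CACHE[key] = (model.state.copy(), model.t)
        else:
            model = self._fresh_model(variant, scaling)
            model.state, model.t = cached[0].copy(), cached[1]
        # final paced beat + pause + post-pause window, recorded
        last_paced = model.t
        post_stim = last_paced + self.pause
        stim = np.array([last_paced, post_stim])
        duration = self.pause + self.post_window
        rec_t, rec_v, rec_c = model._run(duration, stim, cfg, record=True)
        from .myocyte import SimulationTrace
        trace = SimulationTrace(
            time=rec_t, vm=rec_v, cai=rec_c, beat_markers=stim,
            cycle_length=self.cycle_length, pause=self.pause,
            metadata={"protocol": "pause", "n_stimuli": self.n_stimuli,
                      "pause_reference": "stimulus",
                      "variant": variant, "cell_type": self.cell_type})
        return detect_ead(trace, beat=-1, config=ead_config)


#: memoized end-of-train states, keyed by protocol and scaling
_TRAIN_CACHE: dict[tuple, tuple] = {}


def ead_for_scaling(variant: str, scaling: dict[str, float],
                    protocol: PauseProtocolSpec | None = None) -> bool:
    """Convenience wrapper: EAD status of one conductance-scaling point."""
    return (protocol or PauseProtocolSpec()).run(variant, scaling)


def minimal_herg_block_for_ead(variant: str,
                               protocol: PauseProtocolSpec | None = None,
                               resolution: float = 1.0,
                               extra_block: dict[str, float] | None = None,
                               bracket: str = "checked") -> float | None:
    """Smallest hERG block (percent, on a ``resolution`` grid) whose
    post-pause beat shows an EAD, found by bisection.

    EAD induction is monotone in hERG block under this protocol, so
    bisection over the [0, 100] grid is exact.  Returns None if even 100%
    block produces no EAD.  ``extra_block`` fixes other channels' block
    percentages during the search.  ``bracket="assumed"`` skips the two
    endpoint simulations (no EAD at 0% block, EAD at full block -- safe
    for the plain threshold searches, where the endpoints are physically
    certain and far from the returned value).
    """
    protocol = protocol or PauseProtocolSpec()
    extra = {ch: 1.0 - b / 100.0 for ch, b in (extra_block or {}).items()}

    def ead(block_pct: float) -> bool:
        return protocol.run(variant, {**extra,
                                      "IKr": 1.0 - block_pct / 100.0})

    lo, hi = 0.0, 100.0
    if bracket == "checked":
        if ead(lo):
            return lo
        if not ead(hi):
            return None
    elif bracket != "assumed":
        raise ValueError(f"unknown bracket mode {bracket!r}")
    # invariant: no EAD at lo, EAD at hi
    while hi - lo > resolution + 1e-9:
        mid = lo + round((hi - lo) / (2 * resolution)) * resolution
        if mid <= lo or mid >= hi:
            mid = lo + resolution
        if ead(mid):
            hi = mid
        else:
            lo = mid
    # The EAD/no-EAD boundary can be fringed (narrow no-EAD notches from
    # beat-pattern bifurcations just above the onset), which breaks the
    # monotonicity bisection assumes.  Verify downward from the candidate:
    # keep descending while EADs reappear, stopping after two consecutive
    # EAD-free levels.
    best = hi
    misses = 0
    b = best - resolution
    while b >= 0.0 and misses < 2:
        if ead(b):
            best = b
            misses = 0
        else:
            misses += 1
        b -= resolution
    return best


def max_channel_block_with_ead(variant: str, channel: str,
                               herg_block: float,
                               protocol: PauseProtocolSpec | None = None,
                               step: float = 10.0) -> float | None:
    """Largest ``channel`` block on the 0-100% grid (spacing ``step``) at
    which the pause protocol still produces an EAD, at fixed hERG block.

    Assumes the single-crossing geometry (blocking the channel suppresses
    EADs), so bisection over the grid is exact; the acceptance suite
    verifies the single crossing independently.  Returns None if even 0%
    block shows no EAD.
    """
    protocol = protocol or PauseProtocolSpec()

    def ead(block_pct: float) -> bool:
        return protocol.run(variant, {"IKr": 1.0 - herg_block / 100.0,
                                      channel: 1.0 - block_pct / 100.0})

    grid = np.arange(0.0, 100.0 + step / 2, step)
    lo, hi = 0, len(grid) - 1      # indices
    if not ead(grid[lo]):
        return None
    if ead(grid[hi]):
        return float(grid[hi])
    # invariant: EAD at lo, none at hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ead(grid[mid]):
            lo = mid
        else:
            hi = mid
    # guard against fringed boundaries (see minimal_herg_block_for_ead):
    # verify upward, stopping after two consecutive EAD-free levels
    best = lo
    misses = 0
    i = best + 1
    while i < len(grid) and misses < 2:
        if ead(grid[i]):
            best = i
            misses = 0
        else:
            misses += 1
        i += 1
    return float(grid[best])


@dataclass
class EADGrid:
    """Boolean EAD outcome over the (ICaV, INaL, IKs) block grid."""

    herg_block: float
    cav_axis: np.ndarray
    nal_axis: np.ndarray
    ks_axis: np.ndarray
    ead: np.ndarray       # bool, shape (len(cav), len(nal), len(ks))
    status: np.ndarray    # 0 = ok, 1 = simulation failed
    variant: str = "OHR"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (herg_block, cav, nal, ks, ead, status)."""
        rows = []
        for i, j, k in itertools.product(range(len(self.cav_axis)),
                                         range(len(self.nal_axis)),
                                         range(len(self.ks_axis))):
            rows.append({
                "herg_block": self.herg_block,
                "cav": self.cav_axis[i],
                "nal": self.nal_axis[j],
                "ks": self.ks_axis[k],
                "ead": bool(self.ead[i, j, k]),
                "status": int(self.status[i, j, k]),
            })
        return pd.DataFrame(rows)


def scan_grid(variant: str = "OHR", herg_block: float = 60.0,
              step: float = 10.0,
              protocol: PauseProtocolSpec | None = None,
              axes: dict | None = None) -> EADGrid:
    """Run the pause protocol over the (ICaV, INaL, IKs) block grid.

    The default grid is 0-100% inclusive at ``step`` (11 points per axis at
    step 10).  ``axes`` can restrict individual axes (e.g.
    ``{"INaL": [0.0], "IKs": [0.0]}`` for a single-column probe).
    Simulation failures are recorded per point (status 1, EAD False), never
    aborting the scan; results are independent of evaluation order.
    """
    if not 0.0 <= herg_block <= 100.0:
        raise ValueError("herg_block must lie in [0, 100]")
    protocol = protocol or PauseProtocolSpec()
    default_axis = np.arange(0.0, 100.0 + step / 2, step)
    axes = axes or {}
    cav = np.sort(np.asarray(axes.get("ICaV", default_axis), dtype=float))
    nal = np.sort(np.asarray(axes.get("INaL", default_axis), dtype=float))
    ks = np.sort(np.asarray(axes.get("IKs", default_axis), dtype=float))
    ead = np.zeros((len(cav), len(nal), len(ks)), dtype=bool)
    status = np.zeros_like(ead, dtype=np.int64)
    for i, j, k in itertools.product(range(len(cav)), range(len(nal)),
                                     range(len(ks))):
        scaling = {"IKr": 1.0 - herg_block / 100.0,
                   "ICaV": 1.0 - cav[i] / 100.0,
                   "INaL": 1.0 - nal[j] / 100.0,
                   "IKs": 1.0 - ks[k] / 100.0}
        try:
            ead[i, j, k] = protocol.run(variant, scaling)
        except SimulationFailure as exc:
            logger.warning("grid point (cav=%g,nal=%g,ks=%g) failed: %s",
                           cav[i], nal[j], ks[k], exc)
            status[i, j, k] = 1
    return EADGrid(herg_block=herg_block, cav_axis=cav, nal_axis=nal,
                   ks_axis=ks, ead=ead, status=status, variant=variant,
                   metadata={"step": step, "protocol": vars(protocol)})


@dataclass
class DecisionSurface:
    """EAD+/EAD- boundary along the ICaV axis, per (INaL, IKs) column.

    ``boundary[j, k]`` is the ICaV block (percent) separating EAD+ (below)
    from EAD- (at/above) for INaL = nal_axis[j], IKs = ks_axis[k]; -inf
    means the whole column is EAD- and +inf that it is entirely EAD+.
    """

    nal_axis: np.ndarray
    ks_axis: np.ndarray
    boundary: np.ndarray
    herg_block: float
    variant: str
    non_monotone: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return bool(np.all(np.isneginf(self.boundary)))

    def boundary_at(self, nal: float, ks: float) -> float:
        """ICaV boundary interpolated linearly along the nearest columns."""

        def interp1(axis, values, x):
            if len(axis) == 1:
                return values[0]
            x = np.clip(x, axis[0], axis[-1])
            return float(np.interp(x, axis, values))

        # interpolate along INaL within each IKs column, then across IKs
        per_ks = np.array([interp1(self.nal_axis, self.boundary[:, k], nal)
                           for k in range(len(self.ks_axis))])
        return interp1(self.ks_axis, per_ks, ks)

    def classify(self, cav: float, nal: float, ks: float) -> bool:
        """True (EAD+) if the point lies below the interpolated boundary."""
        return bool(cav < self.boundary_at(nal, ks))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, k in itertools.product(range(len(self.nal_axis)),
                                      range(len(self.ks_axis))):
            rows.append({"nal": self.nal_axis[j], "ks": self.ks_axis[k],
                         "cav_boundary": self.boundary[j, k]})
        return pd.DataFrame(rows)


def extract_surface(grid: EADGrid) -> DecisionSurface:
    """Boundary per (INaL, IKs) column: midpoint between the last EAD+ and
    the first EAD- ICaV level.

    EAD status should cross at most once along the ICaV axis (increasing
    ICaV block suppresses EADs); non-monotone columns are flagged and the
    first crossing is used.
    """
    n_nal, n_ks = len(grid.nal_axis), len(grid.ks_axis)
    boundary = np.empty((n_nal, n_ks))
    non_monotone = []
    for j, k in itertools.product(range(n_nal), range(n_ks)):
        col = grid.ead[:, j, k]
        if col.all():
            boundary[j, k] = np.inf
            continue
        if not col.any():
            boundary[j, k] = -np.inf
            continue
        flips = np.nonzero(col[:-1] != col[1:])[0]
        if len(flips) > 1 or not col[0]:
            non_monotone.append((float(grid.nal_axis[j]),
                                 float(grid.ks_axis[k])))
            logger.warning("non-monotone EAD column at nal=%g ks=%g",
                           grid.nal_axis[j], grid.ks_axis[k])
        i = flips[0]
        boundary[j, k] = 0.5 * (grid.cav_axis[i] + grid.cav_axis[i + 1])
    return DecisionSurface(nal_axis=grid.nal_axis.copy(),
                           ks_axis=grid.ks_axis.copy(), boundary=boundary,
                           herg_block=grid.herg_block, variant=grid.variant,
                           non_monotone=non_monotone)


def classify_by_ead(drug: DrugRecord, ratio_threshold: float,
                    surface: DecisionSurface | None = None,
                    variant: str = "OHR",
                    protocol: PauseProtocolSpec | None = None,
                    mode: str = "auto") -> bool:
    """EAD-based drug classification: True = EAD+ (torsadogenic call).

    Drugs whose hERG ratio is at/above ``ratio_threshold`` are EAD- without
    simulation.  Otherwise the drug's block profile at its 60%-hERG-block
    concentration is either tested against the scanned decision surface
    (``mode="surface"``) or simulated directly with all blockable channels
    scaled (``mode="simulate"``, authoritative).  ``mode="auto"`` uses the
    surface when one is supplied.
    """
    a = drug.assay("IKr")
    if a is None:
        raise ValueError(f"drug {drug.name} has no IKr assay")
    ratio = herg_ratio(drug)
    if ratio is not None and ratio >= ratio_threshold:
        return False
    c60 = concentration_at_block(a, 0.6)
    prof = block_profile(drug, c60)
    if mode == "auto":
        mode = "surface" if surface is not None else "simulate"
    if mode == "surface":
        if surface is None:
            raise ValueError("surface mode requires a DecisionSurface")
        return surface.classify(prof["ICaV"], prof["INaL"], prof["IKs"])
    if mode != "simulate":
        raise ValueError(f"unknown mode {mode!r}")
    scaling = {ch: 1.0 - b / 100.0 for ch, b in prof.block.items()}
    scaling["IKr"] = 0.4  # by construction c = IC60_hERG
    return (protocol or PauseProtocolSpec()).run(variant, scaling)
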