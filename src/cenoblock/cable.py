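"""1D string of gap-junction-coupled myocytes and conduction-velocity measurement.

The strand is a discrete chain of cells (default 50 × 100 µm = 5 mm) with
resistive cell-to-cell coupling parameterised by the gap-junction
conductance normalised to membrane capacitance, G_j in pS/pF.  Since
pS/pF = s⁻¹, the per-neighbour voltage relaxation rate in ms⁻¹ is simply
G_j/1000, giving the coupling term

    dV_i/dt += k · (V_{i−1} − 2·V_i + V_{i+1}),   k = G_j/1000 ms⁻¹

with one-sided (no-flux) ends.  A stimulus is applied to cell 1 only;
conduction velocity is measured as total string length divided by the
cell-1-to-cell-N activation delay of a chosen propagated beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ord_model
from .myocyte import StimulusProtocol, prepaced_state

__all__ = [
    "CableConfig",
    "CableTrace",
    "CvResult",
    "coupling_rate",
    "run_cable",
    "activation_times",
    "conduction_velocity",
    "measure_cv",
]

ACTIVATION_THRESHOLD_MV = -20.0


@dataclass(frozen=True)
class CableConfig:
    """Strand geometry, coupling, pacing, and integration settings."""

    n_cells: int = 50
    cell_length_um: float = 100.0
    gj_ps_per_pf: float = 1000.0
    # strand pacing needs a stronger, longer pulse than single-cell pacing:
    # the gap-junction sink drains a 0.5 ms pulse before INa regenerates
    stimulus: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(amplitude=-120.0, duration=3.0, n_beats=2)
    )
    dt: float = 0.005            # ms
    stride_ms: float = 0.1       # output sampling
    celltype: int = 0
    completions: int = 1
    prepace_beats: int = 50

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.gj_ps_per_pf < 0:
            raise ValueError("gap-junction conductance must be >= 0")

    @property
    def length_um(self) -> float:
        return self.n_cells * self.cell_length_um


@dataclass
class CableTrace:
    """Per-cell membrane-potential time series (cells × timepoints)."""

    time: np.ndarray   # ms
    v: np.ndarray      # mV, shape (n_cells, n_times)
    b: np.ndarray      # blocked fraction, same shape
    config: CableConfig | None = None


@dataclass
class CvResult:
    beat_index: int
    activation_times_ms: np.ndarray   # NaN where a cell never activated
    cv_cm_s: float                    # NaN when not propagated
    propagated: bool


def coupling_rate(gj_ps_per_pf: float) -> float:
    """Per-neighbour voltage relaxation rate in ms⁻¹ (pS/pF = s⁻¹)."""
    if gj_ps_per_pf < 0:
        raise ValueError("gap-junction conductance must be >= 0")
    return gj_ps_per_pf / 1000.0


def run_cable(
    config: CableConfig,
    drug: np.ndarray | None = None,
    y0_cell: np.ndarray | None = None,
) -> CableTrace:
    """Simulate the strand; all cells start from the pre-paced single-cell state.

    ``drug`` is a kernel drug-parameter vector (see
    :func:`cenoblock.myocyte.drug_params`); ``y0_cell`` overrides the
    starting state of every cell (e.g. to skip pre-pacing in quick tests).
    """
    if y0_cell is None:
        y0_cell = prepaced_state(
            n_beats=config.prepace_beats,
            cycle_length=config.stimulus.cycle_length,
            dt=config.dt,
            celltype=config.celltype,
            completions=config.completions,
        )
    if drug is None:
        drug = ord_model.pack_drug(mode=0)
    if drug[0] == 2.0:  # equilibrium mode: pin b in the initial state
        y0_cell = np.array(y0_cell, dtype=float)
        y0_cell[41] = drug[6]
    Y = np.tile(np.asarray(y0_cell, dtype=float), (config.n_cells, 1))
    p = config.stimulus
    total = p.n_beats * p.cycle_length
    n_steps = int(round(total / config.dt))
    stride = max(1, int(round(config.stride_ms / config.dt)))
    n_out = n_steps // stride + 1
    V = np.empty((config.n_cells, n_out))
    B = np.empty((config.n_cells, n_out))
    flag, step, cell = ord_model.integrate_string(
        Y, 0.0, n_steps, config.dt, coupling_rate(config.gj_ps_per_pf),
        p.amplitude, p.duration, p.cycle_length, p.start_time, p.n_beats,
        drug, config.celltype, config.completions, stride, V, B,
    )
    if flag != 0:
        raise FloatingPointError(
            f"cable integration unstable at t = {step * config.dt:.3f} ms in cell {cell + 1}"
        )
    t = np.arange(n_out) * stride * config.dt
    return CableTrace(time=t, v=V, b=B, config=config)


def activation_times(
    trace: CableTrace,
    window: tuple[float, float],
    threshold: float = ACTIVATION_THRESHOLD_MV,
) -> np.ndarray:
    """First upward threshold crossing per cell within a time window.

    Linearly interpolated between samples; cells that never cross are NaN.
    """
    t0, t1 = window
    sel = (trace.time >= t0) & (trace.time <= t1)
    if not np.any(sel):
        raise ValueError(f"window [{t0}, {t1}] ms not covered by the trace")
    tw = trace.time[sel]
    out = np.full(trace.v.shape[0], np.nan)
    for c in range(trace.v.shape[0]):
        vw = trace.v[c, sel]
        above = vw >= threshold
        # upward crossings only; a cell already above threshold at window
        # start counts once it has returned below and crosses again
        idx = np.where(~above[:-1] & above[1:])[0]
        if idx.size:
            i = idx[0]
            frac = (threshold - vw[i]) / (vw[i + 1] - vw[i])
            out[c] = tw[i] + frac * (tw[i + 1] - tw[i])
    return out


def conduction_velocity(
    times: np.ndarray,
    config: CableConfig,
    beat_index: int = 1,
) -> CvResult:
    """CV over the whole strand from first/last-cell activation times.

    cv = (n_cells × cell_length) / (t_last − t_first), reported in cm/s.
    The total-string length convention (5 mm at defaults) matches how the
    propagation delay over the strand is read off the raster.
    """
    times = np.asarray(times, dtype=float)
    if np.isnan(times[0]) or np.isnan(times[-1]):
        return CvResult(beat_index, times, float("nan"), propagated=False)
    dt_ms = times[-1] - times[0]
    if dt_ms <= 0:
        raise ValueError("degenerate activation pattern: end-to-end delay <= 0")
    length_cm = config.length_um * 1e-4
    cv = length_cm / (dt_ms * 1e-3)
    return CvResult(beat_index, times, cv, propagated=True)


def measure_cv(
    trace: CableTrace,
    beat_index: int = 1,
    threshold: float = ACTIVATION_THRESHOLD_MV,
) -> CvResult:
    """Activation detection + CV for the given beat (0-based index)."""
    p = trace.config.stimulus
    t0 = p.start_time + beat_index * p.cycle_length
    t1 = min(t0 + p.cycle_length, trace.time[-1])
    times = activation_times(trace, (t0, t1), threshold)
    if np.isnan(times[0]) or np.isnan(times[-1]):
        return CvResult(beat_index, times, float("nan"), propagated=False)
    return conduction_velocity(times, trace.config, beat_index)
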