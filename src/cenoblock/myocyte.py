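"""Single-cell simulation driver over the compiled myocyte kernel."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import ord_model
from .block import BlockKinetics, equilibrium_block_fraction

__all__ = [
    "StimulusProtocol",
    "SingleCellResult",
    "drug_params",
    "run_single_cell",
    "prepaced_state",
    "beat_diagnostics",
]

DT_DEFAULT = 0.005          # ms
STRIDE_DEFAULT = 0.1        # ms output sampling


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic current-clamp pacing."""

    amplitude: float = -80.0     # µA/µF
    duration: float = 0.5        # ms
    cycle_length: float = 1000.0  # ms
    n_beats: int = 1
    start_time: float = 0.0      # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.cycle_length <= self.duration:
            raise ValueError("cycle length must exceed stimulus duration")
        if self.n_beats < 0:
            raise ValueError("n_beats must be >= 0")


@dataclass
class SingleCellResult:
    time: np.ndarray          # ms
    v: np.ndarray             # mV
    b: np.ndarray             # blocked fraction
    final_state: np.ndarray
    diagnostics: list = field(default_factory=list)  # per-beat dicts


def drug_params(
    kin: BlockKinetics | None,
    concentration_uM: float,
    mode: str = "kinetic",
) -> np.ndarray:
    """Kernel drug-parameter vector for a kinetics/concentration/mode choice.

    Zero concentration with kinetics still runs the ODE (trapped drug may
    unbind); ``kin=None`` disables the block entirely.
    """
    if kin is None:
        return ord_model.pack_drug(mode=0)
    if mode == "kinetic":
        return ord_model.pack_drug(
            mode=1,
            concentration_uM=concentration_uM,
            kon_open=kin.kon_open,
            kon_inact=kin.kon_inact,
            koff_open=kin.koff_open,
            koff_inact=kin.koff_inact,
            koff_rest=kin.koff_rest,
        )
    if mode == "equilibrium":
        b_eq = equilibrium_block_fraction(concentration_uM, kin.kd_open_uM)
        return ord_model.pack_drug(mode=2, b_eq=b_eq)
    raise ValueError(f"unknown block mode {mode!r}")


def _check_state(y: np.ndarray) -> None:
    bad = np.where(~np.isfinite(y))[0]
    if bad.size:
        names = [ord_model.STATE_NAMES[i] for i in bad]
        raise FloatingPointError(f"non-finite state variable(s): {names}")


def run_single_cell(
    protocol: StimulusProtocol,
    drug: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    dt: float = DT_DEFAULT,
    stride_ms: float = STRIDE_DEFAULT,
    celltype: int = 0,
    completions: int = 1,
    extra_time: float = 0.0,
) -> SingleCellResult:
    """Pace one myocyte and return its voltage trace with per-beat diagnostics.

    Total simulated time is ``n_beats × cycle_length + extra_time`` (an empty
    protocol with ``n_beats=0`` returns the initial state unchanged).
    """
    if not (0.0 < dt <= 0.02):
        raise ValueError("dt must be in (0, 0.02] ms for the explicit scheme")
    y0 = ord_model.initial_state() if y0 is None else np.array(y0, dtype=float)
    _check_state(y0)
    if drug is None:
        drug = ord_model.pack_drug(mode=0)
    total = protocol.n_beats * protocol.cycle_length + extra_time
    if total <= 0:
        return SingleCellResult(
            time=np.array([0.0]), v=np.array([y0[0]]), b=np.array([y0[41]]),
            final_state=y0, diagnostics=[],
        )
    n_steps = int(round(total / dt))
    stride = max(1, int(round(stride_ms / dt)))
    n_out = n_steps // stride + 1
    Y = y0.reshape(1, -1).copy()
    V = np.empty((1, n_out))
    B = np.empty((1, n_out))
    flag, step, _cell = ord_model.integrate_string(
        Y, 0.0, n_steps, dt, 0.0,
        protocol.amplitude, protocol.duration, protocol.cycle_length,
        protocol.start_time, protocol.n_beats,
        drug, celltype, completions, stride, V, B,
    )
    if flag != 0:
        raise FloatingPointError(
            f"integration unstable at t = {step * dt:.3f} ms (|V| > 200 mV or non-finite)"
        )
    t = np.arange(n_out) * stride * dt
    result = SingleCellResult(time=t, v=V[0], b=B[0], final_state=Y[0])
    for k in range(protocol.n_beats):
        t0 = protocol.start_time + k * protocol.cycle_length
        result.diagnostics.append(
            beat_diagnostics(t, V[0], t0, min(t0 + protocol.cycle_length, t[-1]))
        )
    return result


def beat_diagnostics(t: np.ndarray, v: np.ndarray, t_start: float, t_end: float) -> dict:
    """Peak upstroke velocity (mV/ms ≡ V/s), peak V, and APD90 for one beat window."""
    sel = (t >= t_start) & (t <= t_end)
    tw, vw = t[sel], v[sel]
    if tw.size < 3:
        return {"dvdt_max": np.nan, "v_peak": np.nan, "apd90": np.nan}
    dvdt = np.diff(vw) / np.diff(tw)
    i_up = int(np.argmax(dvdt))
    v_rest = vw[0]
    v_peak = float(vw.max())
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    apd90 = np.nan
    i_peak = int(np.argmax(vw))
    below = np.where(vw[i_peak:] <= v90)[0]
    if below.size:
        i_r = i_peak + below[0]
        # linear interpolation of the repolarization crossing
        if i_r > 0 and vw[i_r - 1] > v90:
            frac = (vw[i_r - 1] - v90) / (vw[i_r - 1] - vw[i_r])
            t_cross = tw[i_r - 1] + frac * (tw[i_r] - tw[i_r - 1])
        else:
            t_cross = tw[i_r]
        apd90 = float(t_cross - tw[i_up])
    return {"dvdt_max": float(dvdt.max()), "v_peak": v_peak, "apd90": apd90}


@lru_cache(maxsize=8)
def _prepaced_cached(n_beats: int, cycle_length: float, dt: float, celltype: int,
                     completions: int) -> bytes:
    protocol = StimulusProtocol(n_beats=n_beats, cycle_length=cycle_length)
    res = run_single_cell(protocol, dt=dt, stride_ms=1.0, celltype=celltype,
                          completions=completions)
    return res.final_state.tobytes()


def prepaced_state(
    n_beats: int = 50,
    cycle_length: float = 1000.0,
    dt: float = DT_DEFAULT,
    celltype: int = 0,
    completions: int = 1,
) -> np.ndarray:
    """Drug-free steady-pacing state used as the starting point of experiments.

    Cached per (n_beats, cycle_length, dt, celltype, completions) within a process.
    """
    raw = _prepaced_cached(n_beats, float(cycle_length), float(dt), int(celltype),
                           int(completions))
    return np.frombuffer(raw, dtype=float).copy()
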