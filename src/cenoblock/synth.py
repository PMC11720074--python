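"""Seeded synthetic-data generators for every input class the pipeline reads.

These emulate the study's raw inputs so the whole pipeline is testable
offline: replicate docking scores (normal noise around a mean binding
energy), per-snapshot MM-PBSA energies (normal with a given mean/SD,
50 snapshots by convention), and idealized propagating-upstroke voltage
traces with a known conduction velocity for exercising the activation-time
and CV estimators.  All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import numpy as np

from .affinity import DockingReplicateSet
from .cable import CableConfig, CableTrace

__all__ = [
    "gen_docking_replicates",
    "gen_mmpbsa_snapshots",
    "gen_propagation_trace",
]


def gen_docking_replicates(
    dg_mean: float,
    noise_sd: float,
    n: int = 3,
    seed: int = 0,
    variant_id: str = "synthetic",
) -> DockingReplicateSet:
    """n replicate docking scores ~ Normal(dg_mean, noise_sd)."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores = dg_mean + noise_sd * rng.standard_normal(n)
    return DockingReplicateSet(variant_id=variant_id, scores=tuple(float(s) for s in scores))


def gen_mmpbsa_snapshots(
    dg_mean: float,
    dg_sd: float,
    n: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """n per-snapshot binding energies ~ Normal(dg_mean, dg_sd)."""
    if n < 2:
        raise ValueError("need n >= 2 snapshots")
    if dg_sd < 0:
        raise ValueError("dg_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return dg_mean + dg_sd * rng.standard_normal(n)


def gen_propagation_trace(
    cv_true_cm_s: float,
    n_cells: int = 50,
    cell_length_um: float = 100.0,
    upstroke_width_ms: float = 1.0,
    v_rest: float = -87.0,
    v_peak: float = 35.0,
    jitter_sd_ms: float = 0.0,
    t_first_ms: float = 5.0,
    duration_ms: float | None = None,
    sample_ms: float = 0.1,
    seed: int = 0,
) -> CableTrace:
    """Idealized strand trace: per-cell sigmoidal upstrokes at constant velocity.

    Upstroke times are spaced so the end-to-end (cell 1 → cell N) delay
    equals total string length / cv_true, matching the total-string CV
    definition; the estimator should therefore recover ``cv_true`` exactly
    up to interpolation error and optional timing jitter.
    ``upstroke_width_ms=0`` produces step upstrokes.
    """
    if cv_true_cm_s <= 0:
        raise ValueError("cv_true must be > 0")
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    length_cm = n_cells * cell_length_um * 1e-4
    total_delay_ms = length_cm / cv_true_cm_s * 1e3
    t_up = t_first_ms + np.arange(n_cells) * total_delay_ms / (n_cells - 1)
    if jitter_sd_ms > 0:
        rng = np.random.default_rng(seed)
        # end cells kept exact so jitter perturbs the profile, not the endpoints
        jitter = jitter_sd_ms * rng.standard_normal(n_cells)
        jitter[0] = jitter[-1] = 0.0
        t_up = t_up + jitter
    if duration_ms is None:
        duration_ms = t_first_ms + total_delay_ms + 20.0
    t = np.arange(0.0, duration_ms + sample_ms / 2, sample_ms)
    if upstroke_width_ms <= 0:
        v = np.where(t[None, :] >= t_up[:, None], v_peak, v_rest)
    else:
        z = (t[None, :] - t_up[:, None]) / (upstroke_width_ms / 4.0)
        v = v_rest + (v_peak - v_rest) / (1.0 + np.exp(-z))
    config = CableConfig(n_cells=n_cells, cell_length_um=cell_length_um)
    return CableTrace(time=t, v=v.astype(float), b=np.zeros_like(v), config=config)
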