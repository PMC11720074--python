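"""Experiment orchestration: variant × gap-junction conductance × concentration.

Reproduces the study's conduction-velocity experiment from the affinity
table: wild-type binding kinetics are anchored to the wild-type docking Kd,
each variant's unblocking rates are rescaled to its own Kd, and each
(variant, G_j, concentration) combination is run on the 50-cell strand with
CV measured on the second propagated beat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import io as _io
from .affinity import ThermalScale, build_affinity_table
from .block import DrugCondition, scale_unblocking_rates, wildtype_kinetics
from .cable import CableConfig, measure_cv, run_cable
from .myocyte import StimulusProtocol, drug_params

__all__ = ["variant_kd_table", "run_matrix", "compare_to_reference"]


def variant_kd_table(
    config: _io.RunConfig,
    scale: ThermalScale | None = None,
) -> pd.DataFrame:
    """Per-variant Kd (µM) for the configured affinity method."""
    docking = _io.load_docking_table(config.docking_csv)
    mmpbsa = _io.load_mmpbsa_table(config.mmpbsa_csv)
    scale = scale or (ThermalScale(config.rt_eff) if config.rt_eff else ThermalScale())
    table = build_affinity_table(docking, mmpbsa, scale=scale)
    return table[table.method == config.affinity_method].set_index("variant_id")


def run_matrix(
    config: _io.RunConfig | None = None,
    wildtype_id: str = "WT",
    beat_index: int = 1,
) -> pd.DataFrame:
    """One CV row per (variant, G_j, concentration) combination.

    Every row carries full provenance: the measured CV, the variant Kd used,
    the equilibrium blocked fraction it implies, and the config hash.
    """
    config = config or _io.RunConfig()
    kd = variant_kd_table(config)
    unknown = [v for v in config.variants if v not in kd.index]
    if unknown:
        raise ValueError(f"unknown variants {unknown}; known: {sorted(kd.index)}")
    kd_wt = float(kd.loc[wildtype_id, "kd_uM"])
    wt_kin = wildtype_kinetics(kd_wt, config.kon_open, config.kon_inact)
    chash = _io.config_hash(config)
    stim = StimulusProtocol(
        amplitude=config.stim_amplitude,
        duration=config.stim_duration_ms,
        cycle_length=config.cycle_length_ms,
        n_beats=config.n_beats,
    )
    rows = []
    for gj in config.gj_values:
        cable_cfg = CableConfig(
            n_cells=config.n_cells,
            cell_length_um=config.cell_length_um,
            gj_ps_per_pf=gj,
            stimulus=stim,
            dt=config.dt_ms,
            stride_ms=config.output_stride_ms,
            celltype={"endo": 0, "epi": 1, "mid": 2}[config.celltype],
            completions=int(config.completions),
            prepace_beats=config.prepace_beats,
        )
        for variant in config.variants:
            kd_var = float(kd.loc[variant, "kd_uM"])
            cond = DrugCondition(
                concentration_uM=0.0, variant_id=variant,
                kd_variant_uM=kd_var, kd_wildtype_uM=kd_wt,
            )
            kin = scale_unblocking_rates(wt_kin, cond)
            for conc in config.concentrations_uM:
                drug = drug_params(kin, conc, mode=config.block_mode)
                trace = run_cable(cable_cfg, drug=drug)
                cv = measure_cv(trace, beat_index=beat_index)
                rows.append(
                    {
                        "variant_id": variant,
                        "gj_ps_per_pf": gj,
                        "concentration_uM": conc,
                        "kd_uM": kd_var,
                        "block_eq": conc / (conc + kd_var),
                        "cv_cm_s": cv.cv_cm_s,
                        "propagated": cv.propagated,
                        "beat_index": cv.beat_index,
                        "block_mode": config.block_mode,
                        "config_hash": chash,
                    }
                )
    return pd.DataFrame(rows)


def compare_to_reference(
    results: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-row relative CV deviation and per-G_j ordering concordance.

    Joins on (variant_id, gj_ps_per_pf); raises if any reference row has no
    matching result.  The ``kendall_tau`` column holds, per G_j group, the
    rank concordance between simulated and reference CV across variants
    (NaN for singleton groups, which are flagged with ``concordance_defined``).
    """
    reference = reference if reference is not None else _io.load_reference_cv()
    merged = reference.merge(
        results, on=["variant_id", "gj_ps_per_pf"],
        how="left", suffixes=("_ref", ""), indicator=True,
    )
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", ["variant_id", "gj_ps_per_pf"]]
        raise ValueError(f"results missing reference keys:\n{missing}")
    merged = merged.drop(columns="_merge")
    merged["rel_dev"] = (merged["cv_cm_s"] - merged["cv_cm_s_ref"]) / merged["cv_cm_s_ref"]
    # failed propagation ranks as the slowest possible conduction
    cv_rank = merged["cv_cm_s"].where(merged.get("propagated", True), 0.0).fillna(0.0)
    taus = {}
    for gj, grp in merged.assign(cv_rank=cv_rank).groupby("gj_ps_per_pf"):
        if len(grp) < 2:
            taus[gj] = np.nan
        else:
            taus[gj] = kendalltau(grp["cv_cm_s_ref"], grp["cv_rank"]).statistic
    merged["kendall_tau"] = merged["gj_ps_per_pf"].map(taus)
    merged["concordance_defined"] = merged["kendall_tau"].notna()
    return merged
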