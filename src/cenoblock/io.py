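"""CSV / config I/O.

All tables are plain UTF-8 comma-separated files with a header row and "."
decimals.  Tables transcribed from typeset sources may carry Unicode minus
signs (U+2212) or non-breaking spaces; readers normalize these to ASCII.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "RunConfig",
    "load_affinity_table",
    "load_docking_table",
    "load_mmpbsa_table",
    "load_reference_cv",
    "write_results",
    "config_hash",
]

_UNICODE_NORMALIZATION = {
    "−": "-",   # minus sign
    "–": "-",   # en dash
    " ": " ",   # no-break space
}


class RunConfig(BaseModel):
    """Validated configuration for a simulation run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    variants: list[str] = Field(default_factory=lambda: ["WT", "N1463K", "N1463Y", "M1766R"])
    gj_values: list[float] = Field(default_factory=lambda: [1000.0, 2000.0])
    concentrations_uM: list[float] = Field(default_factory=lambda: [17.0])
    affinity_method: str = "docking"
    block_mode: str = "kinetic"
    kon_open: float = 0.01           # µM⁻¹·ms⁻¹
    kon_inact: float = 0.01          # µM⁻¹·ms⁻¹
    rt_eff: float | None = None      # None → calibrated default
    dt_ms: float = 0.005
    output_stride_ms: float = 0.1
    cycle_length_ms: float = 1000.0
    n_beats: int = 2
    stim_amplitude: float = -120.0   # µA/µF; strand pacing must beat the gap-junction sink
    stim_duration_ms: float = 3.0
    completions: bool = True         # CiPA conductance recalibration on top of ORd 2011
    prepace_beats: int = 50
    n_cells: int = 50
    cell_length_um: float = 100.0
    celltype: str = "endo"
    seed: int = 0
    docking_csv: str | None = None
    mmpbsa_csv: str | None = None


def _read_normalized_csv(source: str | Path) -> pd.DataFrame:
    """Read a CSV, normalizing typeset Unicode punctuation to ASCII."""
    path = Path(source)
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise
    if not text.strip():
        raise ValueError(f"{path}: empty table file")
    for uni, ascii_ in _UNICODE_NORMALIZATION.items():
        text = text.replace(uni, ascii_)
    try:
        return pd.read_csv(StringIO(text))
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def _packaged(name: str) -> Path:
    return Path(str(resources.files("cenoblock").joinpath("data", name)))


def load_docking_table(path: str | Path | None = None) -> pd.DataFrame:
    """Replicate docking scores; defaults to the packaged published table."""
    df = _read_normalized_csv(path or _packaged("table1_docking.csv"))
    required = {"variant_id", "rep1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"docking table missing columns: {sorted(missing)}")
    return df


def load_mmpbsa_table(path: str | Path | None = None) -> pd.DataFrame:
    """MM-PBSA summaries; defaults to the packaged published table."""
    df = _read_normalized_csv(path or _packaged("table1_mmpbsa.csv"))
    required = {"variant_id", "dg_mean", "dg_sd", "n_snapshots"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mmpbsa table missing columns: {sorted(missing)}")
    return df


def load_affinity_table(path: str | Path) -> pd.DataFrame:
    """Load either affinity-table dialect by sniffing its columns."""
    df = _read_normalized_csv(path)
    if "dg_mean" in df.columns:
        return load_mmpbsa_table(path)
    return load_docking_table(path)


def load_reference_cv() -> pd.DataFrame:
    """Published conduction velocities (variant × gap-junction conductance)."""
    return _read_normalized_csv(_packaged("reference_cv.csv"))


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def config_hash(config: RunConfig) -> str:
    """Short deterministic digest of a full run configuration."""
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
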