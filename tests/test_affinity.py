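"""Binding-energy aggregation and the ΔG ↔ Kd conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenoblock import affinity as aff

SCALE = aff.ThermalScale()


@pytest.mark.parametrize(
    "scores, expected",
    [
        ((-5.479, -5.523, -5.489), -5.497),      # wild-type triplicate
        ((-6.110, -6.253, -6.227), -6.1966667),  # N1463K triplicate
        ((-4.2,), -4.2),                          # single replicate: identity
    ],
)
def test_mean_binding_energy(scores, expected):
    reps = aff.DockingReplicateSet("x", scores)
    assert aff.mean_binding_energy(reps) == pytest.approx(expected, abs=1e-6)


def test_empty_replicates_rejected():
    with pytest.raises(ValueError):
        aff.DockingReplicateSet("x", ())


@pytest.mark.parametrize(
    "dg, kd_uM",
    [
        (-5.497, 90.37),    # wild-type docking mean
        (-6.0063, 38.13),   # N1463Y docking mean
        (-8.8912, 0.287734),  # wild-type MM-PBSA
    ],
)
def test_kd_from_energy_reproduces_published_values(dg, kd_uM):
    assert aff.kd_from_energy(dg, SCALE) * 1e6 == pytest.approx(kd_uM, rel=1e-3)


def test_kd_of_zero_energy_is_one_molar():
    assert aff.kd_from_energy(0.0, SCALE) == 1.0
    assert aff.energy_from_kd(1.0, SCALE) == 0.0


def test_kd_rejects_nonfinite_energy():
    with pytest.raises(ValueError):
        aff.kd_from_energy(float("nan"), SCALE)
    with pytest.raises(ValueError):
        aff.energy_from_kd(0.0, SCALE)


def test_thermal_scale_validation():
    with pytest.raises(ValueError):
        aff.ThermalScale(-1.0)
    assert aff.ThermalScale.physical(298.15).rt_eff == pytest.approx(0.592484, rel=1e-4)


def test_rt_eff_inversion_consistent_across_all_rows(docking_df, mmpbsa_df):
    """Brute-force inversion rt = ΔG / ln Kd row by row: every one of the 18
    table rows implies the same effective RT to within ±0.00015 kcal/mol."""
    rts = []
    for _, r in docking_df.iterrows():
        dg = np.mean([r.rep1, r.rep2, r.rep3])
        rts.append(dg / math.log(r.kd_printed_uM * 1e-6))
    for _, r in mmpbsa_df.iterrows():
        rts.append(r.dg_mean / math.log(r.kd_printed_uM * 1e-6))
    rts = np.array(rts)
    assert rts.min() > 0.5902 and rts.max() < 0.5905
    lstsq = aff.calibrate_rt_eff(
        np.concatenate([docking_df[["rep1", "rep2", "rep3"]].mean(axis=1), mmpbsa_df.dg_mean]),
        np.concatenate([docking_df.kd_printed_uM, mmpbsa_df.kd_printed_uM]) * 1e-6,
    )
    assert lstsq == pytest.approx(aff.RT_EFF_DEFAULT, abs=5e-6)


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=-20.0, max_value=0.0))
def test_energy_kd_round_trip_identity(dg):
    back = aff.energy_from_kd(aff.kd_from_energy(dg, SCALE), SCALE)
    assert back == pytest.approx(dg, rel=1e-10, abs=1e-10)


@settings(max_examples=100, deadline=None)
@given(st.floats(min_value=-20.0, max_value=-0.01), st.floats(min_value=0.01, max_value=5.0))
def test_kd_strictly_increasing_in_energy(dg, step):
    assert aff.kd_from_energy(dg + step, SCALE) > aff.kd_from_energy(dg, SCALE)


def test_summarize_snapshot_energies():
    s = aff.summarize_snapshot_energies([-10.0, -10.0, -10.0, -10.0])
    assert s.dg_mean == -10.0 and s.dg_sd == 0.0
    s = aff.summarize_snapshot_energies([-1.0, 1.0])
    assert s.dg_mean == 0.0 and s.dg_sd == pytest.approx(math.sqrt(2))
    pop = aff.summarize_snapshot_energies([-1.0, 1.0], ddof=0)
    assert pop.dg_sd == pytest.approx(1.0)
    with pytest.raises(ValueError):
        aff.summarize_snapshot_energies([-1.0])


def _estimates(df, method, scale=SCALE):
    out = []
    for _, r in df.iterrows():
        if method == "docking":
            dg = float(np.mean([r.rep1, r.rep2, r.rep3]))
        else:
            dg = float(r.dg_mean)
        out.append(aff.AffinityEstimate(r.variant_id, method, dg, aff.kd_from_energy(dg, scale)))
    return out


def test_docking_flags_match_published_asterisks(docking_df):
    ranked = aff.rank_variants(_estimates(docking_df, "docking"))
    flagged = {e.variant_id for e in ranked if e.stronger_than_wildtype}
    assert flagged == {"N927S", "N1463K", "N1463Y", "M1766R"}


def test_mmpbsa_flags_all_mutants_with_n932s_first(mmpbsa_df):
    ranked = aff.rank_variants(_estimates(mmpbsa_df, "mmpbsa"))
    flagged = {e.variant_id for e in ranked if e.stronger_than_wildtype}
    assert flagged == {v for v in mmpbsa_df.variant_id if v != "WT"}
    assert ranked[0].variant_id == "N932S"


def test_rank_variants_edge_cases():
    wt = aff.AffinityEstimate("WT", "docking", -5.5, 1e-4)
    assert aff.rank_variants([wt]) == [wt] and not wt.stronger_than_wildtype
    with pytest.raises(ValueError, match="wild-type"):
        aff.rank_variants([aff.AffinityEstimate("A", "docking", -5.0, 1e-4)])
    with pytest.raises(ValueError, match="mixed"):
        aff.rank_variants([wt, aff.AffinityEstimate("A", "mmpbsa", -5.0, 1e-4)])


def test_flags_invariant_under_uniform_energy_shift(docking_df):
    base = {e.variant_id: e.stronger_than_wildtype
            for e in aff.rank_variants(_estimates(docking_df, "docking"))}
    shifted = [
        aff.AffinityEstimate(e.variant_id, e.method, e.dg + 1.7,
                             aff.kd_from_energy(e.dg + 1.7, SCALE))
        for e in _estimates(docking_df, "docking")
    ]
    after = {e.variant_id: e.stronger_than_wildtype for e in aff.rank_variants(shifted)}
    assert base == after


def test_all_18_table_cells_reproduced(docking_df, mmpbsa_df):
    """Regression: every printed Kd (9 docking + 9 MM-PBSA) from its printed
    ΔG inputs to within 0.1 % relative error at the calibrated thermal scale."""
    table = aff.build_affinity_table(docking_df, mmpbsa_df)
    for df, method in ((docking_df, "docking"), (mmpbsa_df, "mmpbsa")):
        sub = table[table.method == method].set_index("variant_id")
        for _, r in df.iterrows():
            got = sub.loc[r.variant_id, "kd_uM"]
            assert got == pytest.approx(r.kd_printed_uM, rel=1e-3), (method, r.variant_id)
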