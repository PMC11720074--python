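"""Single-cell electrophysiology: currents, integration, drug hook."""

import numpy as np
import pytest

from cenoblock import ord_model
from cenoblock.block import wildtype_kinetics
from cenoblock.myocyte import StimulusProtocol, drug_params, run_single_cell

IDX = {n: i for i, n in enumerate(ord_model.STATE_NAMES)}


def test_full_block_silences_sodium_currents(rest_state):
    y = rest_state.copy()
    y[IDX["b"]] = 1.0
    y[IDX["m"]] = 0.9  # open gates wide so only the block can zero the current
    cur = ord_model.ionic_currents(y)
    assert cur["INa"] == 0.0 and cur["INaL"] == 0.0
    y[IDX["b"]] = 0.0
    assert ord_model.ionic_currents(y)["INa"] != 0.0


def test_zero_conductances_leave_only_stimulus(rest_state):
    cur = ord_model.ionic_currents(rest_state, g_scale=0.0)
    assert all(v == 0.0 for v in cur.values())


def test_ionic_currents_rejects_nan(rest_state):
    y = rest_state.copy()
    y[IDX["cai"]] = np.nan
    with pytest.raises(ValueError, match="cai"):
        ord_model.ionic_currents(y)


def test_resting_net_current_near_zero(rest_state):
    """At the paced diastolic state the membrane currents nearly balance."""
    cur = ord_model.ionic_currents(rest_state)
    assert abs(sum(cur.values())) < 0.05  # µA/µF


@pytest.mark.parametrize("state_kind", ["rest", "upstroke"])
def test_kernel_and_python_transcriptions_agree(rest_state, state_kind):
    """The compiled step and the readable current transcription implement the
    same equations: the Euler voltage increment equals −Σ I to round-off."""
    if state_kind == "rest":
        y = rest_state.copy()
    else:
        res = run_single_cell(
            StimulusProtocol(n_beats=1, cycle_length=400.0), y0=rest_state,
            stride_ms=0.1,
        )
        y = res.final_state.copy()
        y[IDX["v"]] = -20.0  # probe mid-upstroke voltage with post-beat gates
    dt = 0.005
    y2 = y.reshape(1, -1).copy()
    V = np.empty((1, 1)); B = np.empty((1, 1))
    drug = ord_model.pack_drug(mode=0)
    flag, _, _ = ord_model.integrate_string(
        y2, 0.0, 1, dt, 0.0, 0.0, 1.0, 1000.0, 0.0, 0, drug, 0, 1, 1, V, B)
    assert flag == 0
    dv_kernel = (y2[0, 0] - y[0]) / dt
    dv_python = -sum(ord_model.ionic_currents(y).values())
    assert dv_kernel == pytest.approx(dv_python, rel=1e-8, abs=1e-8)


def test_paced_beat_has_ventricular_ap_shape(rest_state):
    res = run_single_cell(StimulusProtocol(n_beats=1, cycle_length=600.0), y0=rest_state)
    d = res.diagnostics[0]
    assert d["dvdt_max"] > 100.0          # V/s
    assert d["v_peak"] > 20.0
    assert res.v[-1] < -80.0              # repolarized within 600 ms
    assert 150.0 < d["apd90"] < 400.0


def test_dt_refinement_convergence(rest_state):
    """Halving the step changes the action potential by < 0.5 mV."""
    protocol = StimulusProtocol(n_beats=1, cycle_length=400.0)
    a = run_single_cell(protocol, y0=rest_state, dt=0.005, stride_ms=0.1)
    b = run_single_cell(protocol, y0=rest_state, dt=0.0025, stride_ms=0.1)
    assert a.v.shape == b.v.shape
    assert np.max(np.abs(a.v - b.v)) < 0.5


def test_integration_is_deterministic(rest_state):
    protocol = StimulusProtocol(n_beats=1, cycle_length=300.0)
    a = run_single_cell(protocol, y0=rest_state)
    b = run_single_cell(protocol, y0=rest_state)
    assert np.array_equal(a.v, b.v)
    assert np.array_equal(a.final_state, b.final_state)


def test_zero_beats_returns_initial_state(rest_state):
    res = run_single_cell(StimulusProtocol(n_beats=0), y0=rest_state)
    assert res.time.size == 1
    assert np.array_equal(res.final_state, rest_state)


def test_upstroke_slows_monotonically_with_block(rest_state):
    """Stronger equilibrium block ⇒ lower peak dV/dt (D = 0, 17, 170 µM)."""
    kd = 90.37
    dvdts = []
    for conc in [0.0, 17.0, 170.0]:
        drug = drug_params(wildtype_kinetics(kd), conc, mode="equilibrium")
        res = run_single_cell(
            StimulusProtocol(n_beats=1, cycle_length=300.0), drug=drug, y0=rest_state)
        dvdts.append(res.diagnostics[0]["dvdt_max"])
    assert dvdts[0] > dvdts[1] > dvdts[2]


def test_gates_and_concentrations_bounded_over_ten_beats(rest_state):
    res = run_single_cell(
        StimulusProtocol(n_beats=10, cycle_length=500.0), y0=rest_state, stride_ms=1.0)
    y = res.final_state
    gate_idx = [IDX[n] for n in ord_model.STATE_NAMES[9:38]] + [IDX["CaMKt"], IDX["b"]]
    assert all(0.0 <= y[i] <= 1.0 for i in gate_idx)
    conc_idx = [IDX[n] for n in ("nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr")]
    assert all(y[i] > 0.0 for i in conc_idx)
    assert np.all(np.isfinite(res.v))


def test_invalid_dt_rejected(rest_state):
    with pytest.raises(ValueError):
        run_single_cell(StimulusProtocol(n_beats=1), y0=rest_state, dt=0.05)


def test_nan_initial_state_names_variable(rest_state):
    y = rest_state.copy()
    y[IDX["ki"]] = np.nan
    with pytest.raises(FloatingPointError, match="ki"):
        run_single_cell(StimulusProtocol(n_beats=1), y0=y)


def test_stimulus_protocol_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(duration=0.0)
    with pytest.raises(ValueError):
        StimulusProtocol(cycle_length=0.4, duration=0.5)
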