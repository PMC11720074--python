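"""State-dependent block kinetics: rescaling, equilibrium, and the occupancy ODE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from cenoblock import block


def test_wildtype_kinetics_anchored_to_kd():
    kin = block.wildtype_kinetics(90.37)
    assert kin.kd_open_uM == pytest.approx(90.37)
    assert kin.kd_inact_uM == pytest.approx(90.37)
    assert kin.kon_open == block.DEFAULT_KON


@pytest.mark.parametrize(
    "kd_variant, ratio",
    [(90.37, 1.0), (27.62, 0.30563), (36.84, 0.40766)],
)
def test_unblocking_rate_ratio(kd_variant, ratio):
    wt = block.wildtype_kinetics(90.37)
    cond = block.DrugCondition(17.0, "x", kd_variant, 90.37)
    out = block.scale_unblocking_rates(wt, cond)
    assert out.koff_open / wt.koff_open == pytest.approx(ratio, rel=1e-4)
    assert out.kon_open == wt.kon_open and out.kon_inact == wt.kon_inact


@settings(max_examples=100, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e4), st.floats(min_value=1e-3, max_value=1e4))
def test_rescaling_reproduces_target_kd_exactly(kd_wt, kd_var):
    wt = block.wildtype_kinetics(kd_wt)
    out = block.scale_unblocking_rates(wt, block.DrugCondition(1.0, "x", kd_var, kd_wt))
    assert out.kd_open_uM == pytest.approx(kd_var, rel=1e-12)
    assert out.kd_inact_uM == pytest.approx(kd_var, rel=1e-12)


@pytest.mark.parametrize(
    "conc, kd, expected",
    [(5.0, 5.0, 0.5), (0.0, 90.37, 0.0), (17.0, 90.37, 0.15833)],
)
def test_equilibrium_block_fraction(conc, kd, expected):
    assert block.equilibrium_block_fraction(conc, kd) == pytest.approx(expected, rel=1e-3)


def test_equilibrium_block_validation():
    with pytest.raises(ValueError):
        block.equilibrium_block_fraction(1.0, 0.0)
    with pytest.raises(ValueError):
        block.equilibrium_block_fraction(-1.0, 1.0)


def test_no_drug_no_block():
    kin = block.wildtype_kinetics(90.37)
    s = block.BlockState(0.0)
    for _ in range(100):
        s = block.step_block(s, kin, 0.5, 0.3, 0.0, 0.1)
    assert s.b == 0.0


def test_block_relaxation_matches_closed_form():
    """With p_open = 1 the ODE is db/dt = D·kon·(1−b) − koff·b, whose solution
    is mono-exponential toward D/(D+Kd) at rate D·kon + koff."""
    kin = block.wildtype_kinetics(90.37)
    D, dt = 17.0, 0.01
    rate = D * kin.kon_open + kin.koff_open
    b_inf = D * kin.kon_open / rate
    s = block.BlockState(0.0)
    for i in range(500):
        s = block.step_block(s, kin, 1.0, 0.0, D, dt)
    t = 500 * dt
    assert s.b == pytest.approx(b_inf * (1.0 - math.exp(-rate * t)), rel=1e-9)


@pytest.mark.parametrize("p_open, p_inact", [(0.2, 0.5), (1.0, 0.0), (0.0, 0.7), (0.3, 0.3)])
def test_long_time_limit_matches_root_finder(p_open, p_inact):
    """Steady state under any fixed occupancy mix equals the root of the RHS
    found independently by bisection."""
    kin = block.BlockKinetics(kon_open=0.02, koff_open=0.5, kon_inact=0.004, koff_inact=0.09)
    D = 40.0

    def rhs(b):
        on = D * (kin.kon_open * p_open + kin.kon_inact * p_inact)
        off = kin.koff_open * p_open + kin.koff_inact * p_inact
        return on * (1 - b) - off * b

    b_star = brentq(rhs, 0.0, 1.0)
    s = block.BlockState(0.0)
    for _ in range(20000):
        s = block.step_block(s, kin, p_open, p_inact, D, 0.05)
    assert s.b == pytest.approx(b_star, abs=1e-8)


@settings(max_examples=150, deadline=None)
@given(
    b0=st.floats(min_value=0.0, max_value=1.0),
    kon=st.floats(min_value=0.0, max_value=1.0),
    koff=st.floats(min_value=0.0, max_value=10.0),
    po=st.floats(min_value=0.0, max_value=1.0),
    pi=st.floats(min_value=0.0, max_value=1.0),
    conc=st.floats(min_value=0.0, max_value=1000.0),
    dt=st.floats(min_value=1e-4, max_value=10.0),
)
def test_blocked_fraction_stays_bounded(b0, kon, koff, po, pi, conc, dt):
    pi = min(pi, 1.0 - po)
    kin = block.BlockKinetics(kon_open=kon, koff_open=koff, kon_inact=kon, koff_inact=koff)
    s = block.BlockState(b0)
    for _ in range(20):
        s = block.step_block(s, kin, po, pi, conc, dt)
        assert 0.0 <= s.b <= 1.0


def test_kinetic_limit_converges_to_equilibrium_mode():
    """Scaling kon and koff together toward infinity at fixed ratio drives the
    one-step occupancy to the binding isotherm."""
    D, kd = 17.0, 90.37
    target = block.equilibrium_block_fraction(D, kd)
    for speed in [1.0, 100.0, 10000.0]:
        kin = block.BlockKinetics(
            kon_open=0.01 * speed, koff_open=0.01 * kd * speed,
            kon_inact=0.01 * speed, koff_inact=0.01 * kd * speed,
        )
        s = block.BlockState(0.0)
        for _ in range(50):
            s = block.step_block(s, kin, 0.4, 0.4, D, 0.1)
        if speed >= 100.0:
            assert s.b == pytest.approx(target, rel=1e-6)


def test_effective_gna_scale():
    assert block.effective_gna_scale(block.BlockState(0.0)) == 1.0
    assert block.effective_gna_scale(block.BlockState(0.5)) == 0.5
    b = block.equilibrium_block_fraction(17.0, 90.37)
    assert 1.0 - b == pytest.approx(0.84167, rel=1e-4)


def test_step_block_validation():
    kin = block.wildtype_kinetics(90.37)
    with pytest.raises(ValueError):
        block.step_block(block.BlockState(0.0), kin, 0.5, 0.2, 17.0, 0.0)
    with pytest.raises(ValueError):
        block.step_block(block.BlockState(0.0), kin, 1.5, 0.2, 17.0, 0.1)
    with pytest.raises(ValueError):
        block.BlockState(1.2)
    with pytest.raises(ValueError):
        block.DrugCondition(-1.0, "x", 1.0, 1.0)
    with pytest.raises(ValueError):
        block.DrugCondition(1.0, "x", 0.0, 1.0)
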