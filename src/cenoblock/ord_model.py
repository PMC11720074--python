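"""O'Hara–Rudy 2011 human ventricular myocyte model (endo default).

The full published dynamic model: fast and late Na+ current, transient
outward K+, L-type Ca2+ (with Ca-dependent inactivation and CaMK-phosphorylated
modes), rapid/slow delayed rectifiers, inward rectifier, Na/Ca exchange
(myoplasmic and subspace), Na/K pump, background currents, SR release/uptake
and the CaMK signalling that shifts gating between phosphorylated and
non-phosphorylated pathways — 41 state variables, plus one extra state for
the cenobamate blocked fraction ``b`` of the Nav conductance pool.

By default the 2011 parameter set carries the CiPA-initiative conductance
recalibration for in-silico pharmacology (IKr ×1.013, IKs ×1.870,
IK1 ×1.698, INaL ×2.661, ICaL ×1.007; ``completions=0`` restores the
original values).  The stronger inward rectifier hyperpolarises the
diastolic potential, raising Na-channel availability — without it a
50-cell strand at six-fold-reduced gap-junction coupling cannot sustain
propagation at all.

The drug hook scales both INa and INaL by (1 − b); ``b`` follows the
conformation-gated binding ODE of :mod:`cenoblock.block`, advanced with the
same time step using an exact exponential update.  Occupancies feeding the
block ODE are taken from the INa gating variables: open ≈ m³·h·j,
inactivated ≈ 1 − h·j (the non-conducting, non-rested pool).

Integration is Rush–Larsen (exponential update) for every Hodgkin–Huxley
gate and forward Euler for membrane potential and concentrations, the
standard scheme for ORd-class models.  The hot path is compiled with numba;
:func:`ionic_currents` is a plain-Python transcription of the same current
equations kept for inspection and used by the tests as an internal
cross-check of the compiled kernel.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "NSTATE",
    "STATE_NAMES",
    "CELLTYPE",
    "initial_state",
    "ionic_currents",
    "integrate_string",
    "pack_drug",
]

# ---------------------------------------------------------------------------
# constants (published parameter set)

NAO = 140.0   # mM
CAO = 1.8
KO = 5.4
RGAS = 8314.0   # J/(kmol·K)
TEMP = 310.0    # K
FARADAY = 96485.0

CELL_LENGTH_CM = 0.01
CELL_RADIUS_CM = 0.0011
VCELL = 1000.0 * 3.14 * CELL_RADIUS_CM * CELL_RADIUS_CM * CELL_LENGTH_CM  # µL
AGEO = 2.0 * 3.14 * CELL_RADIUS_CM * CELL_RADIUS_CM + 2.0 * 3.14 * CELL_RADIUS_CM * CELL_LENGTH_CM
ACAP = 2.0 * AGEO          # cm²
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

CELLTYPE = {"endo": 0, "epi": 1, "mid": 2}

# Conductance recalibration of the CiPA in-silico proarrhythmia initiative
# (optimized against human ventricular data for drug-trial use); applied on
# top of the 2011 parameter set when ``completions=1``.
CIPA_GKR_SCALE = 1.013
CIPA_GKS_SCALE = 1.870
CIPA_GK1_SCALE = 1.698
CIPA_GNAL_SCALE = 2.661
CIPA_PCA_SCALE = 1.007

STATE_NAMES = [
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
    "b",
]
NSTATE = len(STATE_NAMES)  # 42

IV = 0


def initial_state() -> np.ndarray:
    """Published resting initial conditions (pre-pace before experiments)."""
    y = np.zeros(NSTATE)
    vals = dict(
        v=-87.0, nai=7.0, nass=7.0, ki=145.0, kss=145.0,
        cai=1.0e-4, cass=1.0e-4, cansr=1.2, cajsr=1.2,
        m=0.0, hf=1.0, hs=1.0, j=1.0, hsp=1.0, jp=1.0,
        mL=0.0, hL=1.0, hLp=1.0,
        a=0.0, iF=1.0, iS=1.0, ap=0.0, iFp=1.0, iSp=1.0,
        d=0.0, ff=1.0, fs=1.0, fcaf=1.0, fcas=1.0, jca=1.0, nca=0.0,
        ffp=1.0, fcafp=1.0,
        xrf=0.0, xrs=0.0, xs1=0.0, xs2=0.0, xk1=1.0,
        Jrelnp=0.0, Jrelp=0.0, CaMKt=0.0, b=0.0,
    )
    for i, name in enumerate(STATE_NAMES):
        y[i] = vals[name]
    return y


def pack_drug(
    mode: int = 0,
    concentration_uM: float = 0.0,
    kon_open: float = 0.0,
    kon_inact: float = 0.0,
    koff_open: float = 0.0,
    koff_inact: float = 0.0,
    b_eq: float = 0.0,
    koff_rest: float = 0.0,
) -> np.ndarray:
    """Pack drug parameters for the kernel: mode 0=none, 1=kinetic, 2=equilibrium."""
    return np.array(
        [float(mode), concentration_uM, kon_open, kon_inact,
         koff_open, koff_inact, b_eq, koff_rest],
        dtype=np.float64,
    )


# ---------------------------------------------------------------------------
# compiled kernel


#: Maximum membrane-potential change per internal step (mV); larger proposed
#: increments trigger substepping so the upstroke is resolved independently
#: of the nominal dt.
DV_MAX_MV = 0.05


@njit(cache=True)
def _step_once(y, dt, istim, dv_extra, drug, celltype, completions):
    """Advance one cell by dt in place; returns dV/dt evaluated at entry."""
    v = y[0]
    if abs(v) < 1.0e-6:
        v = 1.0e-6  # avoid 0/0 in GHK driving forces
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
    m = y[9]; hf = y[10]; hs = y[11]; j = y[12]; hsp = y[13]; jp = y[14]
    mL = y[15]; hL = y[16]; hLp = y[17]
    a = y[18]; iF = y[19]; iS = y[20]; ap = y[21]; iFp = y[22]; iSp = y[23]
    d = y[24]; ff = y[25]; fs = y[26]; fcaf = y[27]; fcas = y[28]
    jca = y[29]; nca = y[30]; ffp = y[31]; fcafp = y[32]
    xrf = y[33]; xrs = y[34]; xs1 = y[35]; xs2 = y[36]; xk1 = y[37]
    Jrelnp = y[38]; Jrelp = y[39]; CaMKt = y[40]; b = y[41]

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05; bCaMK = 0.00068; CaMKo = 0.05; KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dCaMKt = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    rtf = RGAS * TEMP / FARADAY
    ENa = rtf * math.log(NAO / nai)
    EK = rtf * math.log(KO / ki)
    PKNa = 0.01833
    EKs = rtf * math.log((KO + PKNa * NAO) / (ki + PKNa * nai))
    vffrt = v * FARADAY * FARADAY / (RGAS * TEMP)
    vfrt = v * FARADAY / (RGAS * TEMP)

    fp_camk = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    # --- INa
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285) + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05) + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99; Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281) + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    GNa = 75.0

    # drug block occupancies from INa gating (non-phosphorylated pathway)
    avail = h * j
    p_open = m * m * m * avail
    p_inact = 1.0 - avail

    mode = drug[0]
    if mode == 1.0:
        D = drug[1]
        p_rest = 1.0 - p_open - p_inact
        if p_rest < 0.0:
            p_rest = 0.0
        on = D * (drug[2] * p_open + drug[3] * p_inact)
        off = drug[4] * p_open + drug[5] * p_inact + drug[7] * p_rest
        tot = on + off
        if tot > 0.0:
            b_inf = on / tot
            b = b_inf + (b - b_inf) * math.exp(-dt * tot)
            if b < 0.0:
                b = 0.0
            elif b > 1.0:
                b = 1.0
    elif mode == 2.0:
        b = drug[6]
    gna_scale = 1.0 - b

    INa = gna_scale * GNa * (v - ENa) * m * m * m * ((1.0 - fp_camk) * h * j + fp_camk * hp * jp)

    # --- INaL
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075
    if completions == 1:
        GNaL = GNaL * CIPA_GNAL_SCALE
    if celltype == 1:
        GNaL = GNaL * 0.6
    INaL = gna_scale * GNaL * (v - ENa) * mL * ((1.0 - fp_camk) * hL + fp_camk * hLp)

    # --- Ito
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if celltype == 1:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF = tiF * delta_epi
    tiS = tiS * delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    ito_i = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ito_ip = AiF * iFp + AiS * iSp
    Gto = 0.02
    if celltype == 1 or celltype == 2:
        Gto = Gto * 4.0
    Ito = Gto * (v - EK) * ((1.0 - fp_camk) * a * ito_i + fp_camk * ap * ito_ip)

    # --- ICaL / ICaNa / ICaK
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6; Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    ktaup = 2.5
    tffp = ktaup * tff
    f_p = Aff * ffp + Afs * fs
    tfcafp = ktaup * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002; k2n = 1000.0
    km2n = jca * 1.0
    tmp = 1.0 + Kmn / cass
    anca = 1.0 / (k2n / km2n + tmp * tmp * tmp * tmp)
    e2v = math.exp(2.0 * vfrt)
    e1v = math.exp(vfrt)
    PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * CAO) / (e2v - 1.0)
    PhiCaNa = 1.0 * vffrt * (0.75 * nass * e1v - 0.75 * NAO) / (e1v - 1.0)
    PhiCaK = 1.0 * vffrt * (0.75 * kss * e1v - 0.75 * KO) / (e1v - 1.0)
    PCa = 0.0001
    if completions == 1:
        PCa = PCa * CIPA_PCA_SCALE
    if celltype == 1:
        PCa = PCa * 1.2
    elif celltype == 2:
        PCa = PCa * 2.5
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (f_p * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fp_camk) * PCa * PhiCaL * gate_np + fp_camk * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fp_camk) * PCaNa * PhiCaNa * gate_np + fp_camk * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fp_camk) * PCaK * PhiCaK * gate_np + fp_camk * PCaKp * PhiCaK * gate_p

    # --- IKr
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + math.exp((v + 55.0) / 75.0)) * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0))
    GKr = 0.046
    if completions == 1:
        GKr = GKr * CIPA_GKR_SCALE
    if celltype == 1:
        GKr = GKr * 1.3
    elif celltype == 2:
        GKr = GKr * 0.8
    IKr = GKr * math.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    # --- IKs
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034
    if completions == 1:
        GKs = GKs * CIPA_GKS_SCALE
    if celltype == 1:
        GKs = GKs * 1.4
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # --- IK1
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * KO + 144.59) / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * KO) / 9.493))
    GK1 = 0.1908
    if completions == 1:
        GK1 = GK1 * CIPA_GK1_SCALE
    if celltype == 1:
        GK1 = GK1 * 1.2
    elif celltype == 2:
        GK1 = GK1 * 1.3
    IK1 = GK1 * math.sqrt(KO) * rk1 * xk1 * (v - EK)

    # --- INaCa (myoplasmic and subspace)
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12; kasymm = 12.5
    wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    Gncx = 0.0008
    if celltype == 1:
        Gncx = Gncx * 1.1
    elif celltype == 2:
        Gncx = Gncx * 1.4
    KmCaAct = 150.0e-6

    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # subspace
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

    # --- INaK
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3pk = 1899.0; k3m = 79300.0; k4pk = 639.0; k4m = 40.0
    Knai0 = 9.073; Knao0 = 27.78; delta_nak = -0.1550
    Knai = Knai0 * math.exp(delta_nak * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta_nak) * vfrt / 3.0)
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    Hp = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + Hp / Khp + nai / Knap + ki / Kxkur)
    t_nai = 1.0 + nai / Knai
    t_nao = 1.0 + NAO / Knao
    t_ki = 1.0 + ki / Kki
    t_ko = 1.0 + KO / Kko
    a1 = (k1p * (nai / Knai) ** 3) / (t_nai ** 3 + t_ki ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (NAO / Knao) ** 3) / (t_nao ** 3 + t_ko ** 2 - 1.0)
    a3 = (k3pk * (KO / Kko) ** 2) / (t_nao ** 3 + t_ko ** 2 - 1.0)
    b3 = (k3m * P * Hp) / (1.0 + MgATP / Kmgatp)
    a4 = (k4pk * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / (t_nai ** 3 + t_ki ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if celltype == 1:
        Pnak = Pnak * 0.9
    elif celltype == 2:
        Pnak = Pnak * 0.7
    INaK = Pnak * (JnakNa + JnakK)

    # --- background and pump currents
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if celltype == 1:
        GKb = GKb * 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * e1v - NAO) / (e1v - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * e2v - 0.341 * CAO) / (e2v - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- diffusion fluxes
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- SR release
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_inf = Jrel_inf * 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_infp = Jrel_infp * 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fp_camk) * Jrelnp + fp_camk * Jrelp

    # --- SR uptake / leak / translocation
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if celltype == 1:
        Jupnp = Jupnp * 1.3
        Jupp = Jupp * 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp_camk) * Jupnp + fp_camk * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- membrane potential
    Iion = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab)
    dv = -(Iion + istim) + dv_extra

    # --- concentration derivatives
    dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * ACAP / (FARADAY * VMYO) + JdiffNa * VSS / VMYO
    dnass = -(ICaNa + 3.0 * INaCa_ss) * ACAP / (FARADAY * VSS) - JdiffNa
    dki = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) * ACAP / (FARADAY * VMYO) + JdiffK * VSS / VMYO
    dkss = -ICaK * ACAP / (FARADAY * VSS) - JdiffK

    cmdnmax = 0.05
    if celltype == 1:
        cmdnmax = cmdnmax * 1.3
    kmcmdn = 0.00238; trpnmax = 0.07; kmtrpn = 0.0005
    BSRmax = 0.047; KmBSR = 0.00087; BSLmax = 1.124; KmBSL = 0.0087
    csqnmax = 10.0; kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2 + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dcai = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * FARADAY * VMYO)
                   - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2 + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dcass = Bcass * (-(ICaL - 2.0 * INaCa_ss) * ACAP / (2.0 * FARADAY * VSS)
                     + Jrel * VJSR / VSS - Jdiff)
    dcansr = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dcajsr = Bcajsr * (Jtr - Jrel)

    # --- updates: Rush–Larsen for gates, Euler for the rest
    y[0] = y[0] + dt * dv
    y[1] = nai + dt * dnai
    y[2] = nass + dt * dnass
    y[3] = ki + dt * dki
    y[4] = kss + dt * dkss
    y[5] = cai + dt * dcai
    y[6] = cass + dt * dcass
    y[7] = cansr + dt * dcansr
    y[8] = cajsr + dt * dcajsr

    y[9] = mss + (m - mss) * math.exp(-dt / tm)
    y[10] = hss + (hf - hss) * math.exp(-dt / thf)
    y[11] = hss + (hs - hss) * math.exp(-dt / ths)
    y[12] = jss + (j - jss) * math.exp(-dt / tj)
    y[13] = hssp + (hsp - hssp) * math.exp(-dt / thsp)
    y[14] = jss + (jp - jss) * math.exp(-dt / tjp)
    y[15] = mLss + (mL - mLss) * math.exp(-dt / tmL)
    y[16] = hLss + (hL - hLss) * math.exp(-dt / thL)
    y[17] = hLssp + (hLp - hLssp) * math.exp(-dt / thLp)
    y[18] = ass + (a - ass) * math.exp(-dt / ta)
    y[19] = iss + (iF - iss) * math.exp(-dt / tiF)
    y[20] = iss + (iS - iss) * math.exp(-dt / tiS)
    y[21] = assp + (ap - assp) * math.exp(-dt / ta)
    y[22] = iss + (iFp - iss) * math.exp(-dt / tiFp)
    y[23] = iss + (iSp - iss) * math.exp(-dt / tiSp)
    y[24] = dss + (d - dss) * math.exp(-dt / td)
    y[25] = fss + (ff - fss) * math.exp(-dt / tff)
    y[26] = fss + (fs - fss) * math.exp(-dt / tfs)
    y[27] = fcass + (fcaf - fcass) * math.exp(-dt / tfcaf)
    y[28] = fcass + (fcas - fcass) * math.exp(-dt / tfcas)
    y[29] = fcass + (jca - fcass) * math.exp(-dt / tjca)
    nca_inf = anca * k2n / km2n
    y[30] = nca_inf + (nca - nca_inf) * math.exp(-dt * km2n)
    y[31] = fss + (ffp - fss) * math.exp(-dt / tffp)
    y[32] = fcass + (fcafp - fcass) * math.exp(-dt / tfcafp)
    y[33] = xrss + (xrf - xrss) * math.exp(-dt / txrf)
    y[34] = xrss + (xrs - xrss) * math.exp(-dt / txrs)
    y[35] = xs1ss + (xs1 - xs1ss) * math.exp(-dt / txs1)
    y[36] = xs2ss + (xs2 - xs2ss) * math.exp(-dt / txs2)
    y[37] = xk1ss + (xk1 - xk1ss) * math.exp(-dt / txk1)
    y[38] = Jrel_inf + (Jrelnp - Jrel_inf) * math.exp(-dt / tau_rel)
    y[39] = Jrel_infp + (Jrelp - Jrel_infp) * math.exp(-dt / tau_relp)
    y[40] = CaMKt + dt * dCaMKt
    y[41] = b
    return dv


@njit(cache=True)
def _step_cell(y, dt, istim, dv_extra, drug, celltype, completions):
    """Advance one cell by dt, substepping fast phases.  0 = OK, 1 = unstable."""
    y_try = y.copy()
    dv = _step_once(y_try, dt, istim, dv_extra, drug, celltype, completions)
    if abs(dv) * dt <= DV_MAX_MV:
        y[:] = y_try
    else:
        n = int(abs(dv) * dt / DV_MAX_MV) + 1
        if n > 256:
            n = 256
        h = dt / n
        for _ in range(n):
            _step_once(y, h, istim, dv_extra, drug, celltype, completions)
    if not math.isfinite(y[0]) or abs(y[0]) > 200.0:
        return 1
    return 0


@njit(cache=True)
def integrate_string(Y, t0, n_steps, dt, k_coup, stim_amp, stim_dur,
                     cycle_length, first_stim, n_stim, drug, celltype,
                     completions, stride, V_out, B_out):
    """Advance a string of cells; stimulate cell 0; sample V (and b) every stride steps.

    Returns (flag, step, cell): flag 0 = OK, 1 = instability (|V| > 200 mV
    or non-finite) at the given step and cell.
    """
    n_cells = Y.shape[0]
    n_out = V_out.shape[1]
    vprev = np.empty(n_cells)
    iout = 0
    for s in range(n_steps):
        if s % stride == 0 and iout < n_out:
            for c in range(n_cells):
                V_out[c, iout] = Y[c, 0]
                B_out[c, iout] = Y[c, 41]
            iout += 1
        t = t0 + s * dt
        istim = 0.0
        if n_stim > 0 and t >= first_stim:
            kbeat = int((t - first_stim) / cycle_length)
            if kbeat < n_stim and (t - first_stim - kbeat * cycle_length) < stim_dur:
                istim = stim_amp
        for c in range(n_cells):
            vprev[c] = Y[c, 0]
        for c in range(n_cells):
            if n_cells > 1 and k_coup > 0.0:
                if c == 0:
                    dv_extra = k_coup * (vprev[1] - vprev[0])
                elif c == n_cells - 1:
                    dv_extra = k_coup * (vprev[n_cells - 2] - vprev[n_cells - 1])
                else:
                    dv_extra = k_coup * (vprev[c - 1] - 2.0 * vprev[c] + vprev[c + 1])
            else:
                dv_extra = 0.0
            ist = istim if c == 0 else 0.0
            flag = _step_cell(Y[c], dt, ist, dv_extra, drug, celltype, completions)
            if flag != 0:
                return flag, s, c
    if iout < n_out:
        for c in range(n_cells):
            V_out[c, iout] = Y[c, 0]
            B_out[c, iout] = Y[c, 41]
    return 0, n_steps, -1


# ---------------------------------------------------------------------------
# plain-Python current transcription (inspection + internal cross-check)


def ionic_currents(y: np.ndarray, celltype: int = 0, g_scale: float = 1.0,
                   completions: int = 1) -> dict:
    """All membrane current densities (µA/µF) at a given state.

    A readable re-transcription of the current equations used by the
    compiled kernel; the test suite checks both transcriptions agree.
    ``g_scale`` uniformly scales every conductance/permeability (handy for
    isolating the stimulus term).  The drug hook multiplies INa and INaL by
    (1 − b) with b read from the state vector.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.where(~np.isfinite(y))[0]]
        raise ValueError(f"non-finite state variable(s): {bad}")
    v = y[0] if abs(y[0]) >= 1e-6 else 1e-6
    (nai, nass, ki, kss, cai, cass) = y[1:7]
    (m, hf, hs, j, hsp, jp, mL, hL, hLp) = y[9:18]
    (a, iF, iS, ap, iFp, iSp) = y[18:24]
    (d, ff, fs, fcaf, fcas, jca, nca, ffp, fcafp) = y[24:33]
    (xrf, xrs, xs1, xs2, xk1) = y[33:38]
    CaMKt = y[40]
    b = y[41]

    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    CaMKa = CaMKb + CaMKt
    fp = 1.0 / (1.0 + 0.15 / CaMKa)

    rtf = RGAS * TEMP / FARADAY
    ENa = rtf * math.log(NAO / nai)
    EK = rtf * math.log(KO / ki)
    EKs = rtf * math.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))
    vffrt = v * FARADAY * FARADAY / (RGAS * TEMP)
    vfrt = v * FARADAY / (RGAS * TEMP)
    e1v, e2v = math.exp(vfrt), math.exp(2.0 * vfrt)

    gna_scale = 1.0 - b
    GNa = 75.0 * g_scale
    h = 0.99 * hf + 0.01 * hs
    hp = 0.99 * hf + 0.01 * hsp
    INa = gna_scale * GNa * (v - ENa) * m ** 3 * ((1.0 - fp) * h * j + fp * hp * jp)

    GNaL = 0.0075 * (CIPA_GNAL_SCALE if completions else 1.0) * (0.6 if celltype == 1 else 1.0) * g_scale
    INaL = gna_scale * GNaL * (v - ENa) * mL * ((1.0 - fp) * hL + fp * hLp)

    Gto = 0.02 * (4.0 if celltype in (1, 2) else 1.0) * g_scale
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    Ito = Gto * (v - EK) * ((1.0 - fp) * a * (AiF * iF + (1 - AiF) * iS)
                            + fp * ap * (AiF * iFp + (1 - AiF) * iSp))

    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    f = 0.6 * ff + 0.4 * fs
    f_p = 0.6 * ffp + 0.4 * fs
    fca = Afcaf * fcaf + (1 - Afcaf) * fcas
    fcap = Afcaf * fcafp + (1 - Afcaf) * fcas
    PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * CAO) / (e2v - 1.0)
    PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * NAO) / (e1v - 1.0)
    PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * KO) / (e1v - 1.0)
    PCa = (0.0001 * (CIPA_PCA_SCALE if completions else 1.0)
           * (1.2 if celltype == 1 else 2.5 if celltype == 2 else 1.0) * g_scale)
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (f_p * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fp) * PCa * PhiCaL * gate_np + fp * 1.1 * PCa * PhiCaL * gate_p
    ICaNa = ((1.0 - fp) * 0.00125 * PCa * PhiCaNa * gate_np
             + fp * 0.00125 * 1.1 * PCa * PhiCaNa * gate_p)
    ICaK = ((1.0 - fp) * 3.574e-4 * PCa * PhiCaK * gate_np
            + fp * 3.574e-4 * 1.1 * PCa * PhiCaK * gate_p)

    GKr = (0.046 * (CIPA_GKR_SCALE if completions else 1.0)
           * (1.3 if celltype == 1 else 0.8 if celltype == 2 else 1.0) * g_scale)
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    xr = Axrf * xrf + (1 - Axrf) * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))) * (1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
    IKr = GKr * math.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    GKs = 0.0034 * (CIPA_GKS_SCALE if completions else 1.0) * (1.4 if celltype == 1 else 1.0) * g_scale
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    GK1 = (0.1908 * (CIPA_GK1_SCALE if completions else 1.0)
           * (1.2 if celltype == 1 else 1.3 if celltype == 2 else 1.0) * g_scale)
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * KO) / 9.493))
    IK1 = GK1 * math.sqrt(KO) * rk1 * xk1 * (v - EK)

    Gncx = 0.0008 * (1.1 if celltype == 1 else 1.4 if celltype == 2 else 1.0) * g_scale
    INaCa_i = _inaca(v, vfrt, nai, cai, 0.8 * Gncx)
    INaCa_ss = _inaca(v, vfrt, nass, cass, 0.2 * Gncx)

    Pnak = 30.0 * (0.9 if celltype == 1 else 0.7 if celltype == 2 else 1.0) * g_scale
    INaK = _inak(vfrt, nai, ki, Pnak)

    GKb = 0.003 * (0.6 if celltype == 1 else 1.0) * g_scale
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = GKb * xkb * (v - EK)
    INab = g_scale * 3.75e-10 * vffrt * (nai * e1v - NAO) / (e1v - 1.0)
    ICab = g_scale * 2.5e-8 * 4.0 * vffrt * (cai * e2v - 0.341 * CAO) / (e2v - 1.0)
    IpCa = g_scale * 0.0005 * cai / (0.0005 + cai)

    return {
        "INa": INa, "INaL": INaL, "Ito": Ito,
        "ICaL": ICaL, "ICaNa": ICaNa, "ICaK": ICaK,
        "IKr": IKr, "IKs": IKs, "IK1": IK1,
        "INaCa_i": INaCa_i, "INaCa_ss": INaCa_ss, "INaK": INaK,
        "INab": INab, "ICab": ICab, "IKb": IKb, "IpCa": IpCa,
    }


def _inaca(v, vfrt, na, ca, g):
    kna1, kna2, kna3, kasymm = 15.0, 5.0, 88.12, 12.5
    wna, wca, wnaca = 6.0e4, 6.0e4, 5.0e3
    kcaon, kcaoff = 1.5e6, 5.0e3
    hca = math.exp(0.1670 * vfrt)
    hna = math.exp(0.5224 * vfrt)
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3 = h9 * wca + h8 * wnaca
    k4 = h3 * wca / hca + h2 * wnaca
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1, E2, E3, E4 = x1 / s, x2 / s, x3 / s, x4 / s
    allo = 1.0 / (1.0 + (150.0e-6 / ca) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * h2 * wnaca - E2 * h8 * wnaca
    JncxCa = E2 * k2 - E1 * k1
    return g * allo * (JncxNa + 2.0 * JncxCa)


def _inak(vfrt, nai, ki, Pnak):
    k1p, k1m, k2p, k2m = 949.5, 182.4, 687.2, 39.4
    k3p, k3m, k4p, k4m = 1899.0, 79300.0, 639.0, 40.0
    Knai = 9.073 * math.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * math.exp((1.0 + 0.1550) * vfrt / 3.0)
    Kki, Kko = 0.5, 0.3582
    MgADP, MgATP, Kmgatp = 0.05, 9.8, 1.698e-7
    Hp, eP, Khp, Knap, Kxkur = 1.0e-7, 4.2, 1.698e-7, 224.0, 292.0
    P = eP / (1.0 + Hp / Khp + nai / Knap + ki / Kxkur)
    dnai = (1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0
    dnao = (1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0
    a1 = k1p * (nai / Knai) ** 3 / dnai
    b1 = k1m * MgADP
    a2 = k2p
    b2 = k2m * (NAO / Knao) ** 3 / dnao
    a3 = k3p * (KO / Kko) ** 2 / dnao
    b3 = k3m * P * Hp / (1.0 + MgATP / Kmgatp)
    a4 = k4p * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = k4m * (ki / Kki) ** 2 / dnai
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    E1, E2, E3, E4 = x1 / s, x2 / s, x3 / s, x4 / s
    return Pnak * (3.0 * (E1 * a3 - E2 * b3) + 2.0 * (E4 * b1 - E3 * a1))
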