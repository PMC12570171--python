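"""Courtemanche–Ramirez–Nattel (CRN) human atrial myocyte model.

The 21-variable CRN model: membrane potential, 15 gating variables and 5
intracellular concentrations (Na+, K+, free Ca2+, SR-uptake and
SR-release Ca2+).  All rate expressions and constants follow the
published formulation; removable singularities in the rate functions are
handled with their analytic limits.

Conventions: time ms, potential mV, currents pA/pF (Cm = 100 pF),
concentrations mM.  ``IonicParams`` carries the multipliers used for AF
electrical remodeling (g_to x0.40, g_CaL x0.35, g_K1 x2.00) and the
per-cell Na+ conductance factor used to emulate heterogeneous
loss-of-function (0.30 on affected cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# physical constants
R_GAS = 8.3143          # J/(mol*K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C/mmol
RTF = R_GAS * TEMP / FARADAY
CM = 100.0              # pF

# cell compartment volumes, um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

# extracellular concentrations, mM
NA_O = 140.0
K_O = 5.4
CA_O = 1.8

# maximal conductances (nS/pF) and pump/exchanger constants
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.00113
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

# Ca handling
K_REL = 30.0
K_UP = 0.00092
I_UP_MAX = 0.005
CA_UP_MAX = 15.0
TRPN_MAX = 0.07
KM_TRPN = 0.0005
CMDN_MAX = 0.05
KM_CMDN = 0.00238
CSQN_MAX = 10.0
KM_CSQN = 0.8
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0
KQ10 = 3.0

STATE_NAMES = ["Vm", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
               "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai",
               "Caup", "Carel"]

# published steady-state initial conditions (quiescent cell)
RESTING_STATE = np.array([
    -81.18,        # Vm
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    1.117e1,       # Nai
    1.390e2,       # Ki
    1.013e-4,      # Cai
    1.488,         # Caup
    1.488,         # Carel
])

# indices of the 12 purely voltage-dependent gates, in state order
VOLTAGE_GATES = ["m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
                 "d", "f", "w"]


@dataclass(frozen=True)
class IonicParams:
    """Conductance multipliers relative to the published CRN values."""

    f_gto: float = 1.0
    f_gcal: float = 1.0
    f_gk1: float = 1.0
    gna_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_gto", "f_gcal", "f_gk1", "gna_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


BASELINE = IonicParams()
# AF electrical remodeling: Ito 40%, ICaL 35%, IK1 200% of normal
AF_REMODELING = IonicParams(f_gto=0.40, f_gcal=0.35, f_gk1=2.00)
# heterogeneous Na+ loss-of-function: 70% reduction on affected cells
BRS_GNA_FACTOR = 0.30


def _safe_ratio(num: np.ndarray, den: np.ndarray, limit: float,
                tol: float = 1e-9) -> np.ndarray:
    """num/den with an analytic limit where den -> 0."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < tol
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_inf_tau(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady states and time constants (ms) of the 12 voltage gates.

    Returns arrays of shape ``(12, len(V))`` ordered as VOLTAGE_GATES.
    """
    V = np.atleast_1d(np.asarray(V, dtype=float))
    inf = np.empty((12, len(V)))
    tau = np.empty((12, len(V)))

    # INa gates (Luo-Rudy style kinetics)
    a_m = _safe_ratio(0.32 * (V + 47.13),
                      1.0 - np.exp(-0.1 * (V + 47.13)), 3.2, 1e-7)
    b_m = 0.08 * np.exp(-V / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    low = V < -40.0
    a_h = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(low,
                   3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                   1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)

    a_j = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0)
    b_j = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V)
        / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))))
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # Ito gates
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau[3] = 1.0 / ((a_oa + b_oa) * KQ10)

    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf[4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau[4] = 1.0 / ((a_oi + b_oi) * KQ10)

    # IKur gates (activation kinetics shared with oa)
    inf[5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    tau[5] = tau[3]

    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    tau[6] = 1.0 / ((a_ui + b_ui) * KQ10)

    # IKr activation
    a_xr = _safe_ratio(0.0003 * (V + 14.1),
                       1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015, 1e-7)
    b_xr = _safe_ratio(7.3898e-5 * (V - 3.3328),
                       np.exp((V - 3.3328) / 5.1237) - 1.0,
                       7.3898e-5 * 5.1237, 1e-7)
    inf[7] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau[7] = 1.0 / (a_xr + b_xr)

    # IKs activation
    a_xs = _safe_ratio(4e-5 * (V - 19.9),
                       1.0 - np.exp(-(V - 19.9) / 17.0), 4e-5 * 17.0, 1e-7)
    b_xs = _safe_ratio(3.5e-5 * (V - 19.9),
                       np.exp((V - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0, 1e-7)
    inf[8] = np.sqrt(1.0 / (1.0 + np.exp(-(V - 19.9) / 12.7)))
    tau[8] = 0.5 / (a_xs + b_xs)

    # ICaL gates
    e_d = np.exp(-(V + 10.0) / 6.24)
    inf[9] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    tau[9] = _safe_ratio(1.0 - e_d, 0.035 * (V + 10.0) * (1.0 + e_d),
                         1.0 / (0.035 * 6.24 * 2.0), 1e-7)
    inf[10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    # SR release inactivation gate w
    e_w = np.exp(-(V - 7.9) / 5.0)
    inf[11] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    tau[11] = _safe_ratio(6.0 * (1.0 - e_w),
                          (1.0 + 0.3 * e_w) * (V - 7.9),
                          6.0 / (5.0 * 1.3), 1e-7)
    return inf, tau


def voltage_factors(V: np.ndarray) -> np.ndarray:
    """Purely voltage-dependent current factors, shape ``(6, len(V))``:
    g_Kur(V), IK1 rectification, IKr rectification, f_NaK, and the two
    Na/Ca-exchanger exponentials."""
    V = np.atleast_1d(np.asarray(V, dtype=float))
    out = np.empty((6, len(V)))
    out[0] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    out[1] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    out[2] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    out[3] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                    + 0.0365 * sigma * np.exp(-V / RTF))
    out[4] = np.exp(GAMMA * V / RTF)
    out[5] = np.exp((GAMMA - 1.0) * V / RTF)
    return out


def _fn_gates(Fn: float) -> tuple[float, float, float]:
    """u_inf, v_inf and tau_v as functions of the SR release flux signal."""
    s = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
    u_inf = s
    tau_v = 1.91 + 2.09 * s
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 1.367e-15))
    return u_inf, v_inf, tau_v


def crn_rhs(state: np.ndarray, params: IonicParams = BASELINE,
            istim: float = 0.0) -> np.ndarray:
    """Time derivative of the full 21-variable state.

    ``istim`` is the stimulus current in pA/pF (depolarizing positive).
    Raises on NaN in the state, naming the offending variable.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (21,):
        raise ValueError("state must have 21 entries")
    bad = np.nonzero(np.isnan(state))[0]
    if len(bad):
        raise FloatingPointError(
            f"NaN in state variable {STATE_NAMES[bad[0]]!r}")

    (Vm, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Caup, Carel) = state

    inf, tau = gate_inf_tau(Vm)
    inf, tau = inf[:, 0], tau[:, 0]
    gkur, ik1f, ikrf, fnak, expg, expg1 = voltage_factors(Vm)[:, 0]

    ena = RTF * np.log(NA_O / Nai)
    ek = RTF * np.log(K_O / Ki)
    eca = 0.5 * RTF * np.log(CA_O / Cai)

    ina = G_NA * params.gna_factor * m ** 3 * h * j * (Vm - ena)
    ik1 = G_K1 * params.f_gk1 * ik1f * (Vm - ek)
    ito = G_TO * params.f_gto * oa ** 3 * oi * (Vm - ek)
    ikur = gkur * ua ** 3 * ui * (Vm - ek)
    ikr = G_KR * xr * ikrf * (Vm - ek)
    iks = G_KS * xs ** 2 * (Vm - ek)
    ical = G_CAL * params.f_gcal * d * f * fca * (Vm - 65.0)
    inak = I_NAK_MAX * fnak * (K_O / (K_O + KM_K_O)) \
        / (1.0 + (KM_NA_I / Nai) ** 1.5)
    inaca = I_NACA_MAX * (expg * Nai ** 3 * CA_O
                          - expg1 * NA_O ** 3 * Cai) \
        / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
           * (1.0 + K_SAT * expg1))
    ibna = G_B_NA * (Vm - ena)
    ibca = G_B_CA * (Vm - eca)
    ipca = I_PCA_MAX * Cai / (0.0005 + Cai)

    irel = K_REL * u ** 2 * v * w * (Carel - Cai)
    itr = (Caup - Carel) / TAU_TR
    iup = I_UP_MAX / (1.0 + K_UP / Cai)
    iupleak = I_UP_MAX * Caup / CA_UP_MAX

    Fn = 1e-12 * V_REL * irel \
        - (5e-13 / FARADAY) * (0.5 * ical * CM - 0.2 * inaca * CM)
    u_inf, v_inf, tau_v = _fn_gates(Fn)
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
            + ibna + ibca + ipca)

    deriv = np.empty(21)
    deriv[0] = -iion + istim
    gates = np.array([m, h, j, oa, oi, ua, ui, xr, xs, d, f, w])
    deriv[1:12] = ((inf - gates) / tau)[:11]
    deriv[15] = (inf[11] - w) / tau[11]
    deriv[12] = (fca_inf - fca) / TAU_F_CA
    deriv[13] = (u_inf - u) / TAU_U
    deriv[14] = (v_inf - v) / tau_v

    deriv[16] = (-3.0 * inak - 3.0 * inaca - ibna - ina) * CM \
        / (FARADAY * V_I)
    deriv[17] = (2.0 * inak - ik1 - ito - ikur - ikr - iks) * CM \
        / (FARADAY * V_I)
    b1 = (2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * FARADAY * V_I) \
        + (V_UP * (iupleak - iup) + irel * V_REL) / V_I
    b2 = 1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2 \
        + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2
    deriv[18] = b1 / b2
    deriv[19] = iup - iupleak - itr * V_REL / V_UP
    deriv[20] = (itr - irel) \
        / (1.0 + CSQN_MAX * KM_CSQN / (Carel + KM_CSQN) ** 2)
    return deriv
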