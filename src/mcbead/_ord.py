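"""Numerical core: O'Hara-Rudy (2011) human ventricular myocyte model.

The model equations and parameters are transcribed from the published
O'Hara-Rudy formulation (endo/mid/epi cell types, 41 state variables,
CaMK-dependent phosphorylation pathways).  The Dutta et al. (2017)
conductance-rescaled variant ("OHRmv") multiplies five maximal
conductances of the base model.

Two integrators are provided:

* ``integrate_euler`` -- fixed-step forward Euler.  This is the gold
  standard for afterdepolarization work; with ``dt = 0.001 ms`` a pause
  protocol integrates ~1e8 steps, so the voltage-dependent rate
  expressions are evaluated through a dense lookup table (0.01 mV grid,
  linear interpolation), the same device production cardiac simulators
  use.  An exact mode (``use_table=False``) evaluates every expression
  directly and is used in tests to bound the table error.

* ``integrate_hybrid`` -- Rush-Larsen updates for the Hodgkin-Huxley
  gates with a two-level adaptive step, for long steady-state pacing
  runs where no EAD decision is taken.

All functions here are deterministic; given identical inputs they
produce bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Physical constants and cell geometry
# ---------------------------------------------------------------------------

R = 8314.0          # J/kmol/K
T = 310.0           # K
F = 96485.0         # C/mol
FRT = F / (R * T)

NAO = 140.0         # mM
CAO = 1.8
KO = 5.4
PKNA = 0.01833

_L = 0.01           # cm
_RAD = 0.0011
VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# CaMK
KMCAMK = 0.15
ACAMK = 0.05
BCAMK = 0.00068
CAMKO = 0.05
KMCAM = 0.0015

# ---------------------------------------------------------------------------
# State vector layout (41 states)
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(STATE_NAMES)

(IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR,
 IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP,
 IA, IIF, IIS, IAP, IIFP, IISP,
 ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP,
 IXRF, IXRS, IXS1, IXS2, IXK1, IJRELNP, IJRELP, ICAMKT) = range(N_STATES)


def initial_state() -> np.ndarray:
    """Published model initial conditions (approximate 1 Hz resting state)."""
    s = np.zeros(N_STATES)
    s[IV] = -87.0
    s[INAI] = 7.0
    s[INASS] = 7.0
    s[IKI] = 145.0
    s[IKSS] = 145.0
    s[ICAI] = 1.0e-4
    s[ICASS] = 1.0e-4
    s[ICANSR] = 1.2
    s[ICAJSR] = 1.2
    for i in (IHF, IHS, IJ, IHSP, IJP, IHL, IHLP, IIF, IIS, IIFP, IISP,
              IFF, IFS, IFCAF, IFCAS, IJCA, IFFP, IFCAFP, IXK1):
        s[i] = 1.0
    return s


# ---------------------------------------------------------------------------
# Model parameters (maximal conductances etc.) per cell type / variant
# ---------------------------------------------------------------------------

PARAM_NAMES = (
    "GNa", "GNaL", "Gto", "PCa", "GKr", "GKs", "GK1", "Gncx", "Pnak",
    "GKb", "PNab", "PCab", "GpCa", "cmdnmax", "jrel_scale", "jup_scale",
    "is_epi",
)
N_PARAMS = len(PARAM_NAMES)

(PGNA, PGNAL, PGTO, PPCA, PGKR, PGKS, PGK1, PGNCX, PPNAK,
 PGKB, PPNAB, PPCAB, PGPCA, PCMDN, PJRELSC, PJUPSC, PISEPI) = range(N_PARAMS)

# conductances, cell-type multipliers and variant rescalings are data,
# shipped as a versioned YAML file next to this module
def _load_param_file() -> dict:
    import importlib.resources as resources

    import yaml
    ref = resources.files("mcbead") / "data" / "ord_params.yaml"
    return yaml.safe_load(ref.read_text())


_PARAM_FILE = _load_param_file()
_BASE = {k: float(v) for k, v in _PARAM_FILE["base"].items()}
_CELLTYPE = {ct: {k: float(v) for k, v in mult.items()}
             for ct, mult in _PARAM_FILE["cell_type_multipliers"].items()}

#: Dutta et al. (2017) conductance rescalings defining the OHRmv variant.
DUTTA_SCALE = {k: float(v)
               for k, v in _PARAM_FILE["variants"]["OHRmv"].items()}

#: conductance parameter targeted by each drug-blockable channel
CHANNEL_PARAM = {"IKr": "GKr", "ICaV": "PCa", "INaL": "GNaL",
                 "INa_fast": "GNa", "IKs": "GKs", "IK1": "GK1", "Ito": "Gto"}


def build_params(cell_type: str = "endo", variant: str = "OHR",
                 gnal_scale: float = 1.0,
                 multipliers: dict[str, float] | None = None) -> np.ndarray:
    """Assemble the parameter vector for one simulation.

    Parameters
    ----------
    cell_type : "endo", "mid" or "epi".
    variant : "OHR" (original) or "OHRmv" (Dutta-rescaled).
    gnal_scale : scaling of the late-sodium conductance applied before any
        drug block (2.0 emulates the LQT3 gain-of-function condition).
    multipliers : per-channel conductance multipliers (1 - block/100),
        keyed by channel name (see CHANNEL_PARAM).
    """
    if cell_type not in _CELLTYPE:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if variant not in ("OHR", "OHRmv"):
        raise ValueError(f"unknown model variant {variant!r}")
    if gnal_scale < 0:
        raise ValueError("gnal_scale must be >= 0")
    g = dict(_BASE)
    if variant == "OHRmv":
        for k, f_ in DUTTA_SCALE.items():
            g[k] *= f_
    for k, f_ in _CELLTYPE[cell_type].items():
        g[k] *= f_
    g["GNaL"] *= gnal_scale
    if multipliers:
        for ch, mult in multipliers.items():
            if ch not in CHANNEL_PARAM:
                raise ValueError(f"unknown channel {ch!r}")
            if not 0.0 <= mult <= 1.0:
                raise ValueError(f"conductance multiplier for {ch} "
                                 f"outside [0, 1]: {mult}")
            g[CHANNEL_PARAM[ch]] *= mult
    p = np.empty(N_PARAMS)
    for i, name in enumerate(PARAM_NAMES[:13]):
        p[i] = g[name]
    p[PCMDN] = 0.05 * (1.3 if cell_type == "epi" else 1.0)
    p[PJRELSC] = 1.7 if cell_type == "mid" else 1.0
    p[PJUPSC] = 1.3 if cell_type == "epi" else 1.0
    p[PISEPI] = 1.0 if cell_type == "epi" else 0.0
    return p


# ---------------------------------------------------------------------------
# Voltage-dependent expressions (steady states, time constants, GHK factors)
# ---------------------------------------------------------------------------

N_VDEP = 48

(VD_MSS, VD_TM, VD_HSS, VD_THF, VD_THS, VD_TJ, VD_HSSP,
 VD_MLSS, VD_HLSS, VD_HLSSP,
 VD_ASS, VD_TA, VD_ISS, VD_TIF, VD_TIS, VD_AIF, VD_ASSP,
 VD_DTIDEV, VD_DTIREC, VD_DELTAEPI,
 VD_DSS, VD_TD, VD_FSS, VD_TFF, VD_TFS, VD_TFCAF, VD_TFCAS, VD_AFCAF,
 VD_XRSS, VD_TXRF, VD_TXRS, VD_AXRF, VD_RKR,
 VD_XS1SS, VD_TXS1, VD_TXS2,
 VD_XK1SS, VD_TXK1, VD_RK1,
 VD_XKB, VD_HCA, VD_HNA, VD_KNAI, VD_KNAO,
 VD_EXPV, VD_EXP2V, VD_GHKNA, VD_GHKCA) = range(N_VDEP)


@njit(cache=True)
def _vdep(v, out):
    """Evaluate all voltage-dependent expressions at membrane potential v."""
    out[VD_MSS] = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    out[VD_TM] = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                        + 8.552 * np.exp(-(v + 77.42) / 5.955))
    out[VD_HSS] = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    out[VD_THF] = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                         + 6.149 * np.exp((v + 0.5096) / 20.27))
    out[VD_THS] = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                         + 0.3343 * np.exp((v + 5.730) / 56.66))
    out[VD_TJ] = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                                + 0.3052 * np.exp((v + 0.9941) / 38.45))
    out[VD_HSSP] = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))

    out[VD_MLSS] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    out[VD_HLSS] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    out[VD_HLSSP] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))

    out[VD_ASS] = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    out[VD_TA] = 1.0515 / (
        1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    out[VD_ISS] = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    out[VD_TIF] = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                                 + 0.08004 * np.exp((v + 50.0) / 16.59))
    out[VD_TIS] = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                                 + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    out[VD_AIF] = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    out[VD_ASSP] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    out[VD_DTIDEV] = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                       + np.exp(-(v - 12.23) / 0.2154))
    out[VD_DTIREC] = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    out[VD_DELTAEPI] = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))

    out[VD_DSS] = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    out[VD_TD] = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0))
                              + np.exp(0.09 * (v + 14.0)))
    out[VD_FSS] = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    out[VD_TFF] = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                               + 0.0045 * np.exp((v + 20.0) / 10.0))
    out[VD_TFS] = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                                  + 0.000035 * np.exp((v + 5.0) / 6.0))
    out[VD_TFCAF] = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                                 + 0.04 * np.exp((v - 4.0) / 7.0))
    out[VD_TFCAS] = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                                   + 0.00012 * np.exp(v / 7.0))
    out[VD_AFCAF] = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))

    out[VD_XRSS] = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    out[VD_TXRF] = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                                  + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    out[VD_TXRS] = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                                  + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    out[VD_AXRF] = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    out[VD_RKR] = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0))
                         * (1.0 + np.exp((v - 10.0) / 30.0)))

    out[VD_XS1SS] = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    out[VD_TXS1] = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                                  + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    out[VD_TXS2] = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                          + 0.0193 * np.exp(-(v + 66.54) / 31.0))

    out[VD_XK1SS] = 1.0 / (1.0 + np.exp(-(v + 2.5538 * KO + 144.59)
                                        / (1.5692 * KO + 3.8115)))
    out[VD_TXK1] = 122.2 / (np.exp(-(v + 127.2) / 20.36)
                            + np.exp((v + 236.8) / 69.33))
    out[VD_RK1] = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * KO) / 9.493))

    out[VD_XKB] = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    vfrt = v * FRT
    out[VD_HCA] = np.exp(0.1670 * vfrt)
    out[VD_HNA] = np.exp(0.5224 * vfrt)
    out[VD_KNAI] = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    out[VD_KNAO] = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)

    vffrt = v * F * FRT
    expv = np.exp(vfrt)
    exp2v = np.exp(2.0 * vfrt)
    out[VD_EXPV] = expv
    out[VD_EXP2V] = exp2v
    if abs(vfrt) < 1e-7:
        # L'Hopital limits of the GHK flux prefactors at v = 0
        out[VD_GHKNA] = F
        out[VD_GHKCA] = 2.0 * F
    else:
        out[VD_GHKNA] = vffrt / (expv - 1.0)
        out[VD_GHKCA] = 4.0 * vffrt / (exp2v - 1.0)


def make_vtable(vmin: float = -120.0, vmax: float = 80.0,
                dv: float = 0.01) -> tuple[float, float, np.ndarray]:
    """Tabulate the voltage-dependent expressions on a uniform grid.

    Returns (vmin, 1/dv, table) where table[i] holds the N_VDEP values at
    v = vmin + i*dv.  Linear interpolation between rows reproduces the
    exact expressions to ~1e-8 relative at the 0.01 mV default.
    """
    n = int(round((vmax - vmin) / dv)) + 1
    table = np.empty((n, N_VDEP))
    for i in range(n):
        _vdep(vmin + i * dv, table[i])
    return vmin, 1.0 / dv, table


_TABLE_CACHE: dict[tuple[float, float, float], tuple] = {}


def default_vtable() -> tuple[float, float, np.ndarray]:
    """Memoized default lookup table."""
    key = (-120.0, 80.0, 0.01)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = make_vtable(*key)
    return _TABLE_CACHE[key]


# ---------------------------------------------------------------------------
# Right-hand side (shared by both integrators)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _slow_terms(s, slow):
    """Reversal potentials and the Ca-dependent IKs factor.

    These depend only on bulk ionic concentrations, which drift by ~1e-6
    relative per microsecond step, so the fixed-step integrator refreshes
    them on a short cycle (every 16 steps) instead of every step; the
    induced error is below 1e-6 mV while saving the dominant share of
    transcendental evaluations.
    """
    slow[0] = (1.0 / FRT) * np.log(NAO / s[INAI])                    # ENa
    slow[1] = (1.0 / FRT) * np.log(KO / s[IKI])                      # EK
    slow[2] = (1.0 / FRT) * np.log((KO + PKNA * NAO)
                                   / (s[IKI] + PKNA * s[INAI]))      # EKs
    slow[3] = 1.0 + 0.6 / (1.0 + (3.8e-5 / s[ICAI]) ** 1.4)          # KsCa


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _rhs(s, vd, p, ist, slow, ds):
    """Time derivatives of all states given precomputed voltage terms.

    ``s`` state vector, ``vd`` voltage-dependent terms, ``p`` parameters,
    ``ist`` stimulus current (uA/uF), ``slow`` the slowly varying terms
    from ``_slow_terms``.  Writes derivatives into ``ds``.
    """
    v = s[IV]
    nai = s[INAI]
    nass = s[INASS]
    ki = s[IKI]
    kss = s[IKSS]
    cai = s[ICAI]
    cass = s[ICASS]
    cansr = s[ICANSR]
    cajsr = s[ICAJSR]

    # CaMK
    camkb = CAMKO * (1.0 - s[ICAMKT]) / (1.0 + KMCAM / cass)
    camka = camkb + s[ICAMKT]
    ds[ICAMKT] = ACAMK * camkb * camka - BCAMK * s[ICAMKT]
    fp = 1.0 / (1.0 + KMCAMK / camka)   # phosphorylated fraction

    # reversal potentials (refreshed on the slow cycle)
    ena = slow[0]
    ek = slow[1]
    eks = slow[2]

    # INa (fast)
    m = s[IM]
    h = 0.99 * s[IHF] + 0.01 * s[IHS]
    hp = 0.99 * s[IHF] + 0.01 * s[IHSP]
    ina = p[PGNA] * (v - ena) * m * m * m * (
        (1.0 - fp) * h * s[IJ] + fp * hp * s[IJP])

    # INaL
    inal = p[PGNAL] * (v - ena) * s[IML] * (
        (1.0 - fp) * s[IHL] + fp * s[IHLP])

    # Ito
    i_gate = vd[VD_AIF] * s[IIF] + (1.0 - vd[VD_AIF]) * s[IIS]
    ip_gate = vd[VD_AIF] * s[IIFP] + (1.0 - vd[VD_AIF]) * s[IISP]
    ito = p[PGTO] * (v - ek) * ((1.0 - fp) * s[IA] * i_gate
                                + fp * s[IAP] * ip_gate)

    # ICaL / ICaNa / ICaK
    f_gate = 0.6 * s[IFF] + 0.4 * s[IFS]
    fca = vd[VD_AFCAF] * s[IFCAF] + (1.0 - vd[VD_AFCAF]) * s[IFCAS]
    fp_gate = 0.6 * s[IFFP] + 0.4 * s[IFS]
    fcap = vd[VD_AFCAF] * s[IFCAFP] + (1.0 - vd[VD_AFCAF]) * s[IFCAS]
    nca = s[INCA]
    jca = s[IJCA]
    phical = vd[VD_GHKCA] * (cass * vd[VD_EXP2V] - 0.341 * CAO)
    phicana = vd[VD_GHKNA] * 0.75 * (nass * vd[VD_EXPV] - NAO)
    phicak = vd[VD_GHKNA] * 0.75 * (kss * vd[VD_EXPV] - KO)
    pca = p[PPCA]
    pcap = 1.1 * pca
    gate_np = s[ID] * (f_gate * (1.0 - nca) + jca * fca * nca)
    gate_p = s[ID] * (fp_gate * (1.0 - nca) + jca * fcap * nca)
    ical = (1.0 - fp) * pca * phical * gate_np + fp * pcap * phical * gate_p
    icana = ((1.0 - fp) * 0.00125 * pca * phicana * gate_np
             + fp * 0.00125 * pcap * phicana * gate_p)
    icak = ((1.0 - fp) * 3.574e-4 * pca * phicak * gate_np
            + fp * 3.574e-4 * pcap * phicak * gate_p)

    # IKr
    xr = vd[VD_AXRF] * s[IXRF] + (1.0 - vd[VD_AXRF]) * s[IXRS]
    ikr = p[PGKR] * np.sqrt(KO / 5.4) * xr * vd[VD_RKR] * (v - ek)

    # IKs
    iks = p[PGKS] * slow[3] * s[IXS1] * s[IXS2] * (v - eks)

    # IK1
    ik1 = p[PGK1] * np.sqrt(KO) * vd[VD_RK1] * s[IXK1] * (v - ek)

    # INaCa (myoplasmic and subspace components)
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    hca = vd[VD_HCA]
    hna = vd[VD_HNA]
    gncx = p[PGNCX]
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
    xs = x1 + x2 + x3 + x4
    e1 = x1 / xs
    e2 = x2 / xs
    e3 = x3 / xs
    e4 = x4 / xs
    allo = 1.0 / (1.0 + (150.0e-6 / cai) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    inaca_i = 0.8 * gncx * allo * (jncxna + 2.0 * jncxca)
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
    xs = x1 + x2 + x3 + x4
    e1 = x1 / xs
    e2 = x2 / xs
    e3 = x3 / xs
    e4 = x4 / xs
    allo = 1.0 / (1.0 + (150.0e-6 / cass) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    inaca_ss = 0.2 * gncx * allo * (jncxna + 2.0 * jncxca)

    # INaK
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    knai = vd[VD_KNAI]
    knao = vd[VD_KNAO]
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = 9.8
    kmgatp = 1.698e-7
    hh = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    pp = ep / (1.0 + hh / khp + nai / knap + ki / kxkur)
    t_nai = nai / knai
    t_nao = NAO / knao
    d_i = (1.0 + t_nai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0
    d_o = (1.0 + t_nao) ** 3 + (1.0 + KO / kko) ** 2 - 1.0
    a1 = k1p * t_nai * t_nai * t_nai / d_i
    b1 = k1m * mgadp
    a2 = k2p
    b2 = k2m * t_nao * t_nao * t_nao / d_o
    a3 = k3p_ * (KO / kko) * (KO / kko) / d_o
    b3 = k3m * pp * hh / (1.0 + mgatp / kmgatp)
    a4 = k4p_ * mgatp / kmgatp / (1.0 + mgatp / kmgatp)
    b4 = k4m * (ki / kki) * (ki / kki) / d_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    xs = x1 + x2 + x3 + x4
    e1 = x1 / xs
    e2 = x2 / xs
    e3 = x3 / xs
    e4 = x4 / xs
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    inak = p[PPNAK] * (jnakna + jnakk)

    # background and pump currents
    ikb = p[PGKB] * vd[VD_XKB] * (v - ek)
    inab = p[PPNAB] * vd[VD_GHKNA] * (nai * vd[VD_EXPV] - NAO)
    icab = p[PPCAB] * vd[VD_GHKCA] * (cai * vd[VD_EXP2V] - 0.341 * CAO)
    ipca = p[PGPCA] * cai / (0.0005 + cai)

    # membrane potential
    ds[IV] = -(ina + inal + ito + ical + icana + icak + ikr + iks + ik1
               + inaca_i + inaca_ss + inak + inab + icab + ipca + ikb + ist)

    # diffusion fluxes
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiff = (cass - cai) / 0.2

    # SR release
    bt = 4.75
    a_rel = 0.5 * bt
    denom = 1.0 + (1.5 / cajsr) ** 8
    jrel_inf = p[PJRELSC] * a_rel * (-ical) / denom
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    ds[IJRELNP] = (jrel_inf - s[IJRELNP]) / tau_rel
    btp = 1.25 * bt
    jrel_infp = p[PJRELSC] * 0.5 * btp * (-ical) / denom
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    ds[IJRELP] = (jrel_infp - s[IJRELP]) / tau_relp
    jrel = (1.0 - fp) * s[IJRELNP] + fp * s[IJRELP]

    # SR uptake and translocation
    jupnp = p[PJUPSC] * 0.004375 * cai / (cai + 0.00092)
    jupp = p[PJUPSC] * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0039375 * cansr / 15.0
    jup = (1.0 - fp) * jupnp + fp * jupp - jleak
    jtr = (cansr - cajsr) / 100.0

    # ionic concentrations
    ds[INAI] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab)
                * ACAP / (F * VMYO) + jdiffna * VSS / VMYO)
    ds[INASS] = (-(icana + 3.0 * inaca_ss) * ACAP / (F * VSS) - jdiffna)
    ds[IKI] = (-(ito + ikr + iks + ik1 + ikb + ist - 2.0 * inak)
               * ACAP / (F * VMYO) + jdiffk * VSS / VMYO)
    ds[IKSS] = -icak * ACAP / (F * VSS) - jdiffk

    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    bsrmax = 0.047
    kmbsr = 0.00087
    bslmax = 1.124
    kmbsl = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    bcai = 1.0 / (1.0 + p[PCMDN] * kmcmdn / ((kmcmdn + cai) * (kmcmdn + cai))
                  + trpnmax * kmtrpn / ((kmtrpn + cai) * (kmtrpn + cai)))
    ds[ICAI] = bcai * (-(ipca + icab - 2.0 * inaca_i) * ACAP / (2.0 * F * VMYO)
                       - jup * VNSR / VMYO + jdiff * VSS / VMYO)
    bcass = 1.0 / (1.0 + bsrmax * kmbsr / ((kmbsr + cass) * (kmbsr + cass))
                   + bslmax * kmbsl / ((kmbsl + cass) * (kmbsl + cass)))
    ds[ICASS] = bcass * (-(ical - 2.0 * inaca_ss) * ACAP / (2.0 * F * VSS)
                         + jrel * VJSR / VSS - jdiff)
    ds[ICANSR] = jup - jtr * VJSR / VNSR
    bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn
                    / ((kmcsqn + cajsr) * (kmcsqn + cajsr)))
    ds[ICAJSR] = bcajsr * (jtr - jrel)

    # gating variables (inf - x) / tau form
    ds[IM] = (vd[VD_MSS] - s[IM]) / vd[VD_TM]
    ds[IHF] = (vd[VD_HSS] - s[IHF]) / vd[VD_THF]
    ds[IHS] = (vd[VD_HSS] - s[IHS]) / vd[VD_THS]
    ds[IJ] = (vd[VD_HSS] - s[IJ]) / vd[VD_TJ]
    ds[IHSP] = (vd[VD_HSSP] - s[IHSP]) / (3.0 * vd[VD_THS])
    ds[IJP] = (vd[VD_HSS] - s[IJP]) / (1.46 * vd[VD_TJ])
    ds[IML] = (vd[VD_MLSS] - s[IML]) / vd[VD_TM]
    ds[IHL] = (vd[VD_HLSS] - s[IHL]) / 200.0
    ds[IHLP] = (vd[VD_HLSSP] - s[IHLP]) / 600.0
    depi = 1.0 + p[PISEPI] * (vd[VD_DELTAEPI] - 1.0)
    tif = vd[VD_TIF] * depi
    tis = vd[VD_TIS] * depi
    ds[IA] = (vd[VD_ASS] - s[IA]) / vd[VD_TA]
    ds[IIF] = (vd[VD_ISS] - s[IIF]) / tif
    ds[IIS] = (vd[VD_ISS] - s[IIS]) / tis
    ds[IAP] = (vd[VD_ASSP] - s[IAP]) / vd[VD_TA]
    dti = vd[VD_DTIDEV] * vd[VD_DTIREC]
    ds[IIFP] = (vd[VD_ISS] - s[IIFP]) / (dti * tif)
    ds[IISP] = (vd[VD_ISS] - s[IISP]) / (dti * tis)
    ds[ID] = (vd[VD_DSS] - s[ID]) / vd[VD_TD]
    ds[IFF] = (vd[VD_FSS] - s[IFF]) / vd[VD_TFF]
    ds[IFS] = (vd[VD_FSS] - s[IFS]) / vd[VD_TFS]
    ds[IFCAF] = (vd[VD_FSS] - s[IFCAF]) / vd[VD_TFCAF]
    ds[IFCAS] = (vd[VD_FSS] - s[IFCAS]) / vd[VD_TFCAS]
    ds[IJCA] = (vd[VD_FSS] - s[IJCA]) / 75.0
    ds[IFFP] = (vd[VD_FSS] - s[IFFP]) / (2.5 * vd[VD_TFF])
    ds[IFCAFP] = (vd[VD_FSS] - s[IFCAFP]) / (2.5 * vd[VD_TFCAF])
    km2n = jca  # 1/ms
    t4 = (1.0 + 0.002 / cass)
    t4 = t4 * t4
    t4 = t4 * t4
    anca = 1.0 / (1000.0 / km2n + t4) if km2n > 0.0 else 0.0
    ds[INCA] = anca * 1000.0 - s[INCA] * km2n
    ds[IXRF] = (vd[VD_XRSS] - s[IXRF]) / vd[VD_TXRF]
    ds[IXRS] = (vd[VD_XRSS] - s[IXRS]) / vd[VD_TXRS]
    ds[IXS1] = (vd[VD_XS1SS] - s[IXS1]) / vd[VD_TXS1]
    ds[IXS2] = (vd[VD_XS1SS] - s[IXS2]) / vd[VD_TXS2]
    ds[IXK1] = (vd[VD_XK1SS] - s[IXK1]) / vd[VD_TXK1]


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _lookup(table, vmin, inv_dv, v, vd):
    x = (v - vmin) * inv_dv
    i = int(x)
    if i < 0:
        i = 0
        x = 0.0
    elif i >= table.shape[0] - 1:
        i = table.shape[0] - 2
        x = float(table.shape[0] - 1)
    w = x - i
    row0 = table[i]
    row1 = table[i + 1]
    for k in range(N_VDEP):
        vd[k] = row0[k] + w * (row1[k] - row0[k])


@njit(cache=True, fastmath=True, error_model="numpy")
def integrate_euler(state, params, table, vmin, inv_dv, use_table,
                    dt, duration, t0, stim_times, stim_dur, stim_amp,
                    rec_stride, rec_t, rec_v, rec_cai):
    """Fixed-step forward Euler integration.

    ``state`` is advanced in place over ``duration`` ms starting at absolute
    time ``t0``.  ``stim_times`` holds sorted absolute stimulus onset times.
    Every ``rec_stride``-th sample (including the initial one) is written to
    the ``rec_*`` arrays.  Returns (status, n_recorded, t_fail) where status
    0 means success and 1 a numerical blow-up.
    """
    n_steps = int(round(duration / dt))
    vd = np.empty(N_VDEP)
    ds = np.empty(N_STATES)
    slow = np.empty(4)
    n_rec = 0
    stim_idx = 0
    n_stim = stim_times.shape[0]
    for k in range(n_steps):
        t = t0 + k * dt
        if k % rec_stride == 0:
            rec_t[n_rec] = t
            rec_v[n_rec] = state[IV]
            rec_cai[n_rec] = state[ICAI]
            n_rec += 1
        while stim_idx < n_stim and t >= stim_times[stim_idx] + stim_dur:
            stim_idx += 1
        ist = 0.0
        if stim_idx < n_stim and t >= stim_times[stim_idx]:
            ist = stim_amp
        v = state[IV]
        if not (-500.0 < v < 500.0) or v != v:
            return 1, n_rec, t
        if use_table:
            _lookup(table, vmin, inv_dv, v, vd)
        else:
            _vdep(v, vd)
        if k % 16 == 0:
            _slow_terms(state, slow)
        _rhs(state, vd, params, ist, slow, ds)
        for i in range(N_STATES):
            state[i] += dt * ds[i]
    # final sample
    rec_t[n_rec] = t0 + n_steps * dt
    rec_v[n_rec] = state[IV]
    rec_cai[n_rec] = state[ICAI]
    n_rec += 1
    return 0, n_rec, 0.0


# gate indices and their (inf, tau) table columns for Rush-Larsen updates;
# tau scale factors handle gates sharing a tabulated time constant.
_RL_GATES = np.array([
    (IM, VD_MSS, VD_TM, 1.0),
    (IHF, VD_HSS, VD_THF, 1.0),
    (IHS, VD_HSS, VD_THS, 1.0),
    (IJ, VD_HSS, VD_TJ, 1.0),
    (IHSP, VD_HSSP, VD_THS, 3.0),
    (IJP, VD_HSS, VD_TJ, 1.46),
    (IML, VD_MLSS, VD_TM, 1.0),
    (IA, VD_ASS, VD_TA, 1.0),
    (IAP, VD_ASSP, VD_TA, 1.0),
    (ID, VD_DSS, VD_TD, 1.0),
    (IFF, VD_FSS, VD_TFF, 1.0),
    (IFS, VD_FSS, VD_TFS, 1.0),
    (IFCAF, VD_FSS, VD_TFCAF, 1.0),
    (IFCAS, VD_FSS, VD_TFCAS, 1.0),
    (IFFP, VD_FSS, VD_TFF, 2.5),
    (IFCAFP, VD_FSS, VD_TFCAF, 2.5),
    (IXRF, VD_XRSS, VD_TXRF, 1.0),
    (IXRS, VD_XRSS, VD_TXRS, 1.0),
    (IXS1, VD_XS1SS, VD_TXS1, 1.0),
    (IXS2, VD_XS1SS, VD_TXS2, 1.0),
    (IXK1, VD_XK1SS, VD_TXK1, 1.0),
])


@njit(cache=True, fastmath=True, error_model="numpy")
def integrate_hybrid(state, params, table, vmin, inv_dv,
                     dt_fast, dt_slow, duration, t0,
                     stim_times, stim_dur, stim_amp,
                     rec_dt, rec_t, rec_v, rec_cai, rl_gates):
    """Rush-Larsen / forward Euler hybrid with a two-level adaptive step.

    Gates listed in ``rl_gates`` advance with the unconditionally stable
    exponential (Rush-Larsen) update; the remaining states use Euler.  The
    fast step is taken during stimulus and rapid membrane motion
    (|dV/dt| > 0.2 mV/ms), the slow step otherwise.  Samples are recorded
    every ``rec_dt`` ms.  Not suitable for afterdepolarization decisions;
    use ``integrate_euler`` there.
    """
    vd = np.empty(N_VDEP)
    ds = np.empty(N_STATES)
    slow = np.empty(4)
    n_rec = 0
    stim_idx = 0
    n_stim = stim_times.shape[0]
    t = t0
    t_end = t0 + duration
    next_rec = t0
    n_gates = rl_gates.shape[0]
    depi_scale = params[PISEPI]
    dvdt = 0.0
    while t < t_end - 1e-9:
        if t >= next_rec - 1e-9:
            rec_t[n_rec] = t
            rec_v[n_rec] = state[IV]
            rec_cai[n_rec] = state[ICAI]
            n_rec += 1
            next_rec += rec_dt
        while stim_idx < n_stim and t >= stim_times[stim_idx] + stim_dur:
            stim_idx += 1
        ist = 0.0
        stim_soon = False
        if stim_idx < n_stim:
            if t >= stim_times[stim_idx]:
                ist = stim_amp
                stim_soon = True
            elif stim_times[stim_idx] - t < dt_slow:
                stim_soon = True
        # three-level step.  The membrane equation and the Ca subsystem stay
        # explicit Euler, so (a) the upstroke needs a near-gold-standard
        # step to keep fast-sodium influx unbiased over long trains, and
        # (b) phases with active Ca cycling need a small step: SR release is
        # explosively sensitive to junctional SR load, and large steps there
        # destabilize heavily loaded cells.
        if stim_soon or abs(dvdt) > 10.0:
            dt = 0.001
        elif abs(dvdt) > 0.2 or state[ICASS] > 2.5e-4:
            dt = dt_fast
        else:
            dt = dt_slow
        if t + dt > next_rec:
            dt = next_rec - t
        if t + dt > t_end:
            dt = t_end - t
        if dt <= 0.0:
            dt = dt_fast
        v = state[IV]
        if not (-500.0 < v < 500.0) or v != v:
            return 1, n_rec, t
        _lookup(table, vmin, inv_dv, v, vd)
        _slow_terms(state, slow)
        _rhs(state, vd, params, ist, slow, ds)
        for g in range(n_gates):
            idx = int(rl_gates[g, 0])
            inf = vd[int(rl_gates[g, 1])]
            tau = vd[int(rl_gates[g, 2])] * rl_gates[g, 3]
            if idx == IIF or idx == IIS or idx == IIFP or idx == IISP:
                continue
            state[idx] = inf + (state[idx] - inf) * np.exp(-dt / tau)
            ds[idx] = 0.0
        # Ito inactivation gates need the epi/CaMK tau corrections, handle
        # them explicitly
        depi = 1.0 + depi_scale * (vd[VD_DELTAEPI] - 1.0)
        tif = vd[VD_TIF] * depi
        tis = vd[VD_TIS] * depi
        dti = vd[VD_DTIDEV] * vd[VD_DTIREC]
        state[IIF] = vd[VD_ISS] + (state[IIF] - vd[VD_ISS]) * np.exp(-dt / tif)
        state[IIS] = vd[VD_ISS] + (state[IIS] - vd[VD_ISS]) * np.exp(-dt / tis)
        state[IIFP] = vd[VD_ISS] + (state[IIFP] - vd[VD_ISS]) * np.exp(
            -dt / (dti * tif))
        state[IISP] = vd[VD_ISS] + (state[IISP] - vd[VD_ISS]) * np.exp(
            -dt / (dti * tis))
        ds[IIF] = 0.0
        ds[IIS] = 0.0
        ds[IIFP] = 0.0
        ds[IISP] = 0.0
        # remaining Euler states
        for i in range(N_STATES):
            state[i] += dt * ds[i]
        dvdt = ds[IV]
        t += dt
    rec_t[n_rec] = t_end
    rec_v[n_rec] = state[IV]
    rec_cai[n_rec] = state[ICAI]
    n_rec += 1
    return 0, n_rec, 0.0
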