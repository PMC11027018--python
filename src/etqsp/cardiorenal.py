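"""Reduced cardiorenal physiology: hemodynamics, filtration, Na/water balance.

The kidney is a single preafferent resistance feeding N identical nephrons
(afferent, efferent, peritubular resistances in series).  Glomerular
filtration follows the Starling balance ``SNGFR = K_f (P_glom - P_bowman -
pi_avg)`` with the capillary-average oncotic pressure approximated as
``pi_in (1 + FF)``, a linear filtration-fraction correction.  Filtered sodium
is reabsorbed sequentially in the proximal tubule, loop of Henle, distal
convoluted tubule, and collecting duct; fractional lithium excretion is
modelled as ``1 - eta_PT`` (lithium as a pure proximal marker).  Volume and
sodium balance close the loop through cardiac output (linear in stressed
blood volume), mean arterial pressure (``MAP = CO x SVR``), and first-order
neurohormonal feedbacks: tubuloglomerular feedback on the afferent arteriole,
a myogenic response on the preafferent vessel, a lumped RAAS activity, ANP,
and vasopressin.  The full chronic machinery of larger cardiorenal models
(glucose handling, non-osmotic Na storage, staged RAAS biochemistry) is
deliberately omitted: the protocols of interest are acute (<= 4 h), where
only the fast feedbacks shape the response.

Endothelin enters exclusively through multiplicative effect multipliers
(one per target parameter, all exactly 1 at baseline), so a model with all
multipliers at one is bit-identical to a model without ET-1.

Units: pressures mmHg, flows L/min, resistances mmHg.min/L, Na mmol,
volumes L, time min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from numba import njit
from scipy.integrate import odeint
from scipy.optimize import root

from .effects import TARGETS
from .kinetics import SimulationError

# state vector layout
CR_IDX = {
    "blood_volume": 0,
    "interstitial_volume": 1,
    "Na_ecf": 2,          # exchangeable sodium of the osmotic pool, mmol
    "raas": 3,            # normalized hormone activities (1 at baseline)
    "anp": 4,
    "adh": 5,
    "tgf": 6,             # afferent TGF resistance multiplier state
    "myo": 7,             # preafferent myogenic multiplier state
    "cum_UNaV": 8,        # bookkeeping integrals
    "cum_Na_in": 9,
    "cum_urine": 10,
    "cum_water_in": 11,
}
N_CR = 12

# output vector layout of the algebra kernel
OUT_IDX = {
    "MAP": 0, "CO": 1, "RBF": 2, "RPF": 3, "GFR": 4, "P_glom": 5,
    "urine_flow": 6, "UNaV": 7, "eta_PT_eff": 8, "plasma_Na": 9,
    "clamp_flag": 10, "Phi_md": 11,
}
N_OUT = 12

_ONES8 = np.ones(8)
_EMPTY_F = np.zeros(0)
_EMPTY_I = np.zeros(0, dtype=np.int64)
_NO_WATER = (np.zeros(1), np.zeros(1), np.zeros(1))
_FLAT_OCC = (np.array([0.0, 1.0]), np.zeros((4, 2)))


@dataclass
class CardiorenalParams:
    """Parameters of the reduced cardiorenal model.

    Vascular resistances are lumped whole-kidney values; the per-nephron
    afferent/efferent resistance is the lumped value times ``N_nephrons``
    and the per-nephron ultrafiltration coefficient is ``K_f / N_nephrons``.
    """

    # renal vascular network (whole-kidney lumped)
    R_preafferent: float
    R_afferent: float
    R_efferent: float
    R_peritubular: float
    N_nephrons: float
    K_f: float               # L/min/mmHg, whole kidney
    P_bowman: float          # mmHg
    P_renal_vein: float      # mmHg
    pi_in: float             # afferent-end plasma oncotic pressure, mmHg
    hematocrit: float
    # tubule
    eta_PT: float
    eta_LoH: float
    eta_DCT: float
    eta_CD: float
    fw0: float               # baseline excreted fraction of post-PT water
    s_adh: float             # log-sensitivity of water excretion to vasopressin
    fw_max: float            # ceiling on the excreted water fraction
    # systemic circulation
    SVR_nominal: float
    CO_nominal: float
    co_volume_gain: float    # dCO/CO per d(stressed volume)/stressed volume
    blood_volume0: float
    interstitial_volume0: float   # non-plasma dilution water (osmotic pool)
    venous_capacitance: float   # unstressed venous volume, L
    venous_compliance: float    # scales (divides) the CO volume gain
    # intake
    Na_intake: float         # mmol/day
    water_intake: float      # L/min
    plasma_Na0: float        # mmol/L
    # feedback gains / time constants (min)
    G_tgf: float = 2.0
    tau_tgf: float = 3.0
    tgf_lo: float = 0.3
    tgf_hi: float = 2.2
    G_myo: float = 1.0
    tau_myo: float = 2.0
    myo_lo: float = 0.5
    myo_hi: float = 2.0
    G_raas_map: float = 3.0
    G_raas_md: float = 1.5
    tau_raas: float = 30.0
    g_raas_svr: float = 0.2
    g_raas_dct: float = 0.3
    g_raas_pt: float = 0.05
    G_anp: float = 5.0
    tau_anp: float = 15.0
    g_anp_cd: float = 1.5
    G_adh: float = 10.0
    tau_adh: float = 20.0
    g_pn_cd: float = 2.0     # pressure-natriuresis gain on collecting duct
    k_exchange: float = 0.3  # blood<->interstitium equilibration, 1/min
    map_offset: float = 0.0   # additive MAP perturbation (autoregulation tests)
    MAP0: float = 93.0
    Phi_md0: float = 1.0      # baseline macula densa Na delivery, mmol/min
    min_urine: float = 5e-5   # L/min floor
    weight_kg: float = 70.0

    def __post_init__(self):
        for name in ["R_preafferent", "R_afferent", "R_efferent",
                     "R_peritubular", "N_nephrons", "K_f", "SVR_nominal",
                     "CO_nominal", "blood_volume0", "interstitial_volume0"]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ["eta_PT", "eta_LoH", "eta_DCT", "eta_CD", "fw0", "fw_max"]:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")

    @property
    def Na_intake_mmol_min(self) -> float:
        return self.Na_intake / 1440.0

    @property
    def R_afferent_per_nephron(self) -> float:
        return self.R_afferent * self.N_nephrons

    @property
    def K_f_per_nephron(self) -> float:
        return self.K_f / self.N_nephrons

    def to_dict(self) -> dict:
        return asdict(self)

    def _array(self) -> np.ndarray:
        return np.array([
            self.R_preafferent, self.R_afferent, self.R_efferent,
            self.R_peritubular, self.K_f, self.P_bowman, self.P_renal_vein,
            self.pi_in, self.hematocrit,
            self.eta_PT, self.eta_LoH, self.eta_DCT, self.eta_CD,
            self.fw0, self.s_adh, self.fw_max,
            self.SVR_nominal, self.CO_nominal, self.co_volume_gain,
            self.blood_volume0, self.interstitial_volume0,
            self.venous_capacitance, self.venous_compliance,
            self.plasma_Na0, self.Na_intake_mmol_min, self.water_intake,
            self.G_tgf, self.tau_tgf, self.tgf_lo, self.tgf_hi,
            self.G_myo, self.tau_myo, self.myo_lo, self.myo_hi,
            self.G_raas_map, self.G_raas_md, self.tau_raas,
            self.g_raas_svr, self.g_raas_dct, self.g_raas_pt,
            self.G_anp, self.tau_anp, self.g_anp_cd,
            self.G_adh, self.tau_adh, self.g_pn_cd,
            self.k_exchange, self.map_offset, self.MAP0, self.Phi_md0,
            self.min_urine,
        ])

    @classmethod
    def reference(cls, *,
                  MAP0: float = 93.0, GFR0_ml_min: float = 120.0,
                  RBF0: float = 1.1, CO0: float = 5.0,
                  plasma_Na0: float = 140.0, Na_intake: float = 150.0,
                  water_intake_ml_min: float = 1.0,
                  urine0_ml_min: float = 1.0,
                  frac_pre: float = 0.22, frac_aff: float = 0.26,
                  frac_eff: float = 0.43,
                  eta_PT: float = 0.70, eta_LoH: float = 0.75,
                  eta_DCT: float = 0.60,
                  pi_in: float = 25.7, P_bowman: float = 10.0,
                  P_renal_vein: float = 4.0, hematocrit: float = 0.45,
                  **overrides) -> "CardiorenalParams":
        """Healthy-human reference set, derived so the nominal operating
        point (MAP 93 mmHg, GFR 120 mL/min, RBF 1.1 L/min, plasma Na
        140 mmol/L) is an exact steady state: K_f, eta_CD and eta_dw are
        solved from the targets rather than quoted."""
        GFR0 = GFR0_ml_min / 1000.0
        urine0 = urine0_ml_min / 1000.0
        R_tot = (MAP0 - P_renal_vein) / RBF0
        R_pre, R_aff, R_eff = (frac_pre * R_tot, frac_aff * R_tot,
                               frac_eff * R_tot)
        R_peri = R_tot - R_pre - R_aff - R_eff
        RPF0 = RBF0 * (1.0 - hematocrit)
        P_glom0 = MAP0 - RBF0 * (R_pre + R_aff)
        dP = P_glom0 - P_bowman
        K_f = GFR0 / (dP - pi_in - pi_in * GFR0 / RPF0)
        if K_f <= 0:
            raise ValueError("reference targets imply non-positive K_f")
        phi_filt = GFR0 * plasma_Na0
        intake_mmol_min = Na_intake / 1440.0
        upstream = phi_filt * (1 - eta_PT) * (1 - eta_LoH) * (1 - eta_DCT)
        eta_CD = 1.0 - intake_mmol_min / upstream
        if not 0 < eta_CD < 1:
            raise ValueError("reference targets imply eta_CD outside (0, 1)")
        fw0 = urine0 / (GFR0 * (1 - eta_PT))
        Phi_md0 = phi_filt * (1 - eta_PT) * (1 - eta_LoH)
        kwargs = dict(
            R_preafferent=R_pre, R_afferent=R_aff, R_efferent=R_eff,
            R_peritubular=R_peri, N_nephrons=2e6, K_f=K_f,
            P_bowman=P_bowman, P_renal_vein=P_renal_vein, pi_in=pi_in,
            hematocrit=hematocrit,
            eta_PT=eta_PT, eta_LoH=eta_LoH, eta_DCT=eta_DCT, eta_CD=eta_CD,
            fw0=fw0, s_adh=8.0, fw_max=0.6,
            SVR_nominal=MAP0 / CO0, CO_nominal=CO0, co_volume_gain=1.0,
            blood_volume0=5.0, interstitial_volume0=39.0,
            venous_capacitance=0.5, venous_compliance=1.0,
            Na_intake=Na_intake, water_intake=water_intake_ml_min / 1000.0,
            plasma_Na0=plasma_Na0, MAP0=MAP0, Phi_md0=Phi_md0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class CardiorenalState:
    """Slow states of the cardiorenal model."""

    blood_volume: float
    interstitial_volume: float
    Na_ecf: float
    raas: float = 1.0
    anp: float = 1.0
    adh: float = 1.0
    tgf: float = 1.0
    myo: float = 1.0
    cum_UNaV: float = 0.0
    cum_Na_in: float = 0.0
    cum_urine: float = 0.0
    cum_water_in: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in CR_IDX])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CardiorenalState":
        return cls(**{k: float(y[i]) for k, i in CR_IDX.items()})

    def plasma_Na(self, params: CardiorenalParams) -> float:
        v_ecf = (self.blood_volume * (1 - params.hematocrit)
                 + self.interstitial_volume)
        return self.Na_ecf / v_ecf

    def validate(self, params: CardiorenalParams) -> None:
        if self.blood_volume <= 0 or self.interstitial_volume <= 0:
            raise ValueError("volumes must be positive")
        na = self.plasma_Na(params)
        if not 120.0 <= na <= 160.0:
            raise ValueError(f"plasma Na {na:.1f} mmol/L outside [120, 160]")


class EffectMultipliers(dict):
    """Per-target multiplicative modifiers; 1.0 everywhere at baseline."""

    def __init__(self, values: dict[str, float] | None = None):
        super().__init__({t: 1.0 for t in TARGETS})
        for k, v in (values or {}).items():
            if k not in TARGETS:
                raise ValueError(f"unknown effect target {k!r}")
            if v < 0:
                raise ValueError("effect multipliers must be >= 0")
            self[k] = float(v)

    def as_array(self) -> np.ndarray:
        return np.array([self[t] for t in TARGETS])


@njit(cache=True)
def _cr_algebra(t, y, cp, base_E,
                occ_t, occ4,
                m_target, m_sig, m_form, m_m, m_b, m_occ0,
                wat_t0, wat_t1, wat_rate, match_urine):
    """Derivatives and instantaneous outputs of the cardiorenal model.

    ``occ4`` holds the four occupancy drive signals (ET_A tissue, ET_B
    tissue, ET_A plasma, ET_B plasma) sampled on ``occ_t``; the ``m_*``
    arrays describe active mechanisms (target index in effect order, signal
    index, form 0=linear/1=sigmoidal, slope, steepness, baseline occupancy).
    """
    (R_pre0, R_aff0, R_eff0, R_peri, Kf, P_bow, P_rv, pi_in, hct) = (
        cp[0], cp[1], cp[2], cp[3], cp[4], cp[5], cp[6], cp[7], cp[8])
    eta_PT, eta_LoH, eta_DCT, eta_CD = cp[9], cp[10], cp[11], cp[12]
    fw0, s_adh, fw_max = cp[13], cp[14], cp[15]
    SVR_nom, CO0, s_co = cp[16], cp[17], cp[18]
    V_b0, V_is0, V_u0, vcomp = cp[19], cp[20], cp[21], cp[22]
    Na0, Na_in_rate, water_base = cp[23], cp[24], cp[25]
    G_tgf, tau_tgf, tgf_lo, tgf_hi = cp[26], cp[27], cp[28], cp[29]
    G_myo, tau_myo, myo_lo, myo_hi = cp[30], cp[31], cp[32], cp[33]
    G_rmap, G_rmd, tau_raas = cp[34], cp[35], cp[36]
    g_rsvr, g_rdct, g_rpt = cp[37], cp[38], cp[39]
    G_anp, tau_anp, g_anp_cd = cp[40], cp[41], cp[42]
    G_adh, tau_adh, g_pn = cp[43], cp[44], cp[45]
    k_ex, map_off, MAP0, Phi_md0, min_urine = cp[46], cp[47], cp[48], cp[49], cp[50]

    # --- effect multipliers ------------------------------------------------
    E = base_E.copy()
    if m_m.shape[0] > 0:
        occ_now = np.empty(4)
        for s in range(4):
            occ_now[s] = np.interp(t, occ_t, occ4[s])
        for j in range(m_m.shape[0]):
            d = occ_now[m_sig[j]] - m_occ0[j]
            if m_form[j] == 0:
                e = 1.0 + m_m[j] * d
                if e < 0.0:
                    e = 0.0
            else:
                x = d / m_b[j]
                if x > 700.0:
                    e = 1.0 - m_m[j] / 2.0
                elif x < -700.0:
                    e = 1.0 + m_m[j] / 2.0
                else:
                    e = 1.0 + m_m[j] / (1.0 + np.exp(x)) - m_m[j] / 2.0
            E[m_target[j]] *= e

    V_b, V_is, Na_ecf = y[0], y[1], y[2]
    a_raas, a_anp, a_adh, tgf, myo = y[3], y[4], y[5], y[6], y[7]

    V_ecf = V_b * (1.0 - hct) + V_is
    C_Na = Na_ecf / V_ecf

    # --- systemic circulation ----------------------------------------------
    V_u = V_u0 * E[6]                       # venous capacitance target
    V_s0 = V_b0 - V_u0
    V_s = V_b - V_u
    CO = CO0 * (1.0 + s_co * (V_s / V_s0 - 1.0) / (vcomp * E[7]))
    if CO < 0.5:
        CO = 0.5
    SVR_eff = SVR_nom * E[3] * (1.0 + g_rsvr * (a_raas - 1.0))
    MAP = CO * SVR_eff + map_off

    # --- renal vascular network --------------------------------------------
    R_pre = R_pre0 * myo * E[0]
    R_aff = R_aff0 * tgf * E[1]
    R_eff = R_eff0 * E[2]
    R_tot = R_pre + R_aff + R_eff + R_peri
    RBF = (MAP - P_rv) / R_tot
    if RBF < 1e-6:
        RBF = 1e-6
    RPF = RBF * (1.0 - hct)
    P_glom = MAP - RBF * (R_pre + R_aff)

    # --- glomerular filtration (Starling, pi_avg = pi_in (1 + FF)) ----------
    clamp_flag = 0.0
    net = P_glom - P_bow - pi_in
    GFR = Kf * net / (1.0 + Kf * pi_in / RPF)
    if GFR <= 0.0:
        GFR = 0.0
        clamp_flag = 1.0

    # --- segmental sodium handling ------------------------------------------
    eta_pt_eff = eta_PT * E[4] * (1.0 + g_rpt * (a_raas - 1.0))
    if eta_pt_eff > 0.999:
        eta_pt_eff = 0.999
    if eta_pt_eff < 0.0:
        eta_pt_eff = 0.0
    eta_dct_eff = eta_DCT * (1.0 + g_rdct * (a_raas - 1.0))
    if eta_dct_eff > 0.999:
        eta_dct_eff = 0.999
    if eta_dct_eff < 0.0:
        eta_dct_eff = 0.0
    eta_cd_eff = (eta_CD * E[5]
                  * (1.0 - g_anp_cd * (a_anp - 1.0))
                  * (1.0 - g_pn * (MAP / MAP0 - 1.0)))
    if eta_cd_eff > 0.999:
        eta_cd_eff = 0.999
    if eta_cd_eff < 0.0:
        eta_cd_eff = 0.0

    phi_filt = GFR * C_Na
    phi_pt = phi_filt * (1.0 - eta_pt_eff)
    phi_md = phi_pt * (1.0 - eta_LoH)
    phi_dct = phi_md * (1.0 - eta_dct_eff)
    UNaV = phi_dct * (1.0 - eta_cd_eff)

    # --- water handling ------------------------------------------------------
    # vasopressin sets the excreted fraction of post-proximal water on a log
    # scale; suppression (water loading) can raise it ~20-fold up to fw_max
    fw = fw0 * np.exp(s_adh * (1.0 - a_adh))
    if fw > fw_max:
        fw = fw_max
    urine = GFR * (1.0 - eta_pt_eff) * fw
    if urine < min_urine:
        urine = min_urine

    water_in = water_base
    for i in range(wat_t0.shape[0]):
        if wat_t0[i] <= t < wat_t1[i]:
            water_in += wat_rate[i]
    if match_urine == 1:
        water_in += urine

    # --- feedback targets -----------------------------------------------------
    tgf_t = 1.0 + G_tgf * (phi_md / Phi_md0 - 1.0)
    if tgf_t < tgf_lo:
        tgf_t = tgf_lo
    if tgf_t > tgf_hi:
        tgf_t = tgf_hi
    myo_t = 1.0 + G_myo * (MAP / MAP0 - 1.0)
    if myo_t < myo_lo:
        myo_t = myo_lo
    if myo_t > myo_hi:
        myo_t = myo_hi
    raas_t = 1.0 - G_rmap * (MAP / MAP0 - 1.0) - G_rmd * (phi_md / Phi_md0 - 1.0)
    if raas_t < 0.0:
        raas_t = 0.0
    anp_t = 1.0 + G_anp * (V_b / V_b0 - 1.0)
    if anp_t < 0.0:
        anp_t = 0.0
    adh_t = 1.0 + G_adh * (C_Na / Na0 - 1.0)
    if adh_t < 0.0:
        adh_t = 0.0

    J_ex = k_ex * ((V_b - V_b0) * V_is0 - (V_is - V_is0) * V_b0) / (V_b0 + V_is0)

    dy = np.empty(12)
    dy[0] = water_in - urine - J_ex
    dy[1] = J_ex
    dy[2] = Na_in_rate - UNaV
    dy[3] = (raas_t - a_raas) / tau_raas
    dy[4] = (anp_t - a_anp) / tau_anp
    dy[5] = (adh_t - a_adh) / tau_adh
    dy[6] = (tgf_t - tgf) / tau_tgf
    dy[7] = (myo_t - myo) / tau_myo
    dy[8] = UNaV
    dy[9] = Na_in_rate
    dy[10] = urine
    dy[11] = water_in

    out = np.empty(12)
    out[0] = MAP
    out[1] = CO
    out[2] = RBF
    out[3] = RPF
    out[4] = GFR
    out[5] = P_glom
    out[6] = urine
    out[7] = UNaV
    out[8] = eta_pt_eff
    out[9] = C_Na
    out[10] = clamp_flag
    out[11] = phi_md
    return dy, out


@njit(cache=True)
def _cr_rhs(t, y, cp, base_E, occ_t, occ4,
            m_target, m_sig, m_form, m_m, m_b, m_occ0,
            wat_t0, wat_t1, wat_rate, match_urine):
    dy, _ = _cr_algebra(t, y, cp, base_E, occ_t, occ4,
                        m_target, m_sig, m_form, m_m, m_b, m_occ0,
                        wat_t0, wat_t1, wat_rate, match_urine)
    return dy


@njit(cache=True)
def _cr_outputs_batch(t_arr, y_arr, cp, base_E, occ_t, occ4,
                      m_target, m_sig, m_form, m_m, m_b, m_occ0,
                      wat_t0, wat_t1, wat_rate, match_urine):
    out = np.empty((t_arr.shape[0], 12))
    for i in range(t_arr.shape[0]):
        _, o = _cr_algebra(t_arr[i], y_arr[i], cp, base_E, occ_t, occ4,
                           m_target, m_sig, m_form, m_m, m_b, m_occ0,
                           wat_t0, wat_t1, wat_rate, match_urine)
        out[i] = o
    return out


def _const_drive_args(params: CardiorenalParams,
                      multipliers: "EffectMultipliers | None" = None):
    """Kernel arguments for a run with constant multipliers and no dosing."""
    base_E = (multipliers.as_array() if multipliers is not None else _ONES8)
    occ_t, occ4 = _FLAT_OCC
    empty_i = _EMPTY_I
    empty_f = _EMPTY_F
    w0, w1, wr = _NO_WATER
    return (params._array(), base_E, occ_t, occ4,
            empty_i, empty_i, empty_i, empty_f, empty_f, empty_f,
            w0, w1, wr, 0)


def cardiorenal_derivatives(state: CardiorenalState, params: CardiorenalParams,
                            multipliers: EffectMultipliers | None = None,
                            t: float = 0.0) -> CardiorenalState:
    """Time derivative of the cardiorenal state under fixed multipliers."""
    if multipliers is not None and min(multipliers.values()) < 0:
        raise ValueError("multipliers must be non-negative")
    args = _const_drive_args(params, multipliers)
    dy = _cr_rhs(t, state.to_array(), *args)
    return CardiorenalState.from_array(dy)


def instantaneous_outputs(state: CardiorenalState, params: CardiorenalParams,
                          multipliers: EffectMultipliers | None = None,
                          t: float = 0.0) -> dict[str, float]:
    """Algebraic outputs (MAP, RBF, GFR, ...) at one state."""
    args = _const_drive_args(params, multipliers)
    _, out = _cr_algebra(t, state.to_array(), *args)
    return {k: float(out[i]) for k, i in OUT_IDX.items()}


def nominal_state(params: CardiorenalParams) -> CardiorenalState:
    v_ecf = params.blood_volume0 * (1 - params.hematocrit) + params.interstitial_volume0
    return CardiorenalState(
        blood_volume=params.blood_volume0,
        interstitial_volume=params.interstitial_volume0,
        Na_ecf=params.plasma_Na0 * v_ecf,
    )


def steady_state_initialize(params: CardiorenalParams,
                            multipliers: EffectMultipliers | None = None,
                            ) -> CardiorenalState:
    """Solve the no-perturbation steady state of the slow states.

    Raises :class:`SimulationError` naming the worst-residual equation if the
    root solve does not converge.
    """
    args = _const_drive_args(params, multipliers)
    guess = nominal_state(params).to_array()[:8]
    ref = np.maximum(np.abs(guess), 0.5)

    def f(z):
        y = np.zeros(N_CR)
        y[:8] = z * ref
        return _cr_rhs(0.0, y, *args)[:8]

    sol = root(f, guess / ref, method="hybr", tol=1e-13)
    resid = f(sol.x)
    # residuals are d/dt of each state; normalize by state scale per minute
    rel = np.abs(resid) / ref
    if rel.max() > 1e-10:
        worst = list(CR_IDX)[int(np.argmax(rel))]
        raise SimulationError(
            f"cardiorenal steady state failed to converge; worst residual in "
            f"d({worst})/dt = {resid[int(np.argmax(rel))]:.3g}")
    y = np.zeros(N_CR)
    y[:8] = sol.x * ref
    return CardiorenalState.from_array(y)


@dataclass
class CRTrajectory:
    """Raw cardiorenal trajectory plus the drive needed to recompute algebra."""

    t: np.ndarray
    y: np.ndarray
    params: CardiorenalParams
    _args: tuple = field(repr=False, default=())

    def outputs_at(self, i: int) -> np.ndarray:
        _, out = _cr_algebra(self.t[i], self.y[i], *self._args)
        return out

    def outputs(self) -> np.ndarray:
        return _cr_outputs_batch(self.t, self.y, *self._args)

    def state_at(self, i: int) -> CardiorenalState:
        return CardiorenalState.from_array(self.y[i])


def simulate_cardiorenal(params: CardiorenalParams,
                         y0: CardiorenalState,
                         t_grid: np.ndarray,
                         multipliers: EffectMultipliers | None = None,
                         occ_t: np.ndarray | None = None,
                         occ4: np.ndarray | None = None,
                         mech_arrays: tuple | None = None,
                         water_events: tuple | None = None,
                         match_urine_output: bool = False,
                         rtol: float = 1e-7, atol: float = 1e-9,
                         ) -> CRTrajectory:
    """Integrate the cardiorenal model over ``t_grid``.

    Occupancy-driven mechanisms are supplied through ``occ_t``/``occ4``
    (drive signals) and ``mech_arrays`` (packed mechanism description from
    :func:`etqsp.coupled.pack_mechanisms`).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    base_E = (multipliers.as_array() if multipliers is not None else _ONES8)
    if occ_t is None or occ4 is None:
        occ_t, occ4 = _FLAT_OCC
    if mech_arrays is None:
        mech_arrays = (_EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F)
    if water_events is None:
        water_events = _NO_WATER
    w0, w1, wr = water_events
    args = (params._array(), base_E, occ_t, np.ascontiguousarray(occ4),
            *mech_arrays, w0, w1, wr, 1 if match_urine_output else 0)
    crit = np.unique(np.concatenate([w0, w1]))
    crit = crit[(crit > t_grid[0]) & (crit < t_grid[-1])]
    y, info = odeint(_cr_rhs, y0.to_array(), t_grid, args=args, tfirst=True,
                     rtol=rtol, atol=atol, mxstep=8000,
                     tcrit=crit if crit.size else None, full_output=True)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"cardiorenal solve failed: {info['message']}")
    return CRTrajectory(t=t_grid, y=y, params=params, _args=args)


@dataclass
class ModelOutputs:
    """Tidy per-time-point output panel of a simulated study arm.

    ``FENa`` is reported as a percent of the filtered sodium load and is
    missing (NaN) wherever GFR is zero; ``FELi`` is the fractional lithium
    excretion, i.e. the fraction of filtrate escaping the proximal tubule.
    """

    time: np.ndarray
    MAP: np.ndarray          # mmHg
    RBF: np.ndarray          # L/min
    RPF: np.ndarray          # L/min
    GFR: np.ndarray          # mL/min
    RVR: np.ndarray          # mmHg.min/L
    SVR: np.ndarray          # mmHg.min/L
    urine_flow: np.ndarray   # mL/min
    UNaV: np.ndarray         # mmol/min
    FENa: np.ndarray         # %
    FELi: np.ndarray         # %
    plasma_ET1: np.ndarray   # pM
    clamp_flag: np.ndarray = field(default_factory=lambda: np.zeros(0))

    VARIABLES = ("MAP", "RBF", "RPF", "GFR", "RVR", "SVR", "urine_flow",
                 "UNaV", "FENa", "FELi", "plasma_ET1")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.VARIABLES:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self):
        """Long-format (time, variable, value) DataFrame."""
        import pandas as pd
        rows = []
        for var in self.VARIABLES:
            rows.append(pd.DataFrame(
                {"time": self.time, "variable": var, "value": self[var]}))
        return pd.concat(rows, ignore_index=True)


def compute_derived(traj: CRTrajectory,
                    plasma_ET1: np.ndarray | None = None) -> ModelOutputs:
    """Derive the measured-variable panel from a raw trajectory.

    Enforced identities: ``RVR = MAP / RBF``, ``RBF = RPF / (1 - hct)``,
    ``FENa = UNaV / (GFR * plasma_Na)``, ``FELi = 1 - eta_PT_effective``.
    """
    out = traj.outputs()
    MAP = out[:, OUT_IDX["MAP"]]
    CO = out[:, OUT_IDX["CO"]]
    RBF = out[:, OUT_IDX["RBF"]]
    RPF = out[:, OUT_IDX["RPF"]]
    GFR_L = out[:, OUT_IDX["GFR"]]
    urine = out[:, OUT_IDX["urine_flow"]]
    UNaV = out[:, OUT_IDX["UNaV"]]
    eta_pt = out[:, OUT_IDX["eta_PT_eff"]]
    C_Na = out[:, OUT_IDX["plasma_Na"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        FENa = np.where(GFR_L > 0, UNaV / (GFR_L * C_Na) * 100.0, np.nan)
    if plasma_ET1 is None:
        plasma_ET1 = np.full(len(traj.t), np.nan)
    return ModelOutputs(
        time=traj.t,
        MAP=MAP,
        RBF=RBF,
        RPF=RPF,
        GFR=GFR_L * 1000.0,
        RVR=MAP / RBF,
        SVR=MAP / CO,
        urine_flow=urine * 1000.0,
        UNaV=UNaV,
        FENa=FENa,
        FELi=(1.0 - eta_pt) * 100.0,
        plasma_ET1=np.asarray(plasma_ET1, dtype=float),
        clamp_flag=out[:, OUT_IDX["clamp_flag"]],
    )
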