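"""Cardiorespiratory feedback model driven by mu-opioid receptor occupancy.

The model closes the loop between ventilation, gas exchange and circulation:

* Three ventilatory drives -- central chemoreflex (delayed arterial CO2),
  peripheral chemoreflex (arterial CO2 with hypoxic potentiation) and a
  tonic wakefulness drive -- sum to minute ventilation.  Opioid-bound
  receptors suppress all three drives through a saturable occupancy-effect
  function; antagonist-bound receptors are silent.
* Alveolar gas balances for CO2 and O2 (conversion factor 863 mmHg between
  STPD gas exchange and BTPS alveolar ventilation), linear blood CO2
  content, Hill-type O2 content (haemoglobin saturation), and lumped tissue
  stores with metabolic CO2 production / O2 consumption.
* Circulation: an energy-like cardiac performance state that recovers while
  systemic O2 delivery exceeds a critical level and decays exponentially
  under delivery deficit.  Total blood flow is ``q0 * E``; cardiac arrest is
  the flow trace reaching 0.01 L/min, which terminates the simulation.

Severe sustained ventilation loss therefore produces hypoxaemia, delivery
deficit and circulatory collapse in minutes, while recovery of ventilation
(antagonist rescue) restores delivery and halts the decay -- the behaviour
the overdose simulations probe.

The parameter set is a pluggable, provenance-annotated bundle; the default
shipped with the package is a self-authored synthetic calibration (see
``docs/methods.md``), anchored so that the *normocapnic* baseline is an exact
fixed point at the arterial CO2 setpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import brentq


class TolerancePreset(BaseModel):
    """Occupancy-effect parameters for one population (chronic / naive)."""

    model_config = ConfigDict(extra="forbid")

    f50: float = Field(gt=0, description="occupancy giving half-maximal drive loss")
    gamma: float = Field(gt=0, description="steepness of the occupancy-effect curve")
    e_max: float = Field(default=1.0, gt=0, le=1.0)


class PhysiologyParameters(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # gas setpoints (mmHg)
    pa_co2_setpoint: float = Field(default=40.28, ge=0)
    pa_co2_hypercapnic: float = Field(default=45.30, ge=0)
    pa_co2_anchor: float = Field(default=40.28, ge=0,
                                 description="normocapnic anchor for metabolic calibration")
    pi_co2: float = Field(default=0.0, ge=0)
    pi_o2: float = Field(default=150.0, ge=0)
    # ventilatory control
    g_central: float = Field(default=1.2, gt=0, description="L/min/mmHg")
    g_peripheral: float = Field(default=0.6, gt=0, description="L/min/mmHg")
    drive_threshold: float = Field(default=37.56, gt=0, description="mmHg")
    w_drive: float = Field(default=2.1, ge=0, description="wakefulness drive (L/min)")
    tau_central: float = Field(default=180.0, gt=0, description="s")
    tau_peripheral: float = Field(default=30.0, gt=0, description="s")
    tau_wake: float = Field(default=60.0, gt=0, description="s")
    tau_delay: float = Field(default=10.0, gt=0, description="s, per delay-chain stage")
    g_hypoxic: float = Field(default=1.0, ge=0)
    hypoxic_p0: float = Field(default=25.0, gt=0, description="mmHg")
    hypoxic_scale: float = Field(default=12.0, gt=0, description="mmHg")
    chd_p50: float = Field(default=30.0, gt=0,
                           description="mmHg, central hypoxic depression midpoint")
    chd_slope: float = Field(default=5.0, gt=0, description="mmHg")
    dead_space_fraction: float = Field(default=0.3, ge=0, lt=1)
    # gas stores and transport
    vl_co2: float = Field(default=3.0, gt=0, description="L, lung CO2 store volume")
    vl_o2: float = Field(default=2.5, gt=0, description="L, lung O2 store volume")
    store_co2: float = Field(default=0.35, gt=0, description="L gas / mmHg, tissue CO2 store")
    vt_o2: float = Field(default=6.0, gt=0, description="L blood-equivalent tissue O2 store")
    beta_co2: float = Field(default=0.0065, gt=0, description="L gas/L blood/mmHg")
    hb_capacity: float = Field(default=0.197, gt=0, description="L O2 / L blood")
    o2_sol: float = Field(default=3.1e-5, gt=0, description="L O2/L blood/mmHg dissolved")
    p50: float = Field(default=26.0, gt=0, description="mmHg")
    hill_h: float = Field(default=2.7, gt=0)
    rq: float = Field(default=0.85, gt=0, description="respiratory quotient")
    vo2_km: float = Field(default=2.0, gt=0, description="mmHg, metabolism shutdown scale in deep hypoxia")
    # circulation
    q0: float = Field(default=5.0, gt=0, description="L/min, baseline cardiac output")
    do2_crit: float = Field(default=0.35, gt=0, description="L O2/min critical delivery")
    k_fail: float = Field(default=0.005, gt=0, description="1/s cardiac decay under deficit")
    k_recover: float = Field(default=0.004, gt=0, description="1/s cardiac recovery")
    e50_flow: float = Field(default=0.15, gt=0, lt=1,
                            description="performance state at half-maximal flow")
    flow_hill: float = Field(default=2.0, gt=0)
    arrest_flow_threshold: float = Field(default=0.01, gt=0, description="L/min")
    tolerance: TolerancePreset = TolerancePreset(f50=0.78, gamma=4.0)


class PhysiologyState(BaseModel):
    """Instantaneous physiological state; ventilation/flows are derived fields."""

    model_config = ConfigDict(extra="forbid")

    pa_co2: float = Field(ge=0, description="alveolar/arterial CO2 (mmHg)")
    pa_o2: float = Field(ge=0, description="alveolar/arterial O2 (mmHg)")
    pv_co2: float = Field(ge=0, description="venous/tissue CO2 (mmHg)")
    pv_o2: float = Field(ge=0, description="venous/tissue O2 (mmHg)")
    d_central: float = Field(ge=0)
    d_peripheral: float = Field(ge=0)
    d_wake: float = Field(ge=0)
    x1: float = Field(ge=0, description="CO2 transport delay stage 1 (mmHg)")
    x2: float = Field(ge=0, description="CO2 transport delay stage 2 (mmHg)")
    energy: float = Field(ge=0, le=1.0, description="cardiac performance state")
    ventilation: float = Field(ge=0, description="minute ventilation (L/min)")
    cardiac_output: float = Field(ge=0, description="L/min")
    total_flow: float = Field(ge=0, description="L/min")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.pa_co2, self.pa_o2, self.pv_co2, self.pv_o2, self.d_central,
             self.d_peripheral, self.d_wake, self.x1, self.x2, self.energy]
        )


N_STATES = 10  # length of the physiology state vector
(I_PACO2, I_PAO2, I_PVCO2, I_PVO2, I_DC, I_DP, I_DW, I_X1, I_X2, I_E) = range(N_STATES)


def drive_suppression(f_op: float, tolerance: TolerancePreset | None = None) -> np.ndarray:
    """Multipliers in [0, 1] applied to (central, peripheral, wakefulness) drives.

    The effect is a saturable Hill function of opioid occupancy; the
    population presets differ in ``f50`` (pharmacodynamic tolerance shifts the
    curve toward higher occupancies in chronic users).  Antagonist occupancy
    does not appear: antagonist-bound receptors are silent.
    """
    if not 0.0 <= f_op <= 1.0:
        raise ValueError("opioid occupancy must lie in [0, 1]")
    tol = tolerance or TolerancePreset(f50=0.78, gamma=4.0)
    eff = tol.e_max * f_op**tol.gamma / (f_op**tol.gamma + tol.f50**tol.gamma)
    m = 1.0 - eff
    return np.array([m, m, m])


def o2_content(p_o2, params: PhysiologyParameters):
    """Blood O2 content (L O2 / L blood): Hill saturation plus dissolved O2."""
    p = np.clip(p_o2, 0.0, None)
    sat = p**params.hill_h / (p**params.hill_h + params.p50**params.hill_h)
    return params.hb_capacity * sat + params.o2_sol * p


def _o2_content_slope(p_o2: float, params: PhysiologyParameters) -> float:
    p = max(p_o2, 1e-6)
    h = params.hill_h
    ph = p**h
    p50h = params.p50**h
    dsat = h * ph / p * p50h / (ph + p50h) ** 2
    return params.hb_capacity * dsat + params.o2_sol


def _p_from_o2_content(c: float, params: PhysiologyParameters) -> float:
    if c <= 0:
        return 0.0
    hi = 800.0
    if o2_content(hi, params) <= c:
        return hi
    return brentq(lambda p: o2_content(p, params) - c, 0.0, hi, xtol=1e-10)


def total_flow_from_energy(e: float, params: PhysiologyParameters) -> float:
    """Total blood flow as a saturating function of cardiac performance.

    Normalized so flow equals ``q0`` at full performance; the heart
    compensates until the performance state is low, then flow collapses --
    which keeps early circulatory failure reversible if oxygenation is
    restored in time.
    """
    e = min(max(e, 0.0), 1.0)
    h = params.flow_hill
    e50h = params.e50_flow**h
    return params.q0 * (e**h / (e**h + e50h)) * (1.0 + e50h)


def hypoxic_potentiation(p_o2, params: PhysiologyParameters):
    """Peripheral-drive multiplier, ~1 in normoxia and rising in hypoxia."""
    return 1.0 + params.g_hypoxic * np.exp(-(p_o2 - params.hypoxic_p0) / params.hypoxic_scale)


def central_hypoxic_depression(p_o2, params: PhysiologyParameters):
    """Central-drive attenuation by brain hypoxia (~1 above PaO2 ~ 45 mmHg).

    Carotid-body (peripheral) output is *stimulated* by hypoxia, but the
    central generator is depressed by it; the resulting positive feedback --
    hypoxia, less central drive, deeper hypoxia -- is what makes sustained
    severe hypoventilation lethal rather than self-limiting.
    """
    return 1.0 / (1.0 + np.exp(-(p_o2 - params.chd_p50) / params.chd_slope))


class MetabolicRates(NamedTuple):
    vco2: float  # L STPD / min
    vo2: float


def metabolic_rates(params: PhysiologyParameters) -> MetabolicRates:
    """CO2 production / O2 consumption anchored to the normocapnic setpoint.

    Chosen so that the drive-determined ventilation at the arterial CO2
    anchor exactly clears metabolic CO2 -- i.e. the normocapnic baseline is a
    fixed point by construction.  Metabolism does not change with the
    inspired-gas condition.
    """
    p = params.pa_co2_anchor
    thr = params.drive_threshold
    # ventilation at anchor; hypoxic potentiation evaluated self-consistently
    psi = 1.0
    for _ in range(5):
        vent = (params.g_central + params.g_peripheral * psi) * max(p - thr, 0.0) + params.w_drive
        va = (1.0 - params.dead_space_fraction) * vent
        vco2 = va * p / 863.0
        vo2 = vco2 / params.rq
        pa_o2 = 150.0 - 863.0 * vo2 / va  # normocapnic air anchor
        psi = float(hypoxic_potentiation(pa_o2, params))
    return MetabolicRates(vco2=vco2, vo2=vo2)


def steady_state(
    params: PhysiologyParameters, multipliers: Sequence[float] = (1.0, 1.0, 1.0)
) -> PhysiologyState:
    """Solve the closed-loop equilibrium for the current inspired-gas setting."""
    rates = metabolic_rates(params)
    thr = params.drive_threshold
    m_c, m_p, m_w = multipliers
    fds = 1.0 - params.dead_space_fraction

    def residual(p_co2: float) -> float:
        vent, _, _ = _drive_ventilation(p_co2, p_co2, params, rates, m_c, m_p, m_w)
        va = fds * vent
        return va * (p_co2 - params.pi_co2) - 863.0 * rates.vco2

    lo = params.pi_co2 + 1e-3
    hi = 200.0
    if residual(hi) < 0:
        raise RuntimeError("no ventilatory equilibrium below 200 mmHg CO2")
    p_star = brentq(residual, lo, hi, xtol=1e-10)
    vent, psi, chd = _drive_ventilation(p_star, p_star, params, rates, m_c, m_p, m_w)
    va = fds * vent
    pa_o2 = params.pi_o2 - 863.0 * rates.vo2 / va
    pv_co2 = p_star + rates.vco2 / (params.q0 * params.beta_co2)
    cv_o2 = max(float(o2_content(pa_o2, params)) - rates.vo2 / params.q0, 1e-6)
    pv_o2 = _p_from_o2_content(cv_o2, params)
    return PhysiologyState(
        pa_co2=p_star,
        pa_o2=pa_o2,
        pv_co2=pv_co2,
        pv_o2=pv_o2,
        d_central=params.g_central * max(p_star - thr, 0.0) * chd,
        d_peripheral=params.g_peripheral * max(p_star - thr, 0.0) * psi,
        d_wake=params.w_drive,
        x1=p_star,
        x2=p_star,
        energy=1.0,
        ventilation=vent,
        cardiac_output=params.q0,
        total_flow=params.q0,
    )


def _drive_ventilation(p_co2, p_o2_guess, params, rates, m_c, m_p, m_w):
    """Ventilation at quasi-steady drives for arterial CO2 = p_co2."""
    thr = params.drive_threshold
    fds = 1.0 - params.dead_space_fraction
    psi = 1.0
    chd = 1.0
    vent = params.w_drive
    for _ in range(8):
        d_c = params.g_central * max(p_co2 - thr, 0.0) * chd
        d_p = params.g_peripheral * max(p_co2 - thr, 0.0) * psi
        vent = m_c * d_c + m_p * d_p + m_w * params.w_drive
        va = max(fds * vent, 1e-6)
        pa_o2 = max(params.pi_o2 - 863.0 * rates.vo2 / va, 0.0)
        psi = float(hypoxic_potentiation(pa_o2, params))
        chd = float(central_hypoxic_depression(pa_o2, params))
    return vent, psi, chd


def ventilation_from_vector(
    y: np.ndarray, multipliers: Sequence[float]
) -> float:
    m_c, m_p, m_w = multipliers
    return max(0.0, m_c * y[I_DC] + m_p * y[I_DP] + m_w * y[I_DW])


def physiology_rates(
    y: np.ndarray,
    multipliers: Sequence[float],
    params: PhysiologyParameters,
    rates: MetabolicRates,
) -> np.ndarray:
    """Time derivative (per second) of the physiology state vector."""
    pa_co2, pa_o2 = max(y[I_PACO2], 0.0), max(y[I_PAO2], 0.0)
    pv_co2, pv_o2 = max(y[I_PVCO2], 0.0), max(y[I_PVO2], 0.0)
    q = total_flow_from_energy(y[I_E], params)

    vent = ventilation_from_vector(y, multipliers)
    va = (1.0 - params.dead_space_fraction) * vent

    # metabolism shuts down only in deep tissue hypoxia (keeps contents
    # positive; indistinguishable from 1 at normal venous PO2)
    f_met = -math.expm1(-pv_o2 / params.vo2_km)
    vo2 = rates.vo2 * f_met
    vco2 = rates.vco2 * f_met

    ca_co2 = params.beta_co2 * pa_co2
    cv_co2 = params.beta_co2 * pv_co2
    ca_o2 = float(o2_content(pa_o2, params))
    cv_o2 = float(o2_content(pv_o2, params))

    dy = np.empty(N_STATES)
    dy[I_PACO2] = (va * (params.pi_co2 - pa_co2) + 863.0 * q * (cv_co2 - ca_co2)) / (
        params.vl_co2 * 60.0
    )
    dy[I_PAO2] = (va * (params.pi_o2 - pa_o2) + 863.0 * q * (cv_o2 - ca_o2)) / (
        params.vl_o2 * 60.0
    )
    dy[I_PVCO2] = (vco2 + q * (ca_co2 - cv_co2)) / (params.store_co2 * 60.0)
    slope = _o2_content_slope(pv_o2, params)
    dy[I_PVO2] = (-vo2 + q * (ca_o2 - cv_o2)) / (params.vt_o2 * slope * 60.0)

    thr = params.drive_threshold
    psi = float(hypoxic_potentiation(pa_o2, params))
    chd = float(central_hypoxic_depression(pa_o2, params))
    dy[I_DC] = (
        params.g_central * max(y[I_X2] - thr, 0.0) * chd - y[I_DC]
    ) / params.tau_central
    dy[I_DP] = (
        params.g_peripheral * max(pa_co2 - thr, 0.0) * psi - y[I_DP]
    ) / params.tau_peripheral
    dy[I_DW] = (params.w_drive - y[I_DW]) / params.tau_wake
    dy[I_X1] = (pa_co2 - y[I_X1]) / params.tau_delay
    dy[I_X2] = (y[I_X1] - y[I_X2]) / params.tau_delay

    do2 = q * ca_o2
    phi = min(do2 / params.do2_crit, 2.0) - 1.0
    e = min(max(y[I_E], 0.0), 1.0)
    dy[I_E] = params.k_fail * min(phi, 0.0) * e + params.k_recover * max(phi, 0.0) * (1.0 - e)
    return dy


def set_hypercapnic(params: PhysiologyParameters) -> PhysiologyParameters:
    """Switch to the hypercapnic-challenge CO2 settings (idempotent).

    Only the two CO2 parameters change, per the validation-study protocol:
    the arterial CO2 setpoint moves to its hypercapnic value and inspired CO2
    to 34 mmHg.  The inspired O2 of the gas mixture is handled separately by
    the protocol runner.
    """
    return params.model_copy(
        update={"pa_co2_setpoint": params.pa_co2_hypercapnic, "pi_co2": 34.0}
    )


@dataclass
class ArrestDetection:
    arrest: bool
    time_s: float | None


def detect_cardiac_arrest(
    time_s: np.ndarray, total_flow: np.ndarray, threshold: float = 0.01
) -> ArrestDetection:
    """First time total blood flow reaches the arrest threshold (inclusive).

    The crossing time is linearly interpolated between grid points.
    """
    t = np.asarray(time_s, dtype=float)
    q = np.asarray(total_flow, dtype=float)
    if t.size == 0 or q.size != t.size:
        raise ValueError("empty or mismatched flow trace")
    below = q <= threshold
    if not below.any():
        return ArrestDetection(False, None)
    i = int(np.argmax(below))
    if i == 0 or q[i] == threshold:
        return ArrestDetection(True, float(t[i]))
    # interpolate the crossing between i-1 and i
    q0, q1 = q[i - 1], q[i]
    frac = (q0 - threshold) / (q0 - q1)
    return ArrestDetection(True, float(t[i - 1] + frac * (t[i] - t[i - 1])))
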