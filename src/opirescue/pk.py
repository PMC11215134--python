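"""Compartmental pharmacokinetics for opioid antagonists and opioids.

Antagonists given intranasally (IN) or intramuscularly (IM) follow a
two-compartment disposition model with linear elimination and *parallel*
zero-order and first-order absorption: a fraction ``f0`` of the bioavailable
dose enters the central compartment at a constant rate over a duration ``d2``
starting at the dose time, while the remaining fraction ``1 - f0`` enters
first-order with rate constant ``ka`` after a lag ``t_lag``.  Opioids are
given as intravenous boluses or infusions into the same two-compartment
structure.

All profiles are evaluated with closed-form bi-exponential solutions
(superposition over dose events); an independent ODE path is provided for
cross-validation.  Internal time is seconds, amounts are mg (salt basis for
antagonists, as labelled), concentrations are ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

Route = Literal["intranasal", "intramuscular", "intravenous"]

SEC_PER_HOUR = 3600.0


class PopulationPKModel(BaseModel):
    """Typical-value population PK model for one drug (possibly two routes).

    Rate constants and clearances are per hour; volumes in litres. ``iiv``
    maps parameter names to between-subject variability as %CV.
    """

    model_config = ConfigDict(extra="forbid")

    drug: str
    routes: list[Route]
    cl_f: float = Field(gt=0)
    vc_f: float = Field(gt=0)
    q_f: float = Field(gt=0)
    vp_f: float = Field(gt=0)
    ka: dict[str, float] = Field(default_factory=dict)
    f0: dict[str, float] = Field(default_factory=dict)
    d2: float = Field(default=0.0, ge=0)
    t_lag: float = Field(default=0.0, ge=0)
    f_rel: float = Field(default=1.0, gt=0, le=1.0)
    wt_exponent: float = 0.0
    wt_ref: float = Field(default=74.7, gt=0)
    std_eff: float = 0.0
    sigma2: float = Field(default=0.0, ge=0)
    iiv: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_absorption(self) -> "PopulationPKModel":
        for route in self.routes:
            if route == "intravenous":
                continue
            if route not in self.ka:
                raise ValueError(f"{self.drug}: missing ka for route {route}")
            if self.ka[route] <= 0:
                raise ValueError(f"{self.drug}: ka must be positive")
            frac = self.f0.get(route, 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.drug}: f0 must lie in [0, 1]")
            if frac > 0 and self.d2 <= 0:
                raise ValueError(f"{self.drug}: d2 must be positive when f0 > 0")
        return self


class IndividualPKParameters(BaseModel):
    """One subject's realized disposition/absorption constants for one route."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    route: Route
    cl: float = Field(gt=0)
    vc: float = Field(gt=0)
    q: float = Field(gt=0)
    vp: float = Field(gt=0)
    ka: float = Field(default=0.0, ge=0)
    f0: float = Field(default=0.0, ge=0, le=1.0)
    d2: float = Field(default=0.0, ge=0)
    t_lag: float = Field(default=0.0, ge=0)
    bioavail: float = Field(default=1.0, gt=0, le=1.0)
    weight: float = Field(default=74.7, gt=0)


class DoseEvent(BaseModel):
    """A single administration: time in seconds, amount in mg (salt basis)."""

    model_config = ConfigDict(extra="forbid")

    time_s: float = Field(ge=0)
    amount_mg: float = Field(ge=0)
    route: Route
    drug: str = ""
    infusion_duration_s: Optional[float] = Field(default=None, gt=0)

    @property
    def is_infusion(self) -> bool:
        return self.infusion_duration_s is not None

    @model_validator(mode="after")
    def _check_infusion(self) -> "DoseEvent":
        if self.infusion_duration_s is not None and self.route != "intravenous":
            raise ValueError("infusion dosing requires the intravenous route")
        return self


@dataclass
class PlasmaProfile:
    """Concentration-time profile on a fixed grid (seconds, ng/mL)."""

    time_s: np.ndarray
    conc_ng_ml: np.ndarray
    drug: str = ""

    def to_frame(self, subject_id: str = "typical"):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "drug": self.drug,
                "time_s": self.time_s,
                "conc_ng_ml": self.conc_ng_ml,
            }
        )


def typical_parameters(
    model: PopulationPKModel,
    weight: float = 74.7,
    route: Route | None = None,
    hypercapnic_study: bool = False,
) -> IndividualPKParameters:
    """Realize the typical subject for ``model`` at a given body weight.

    Apparent clearance scales allometrically as ``(weight / wt_ref) **
    wt_exponent``.  Under the hypercapnic-study condition the intranasal
    first-order absorption rate constant is shifted proportionally by
    ``std_eff`` (mucosal drying blunts the nasal absorption enhancer).
    Intranasal doses carry the relative bioavailability ``f_rel`` versus the
    intramuscular reference.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if route is None:
        route = model.routes[0]
    if route not in model.routes:
        raise ValueError(f"route {route!r} not supported by the {model.drug} model")
    cl = model.cl_f * (weight / model.wt_ref) ** model.wt_exponent
    ka = model.ka.get(route, 0.0)
    if route == "intranasal" and hypercapnic_study:
        ka = ka * (1.0 + model.std_eff)
    bioavail = model.f_rel if route == "intranasal" and "intramuscular" in model.routes else 1.0
    return IndividualPKParameters(
        drug=model.drug,
        route=route,
        cl=cl,
        vc=model.vc_f,
        q=model.q_f,
        vp=model.vp_f,
        ka=ka,
        f0=model.f0.get(route, 0.0),
        d2=model.d2 if route != "intravenous" else 0.0,
        t_lag=model.t_lag if route != "intravenous" else 0.0,
        bioavail=bioavail,
        weight=weight,
    )


# ---------------------------------------------------------------------------
# closed-form machinery


@dataclass
class Disposition:
    """Two-compartment disposition in per-second micro constants.

    The central-concentration impulse response to a unit bolus is
    ``(c_a * exp(-alpha t) + c_b * exp(-beta t)) / vc`` with ``alpha > beta``
    the eigenvalues of the disposition matrix.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    c_a: float
    c_b: float
    vc: float


def disposition(params: IndividualPKParameters) -> Disposition:
    k10 = params.cl / params.vc / SEC_PER_HOUR
    k12 = params.q / params.vc / SEC_PER_HOUR
    k21 = params.q / params.vp / SEC_PER_HOUR
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = alpha - beta
    if denom <= 0:  # degenerate repeated root; nudge apart
        denom = max(1e-15, abs(alpha) * 1e-9)
        alpha += denom
    c_a = (alpha - k21) / (alpha - beta)
    c_b = (k21 - beta) / (alpha - beta)
    return Disposition(k10, k12, k21, alpha, beta, c_a, c_b, params.vc)


def _ediff(lam: float, ka: float, t: np.ndarray) -> np.ndarray:
    """(exp(-lam t) - exp(-ka t)) / (ka - lam), stable when ka ~ lam.

    Both exponentials are bounded by 1 for non-negative rates/times, so the
    direct difference is safe; only the removable singularity at ka = lam
    needs the series branch.
    """
    d = ka - lam
    x = d * t
    small = np.abs(x) < 1e-6
    safe_d = np.where(small, 1.0, d)
    direct = (np.exp(-lam * t) - np.exp(-ka * t)) / safe_d
    series = np.exp(-lam * t) * t * (1.0 - x / 2.0)
    return np.where(small, series, direct)


def _bolus_conc(dsp: Disposition, amount: float, tau: np.ndarray) -> np.ndarray:
    c = amount / dsp.vc * (dsp.c_a * np.exp(-dsp.alpha * tau) + dsp.c_b * np.exp(-dsp.beta * tau))
    return np.where(tau >= 0, c, 0.0)


def _zero_order_conc(dsp: Disposition, amount: float, dur_s: float, tau: np.ndarray) -> np.ndarray:
    """Constant-rate input of ``amount`` over ``dur_s`` seconds starting at tau=0."""
    if dur_s <= 0:
        return _bolus_conc(dsp, amount, tau)
    rate = amount / dur_s
    out = np.zeros_like(tau, dtype=float)
    for lam, c in ((dsp.alpha, dsp.c_a), (dsp.beta, dsp.c_b)):
        during = rate * c / (dsp.vc * lam) * (-np.expm1(-lam * np.clip(tau, 0.0, None)))
        after_tau = np.clip(tau - dur_s, 0.0, None)
        after = (
            rate
            * c
            / (dsp.vc * lam)
            * (np.exp(-lam * after_tau) - np.exp(-lam * np.clip(tau, 0.0, None)))
        )
        out += np.where(tau <= dur_s, during, after)
    return np.where(tau >= 0, out, 0.0)


def _first_order_conc(
    dsp: Disposition, amount: float, ka_s: float, tau: np.ndarray
) -> np.ndarray:
    """First-order input with per-second rate ``ka_s`` starting at tau=0."""
    taup = np.clip(tau, 0.0, None)
    out = amount * ka_s / dsp.vc * (
        dsp.c_a * _ediff(dsp.alpha, ka_s, taup) + dsp.c_b * _ediff(dsp.beta, ka_s, taup)
    )
    return np.where(tau >= 0, out, 0.0)


def _single_dose_conc(
    params: IndividualPKParameters, dsp: Disposition, dose: DoseEvent, t: np.ndarray
) -> np.ndarray:
    tau = t - dose.time_s
    if dose.route == "intravenous":
        if dose.is_infusion:
            return _zero_order_conc(dsp, dose.amount_mg, dose.infusion_duration_s, tau)
        return _bolus_conc(dsp, dose.amount_mg, tau)
    bio = dose.amount_mg * params.bioavail
    conc = np.zeros_like(tau, dtype=float)
    if params.f0 > 0:
        conc += _zero_order_conc(dsp, bio * params.f0, params.d2 * SEC_PER_HOUR, tau)
    if params.f0 < 1:
        ka_s = params.ka / SEC_PER_HOUR
        conc += _first_order_conc(
            dsp, bio * (1.0 - params.f0), ka_s, tau - params.t_lag * SEC_PER_HOUR
        )
    return conc


def conc_function(params: IndividualPKParameters, doses: Sequence[DoseEvent]):
    """Return a vectorized closed-form ``C(t)`` (t in s, C in ng/mL).

    mg / L equals ug/mL; the factor 1000 converts to ng/mL.
    """
    dsp = disposition(params)
    dose_list = list(doses)
    for d in dose_list:
        if d.amount_mg < 0:
            raise ValueError("negative dose amount")

    def conc(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        total = np.zeros_like(t)
        for dose in dose_list:
            if dose.amount_mg == 0:
                continue
            total += _single_dose_conc(params, dsp, dose, t)
        return np.clip(total * 1000.0, 0.0, None)

    return conc


def plasma_concentration(
    params: IndividualPKParameters,
    doses: Sequence[DoseEvent],
    time_grid: np.ndarray,
    method: Literal["closed_form", "ode"] = "closed_form",
) -> PlasmaProfile:
    """Plasma concentration-time profile by superposition over dose events."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    doses = sorted(doses, key=lambda d: d.time_s)
    if method == "closed_form":
        conc = conc_function(params, doses)(t)
    elif method == "ode":
        conc = _ode_concentration(params, doses, t)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PlasmaProfile(time_s=t, conc_ng_ml=conc, drug=params.drug)


def _ode_concentration(
    params: IndividualPKParameters, doses: Sequence[DoseEvent], t: np.ndarray
) -> np.ndarray:
    """Independent ODE evaluation (forcing-function inputs, segment-wise)."""
    from scipy.integrate import solve_ivp

    dsp = disposition(params)
    ka_s = params.ka / SEC_PER_HOUR
    d2_s = params.d2 * SEC_PER_HOUR
    lag_s = params.t_lag * SEC_PER_HOUR

    inputs = []  # (kind, start, stop_or_None, magnitude)
    bolus = []  # (time, amount)
    for d in doses:
        if d.amount_mg == 0:
            continue
        if d.route == "intravenous":
            if d.is_infusion:
                inputs.append(("zero", d.time_s, d.time_s + d.infusion_duration_s,
                               d.amount_mg / d.infusion_duration_s))
            else:
                bolus.append((d.time_s, d.amount_mg))
        else:
            bio = d.amount_mg * params.bioavail
            if params.f0 > 0:
                inputs.append(("zero", d.time_s, d.time_s + d2_s, bio * params.f0 / d2_s))
            if params.f0 < 1:
                inputs.append(("first", d.time_s + lag_s, None, bio * (1 - params.f0)))

    def rate_in(tt: float) -> float:
        r = 0.0
        for kind, start, stop, mag in inputs:
            if kind == "zero":
                if start <= tt < stop:
                    r += mag
            else:
                if tt >= start:
                    r += mag * ka_s * math.exp(-ka_s * (tt - start))
        return r

    def rhs(tt, y):
        a1, a2 = y
        return [
            rate_in(tt) - (dsp.k10 + dsp.k12) * a1 + dsp.k21 * a2,
            dsp.k12 * a1 - dsp.k21 * a2,
        ]

    breaks = {float(t[0]), float(t[-1])}
    for kind, start, stop, _ in inputs:
        breaks.add(start)
        if stop is not None:
            breaks.add(stop)
    for tb, _ in bolus:
        breaks.add(tb)
    breaks = sorted(b for b in breaks if t[0] <= b <= t[-1])

    conc = np.zeros_like(t)
    y = [0.0, 0.0]
    t_cursor = float(t[0])
    for tb, amt in sorted(bolus):
        if tb <= t_cursor:
            y[0] += amt
    # record t[0]
    conc[t == t_cursor] = y[0] / dsp.vc * 1000.0
    seg_edges = [b for b in breaks if b > t_cursor]
    for edge in seg_edges:
        mask = (t > t_cursor) & (t <= edge)
        t_eval = t[mask]
        sol = solve_ivp(
            rhs, (t_cursor, edge), y, method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True, max_step=(edge - t_cursor),
        )
        if not sol.success:
            raise RuntimeError(f"PK ODE integration failed: {sol.message}")
        if t_eval.size:
            conc[mask] = sol.sol(t_eval)[0] / dsp.vc * 1000.0
        y = list(sol.sol(edge))
        for tb, amt in bolus:
            if math.isclose(tb, edge, abs_tol=1e-9):
                y[0] += amt
        t_cursor = edge
    return np.clip(conc, 0.0, None)


def terminal_half_life(params: IndividualPKParameters) -> float:
    """Terminal (beta-phase) half-life in hours.

    ``beta`` is the slow eigenvalue of the disposition system with
    micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp.
    """
    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if beta <= 0 or alpha <= 0:
        raise ValueError("invalid disposition parameters (non-positive eigenvalue)")
    # residue of the slow phase in the central impulse response; when the
    # inter-compartmental clearance vanishes the beta phase carries no
    # amplitude and the observable terminal slope is the central eigenvalue
    if (k21 - beta) / (alpha - beta) < 1e-9:
        return math.log(2.0) / alpha
    return math.log(2.0) / beta


KNOWN_OPIOIDS = ("fentanyl", "carfentanil", "remifentanil")


def opioid_concentration(
    opioid: str,
    params: Optional[IndividualPKParameters],
    doses: Sequence[DoseEvent],
    time_grid: np.ndarray,
) -> PlasmaProfile:
    """IV bolus/infusion profile for a synthetic opioid."""
    if opioid not in KNOWN_OPIOIDS:
        raise ValueError(f"unknown opioid {opioid!r}; expected one of {KNOWN_OPIOIDS}")
    if params is None:
        raise ValueError(f"opioid PK bundle not provided for {opioid!r}")
    profile = plasma_concentration(params, doses, time_grid)
    profile.drug = opioid
    return profile
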