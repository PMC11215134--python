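"""Per-subject and per-trial overdose simulation.

A subject's coupled system stacks four drug states (effect-site
concentrations and receptor occupancies of one opioid and one antagonist)
on top of the ten physiology states.  Plasma concentrations enter as
closed-form forcing functions of time, so dosing never enlarges the state
vector.

The rescue policy is event-driven: at the first *downward* crossing of
minute ventilation through ``trigger_fraction`` of the subject's own
pre-dose baseline, the antagonist dose (n simultaneous units as one summed
administration) is scheduled ``delay_s`` later.  Integration stops at
cardiac arrest (total blood flow reaching the arrest threshold) or at the
horizon.  A single rescue per subject; later crossings are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import physiology as phys
from .binding import BindingParameters, effect_site_rate, receptor_rates, to_free_molar
from .bundle import ParameterBundle, antagonist_pk_key, default_bundle
from .physiology import (
    N_STATES,
    I_E,
    PhysiologyParameters,
    drive_suppression,
    metabolic_rates,
    steady_state,
    ventilation_from_vector,
)
from .pk import DoseEvent, IndividualPKParameters, conc_function
from .population import VirtualSubject
from .stats import BootstrapSummary, bootstrap_incidence

log = logging.getLogger(__name__)

# stacked state layout: drug block then physiology block
I_CE_OP, I_CE_ANT, I_FOP, I_FANT = range(4)
PHYS0 = 4


@dataclass
class RescuePolicy:
    """Ventilation-triggered antagonist administration."""

    antagonist: Optional[str] = "nalmefene"
    route: str = "intranasal"
    n_simultaneous_doses: int = 1
    dose_per_unit_mg: float = 3.0
    trigger_fraction: float = 0.40
    delay_s: float = 60.0

    def __post_init__(self):
        if not 0.0 < self.trigger_fraction < 1.0:
            raise ValueError("trigger_fraction must lie in (0, 1)")
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")
        if self.n_simultaneous_doses < 0:
            raise ValueError("dose count must be >= 0")

    @property
    def total_dose_mg(self) -> float:
        return self.n_simultaneous_doses * self.dose_per_unit_mg

    @property
    def active(self) -> bool:
        return self.antagonist is not None and self.total_dose_mg > 0


@dataclass
class Scenario:
    opioid: str = "fentanyl"
    opioid_dose_mg: float = 1.63
    population: str = "chronic"
    rescue: RescuePolicy = field(default_factory=RescuePolicy)
    horizon_s: float = 14400.0
    seed: int = 1
    rtol: float = 1e-6
    atol: float = 1e-8
    bootstrap_m: int = 400
    bootstrap_b: int = 2500

    def __post_init__(self):
        if self.opioid_dose_mg < 0:
            raise ValueError("opioid dose must be >= 0")
        if self.horizon_s <= 0:
            raise ValueError("horizon must be positive")

    def describe(self) -> str:
        r = self.rescue
        arm = (
            f"{r.n_simultaneous_doses}x{r.dose_per_unit_mg}mg {r.antagonist} ({r.route})"
            if r.active
            else "no antagonist"
        )
        return f"{self.opioid} {self.opioid_dose_mg} mg, {self.population}, {arm}"


@dataclass
class SubjectResult:
    subject_id: int
    arrest: bool
    arrest_time_s: Optional[float]
    trigger_time_s: Optional[float]
    nadir_ventilation: float
    baseline_ventilation: float
    traces: Optional[pd.DataFrame] = None


@dataclass
class TrialResult:
    scenario: Scenario
    subjects: list[SubjectResult]
    incidence_pct: float
    bootstrap: BootstrapSummary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "arrest": [s.arrest for s in self.subjects],
                "arrest_time_s": [s.arrest_time_s for s in self.subjects],
                "trigger_time_s": [s.trigger_time_s for s in self.subjects],
                "nadir_vent": [s.nadir_ventilation for s in self.subjects],
            }
        )


class _SubjectSystem:
    """RHS and events for one subject under one scenario."""

    def __init__(
        self,
        op_binding: BindingParameters,
        ant_binding: Optional[BindingParameters],
        params: PhysiologyParameters,
    ):
        self.b_op = op_binding
        self.b_ant = ant_binding
        self.params = params
        self.rates = metabolic_rates(params)
        self.op_conc = lambda t: 0.0
        self.ant_conc = lambda t: 0.0

    def set_opioid_doses(self, pk: IndividualPKParameters, doses: Sequence[DoseEvent]):
        fn = conc_function(pk, doses)
        self.op_conc = lambda t: float(fn(t)[0])

    def set_antagonist_doses(self, pk: IndividualPKParameters, doses: Sequence[DoseEvent]):
        fn = conc_function(pk, doses)
        self.ant_conc = lambda t: float(fn(t)[0])

    def multipliers(self, y: np.ndarray) -> np.ndarray:
        f_op = min(max(y[I_FOP], 0.0), 1.0)
        return drive_suppression(f_op, self.params.tolerance)

    def ventilation(self, y: np.ndarray) -> float:
        return ventilation_from_vector(y[PHYS0:], self.multipliers(y))

    def flow(self, y: np.ndarray) -> float:
        return phys.total_flow_from_energy(y[PHYS0 + I_E], self.params)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty(PHYS0 + N_STATES)
        cp_op = to_free_molar(self.op_conc(t), self.b_op.mw, self.b_op.fu)
        dy[I_CE_OP] = effect_site_rate(y[I_CE_OP], cp_op, self.b_op.k_e0)
        if self.b_ant is not None:
            cp_ant = to_free_molar(self.ant_conc(t), self.b_ant.mw, self.b_ant.fu)
            dy[I_CE_ANT] = effect_site_rate(y[I_CE_ANT], cp_ant, self.b_ant.k_e0)
        else:
            dy[I_CE_ANT] = 0.0
        d_op, d_ant = receptor_rates(
            y[I_FOP], y[I_FANT], max(y[I_CE_OP], 0.0), max(y[I_CE_ANT], 0.0),
            self.b_op, self.b_ant,
        )
        dy[I_FOP] = d_op
        dy[I_FANT] = d_ant
        dy[PHYS0:] = phys.physiology_rates(
            y[PHYS0:], self.multipliers(y), self.params, self.rates
        )
        return dy


def _initial_state(system: _SubjectSystem) -> tuple[np.ndarray, float]:
    base = steady_state(system.params)
    y0 = np.zeros(PHYS0 + N_STATES)
    y0[PHYS0:] = base.to_vector()
    return y0, base.ventilation


def run_subject(
    subject: VirtualSubject,
    scenario: Scenario,
    bundle: Optional[ParameterBundle] = None,
    store_traces: bool = False,
    trace_dt: float = 5.0,
) -> SubjectResult:
    """Integrate one subject through the overdose scenario."""
    bundle = bundle or default_bundle()
    rescue = scenario.rescue

    op_pk = subject.pk.get(scenario.opioid)
    if op_pk is None:
        raise ValueError(f"subject {subject.id}: no PK parameters for {scenario.opioid!r}")
    op_binding = subject.binding[scenario.opioid]
    ant_binding = None
    ant_pk = None
    if rescue.active:
        ant_binding = subject.binding[rescue.antagonist]
        ant_pk = subject.pk[antagonist_pk_key(rescue.antagonist, rescue.route)]

    params = bundle.physiology_parameters(subject.preset)
    system = _SubjectSystem(op_binding, ant_binding, params)
    system.set_opioid_doses(
        op_pk,
        [DoseEvent(time_s=0.0, amount_mg=scenario.opioid_dose_mg, route="intravenous",
                   drug=scenario.opioid)],
    )

    y0, baseline = _initial_state(system)
    thr = params.arrest_flow_threshold
    trig_level = rescue.trigger_fraction * baseline

    def ev_arrest(t, y):
        return system.flow(y) - thr

    ev_arrest.terminal = True
    ev_arrest.direction = -1

    def ev_trigger(t, y):
        return system.ventilation(y) - trig_level

    ev_trigger.direction = -1
    ev_trigger.terminal = rescue.active

    solver_kw = dict(method="LSODA", rtol=scenario.rtol, atol=scenario.atol,
                     dense_output=True)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []

    def integrate(t0, t1, y, events):
        sol = solve_ivp(system.rhs, (t0, t1), y, events=events, **solver_kw)
        if not sol.success:
            raise RuntimeError(
                f"solver failure for subject {subject.id} in scenario "
                f"[{scenario.describe()}]: {sol.message}"
            )
        grid = np.arange(t0, sol.t[-1], trace_dt if not store_traces else min(trace_dt, 1.0))
        grid = np.append(grid, sol.t[-1])
        times.append(grid)
        states.append(sol.sol(grid))
        return sol

    trigger_time = None
    arrest_time = None
    horizon = scenario.horizon_s

    sol = integrate(0.0, horizon, y0, [ev_arrest, ev_trigger])
    if sol.t_events[1].size:
        trigger_time = float(sol.t_events[1][0])
    if sol.t_events[0].size:
        arrest_time = float(sol.t_events[0][0])
    elif rescue.active and trigger_time is not None:
        # phase B: trigger to administration time (delay), arrest still armed
        y = sol.y[:, -1].copy()
        t_dose = trigger_time + rescue.delay_s
        if t_dose < horizon:
            sol = integrate(trigger_time, t_dose, y, [ev_arrest])
            if sol.t_events[0].size:
                arrest_time = float(sol.t_events[0][0])
            else:
                # phase C: antagonist on board
                y = sol.y[:, -1].copy()
                system.set_antagonist_doses(
                    ant_pk,
                    [DoseEvent(time_s=t_dose, amount_mg=rescue.total_dose_mg,
                               route=rescue.route, drug=rescue.antagonist)],
                )
                log.info(
                    "subject %d: trigger at %.1f s, %s %.1f mg administered at %.1f s",
                    subject.id, trigger_time, rescue.antagonist,
                    rescue.total_dose_mg, t_dose,
                )
                sol = integrate(t_dose, horizon, y, [ev_arrest])
                if sol.t_events[0].size:
                    arrest_time = float(sol.t_events[0][0])
        else:
            sol = integrate(trigger_time, horizon, y, [ev_arrest])
            if sol.t_events[0].size:
                arrest_time = float(sol.t_events[0][0])

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    vent = np.array([system.ventilation(y_all[:, j]) for j in range(y_all.shape[1])])
    flow = np.array([system.flow(y_all[:, j]) for j in range(y_all.shape[1])])

    if arrest_time is not None:
        log.info("subject %d: cardiac arrest at %.1f s", subject.id, arrest_time)

    traces = None
    if store_traces:
        traces = pd.DataFrame(
            {
                "time_s": t_all,
                "ventilation": vent,
                "pa_o2": y_all[PHYS0 + phys.I_PAO2],
                "pa_co2": y_all[PHYS0 + phys.I_PACO2],
                "cardiac_output": flow,
                "f_op": y_all[I_FOP],
                "f_ant": y_all[I_FANT],
            }
        )

    return SubjectResult(
        subject_id=subject.id,
        arrest=arrest_time is not None,
        arrest_time_s=arrest_time,
        trigger_time_s=trigger_time,
        nadir_ventilation=float(vent.min()),
        baseline_ventilation=baseline,
        traces=traces,
    )


def run_trial(
    subjects: Sequence[VirtualSubject],
    scenario: Scenario,
    bundle: Optional[ParameterBundle] = None,
) -> TrialResult:
    """Run every subject and summarize arrest incidence with the bootstrap."""
    if len(subjects) == 0:
        raise ValueError("empty population")
    bundle = bundle or default_bundle()
    results = [run_subject(s, scenario, bundle) for s in subjects]
    outcomes = np.array([r.arrest for r in results], dtype=float)
    incidence = float(100.0 * outcomes.mean())
    m = min(scenario.bootstrap_m, len(subjects))
    summary = bootstrap_incidence(outcomes, m=m, b=scenario.bootstrap_b, seed=scenario.seed)
    log.info("trial [%s]: incidence %.1f%% (n=%d)", scenario.describe(), incidence,
             len(subjects))
    return TrialResult(scenario=scenario, subjects=results, incidence_pct=incidence,
                       bootstrap=summary)


# ---------------------------------------------------------------------------
# hypercapnic remifentanil validation protocol


VALIDATION_TIMELINE = {
    "remifentanil_start_s": 600.0,
    "antagonist_time_s": 1500.0,
    "end_s": 2760.0,
}


def simulate_validation_protocol(
    antagonist: Optional[str],
    bundle: Optional[ParameterBundle] = None,
    weight: float = 74.7,
    remifentanil_n: float = 0.75,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> pd.DataFrame:
    """Typical-subject run of the hypercapnic remifentanil challenge.

    Timeline: hypercapnic gas (7% CO2, 50% O2) from t = 0; remifentanil
    0.5 ug/kg IV bolus plus a 0.175 ug/kg/min infusion from t = 10 min;
    a single IN antagonist dose (3 mg nalmefene HCl or 4 mg naloxone HCl)
    at t = 25 min -- the nadir of minute ventilation; monitoring to 46 min.
    Run in the opioid-naive preset; nalmefene absorption carries the
    hypercapnic-study shift.  ``antagonist=None`` simulates no reversal.
    """
    bundle = bundle or default_bundle()
    if antagonist not in (None, "nalmefene", "naloxone"):
        raise ValueError(f"unknown antagonist {antagonist!r}")

    params = phys.set_hypercapnic(bundle.physiology_parameters("naive"))
    params = params.model_copy(update={"pi_o2": 356.0})  # 50% O2 mixture

    remi_pk = bundle.pk_model("remifentanil")
    from .pk import typical_parameters

    op_pk = typical_parameters(remi_pk, weight=weight, route="intravenous")
    op_binding = bundle.binding_parameters("remifentanil").model_copy(
        update={"n": remifentanil_n}
    )

    ant_binding = None
    ant_pk = None
    dose_mg = 0.0
    if antagonist is not None:
        ant_binding = bundle.binding_parameters(antagonist)
        key = antagonist_pk_key(antagonist, "intranasal")
        ant_pk = typical_parameters(
            bundle.pk_model(key), weight=weight, route="intranasal",
            hypercapnic_study=True,
        )
        dose_mg = 3.0 if antagonist == "nalmefene" else 4.0

    system = _SubjectSystem(op_binding, ant_binding, params)
    t_remi = VALIDATION_TIMELINE["remifentanil_start_s"]
    t_ant = VALIDATION_TIMELINE["antagonist_time_s"]
    t_end = VALIDATION_TIMELINE["end_s"]
    bolus_mg = 0.5 * weight / 1000.0
    infusion_rate_mg_s = 0.175 * weight / 1000.0 / 60.0
    system.set_opioid_doses(
        op_pk,
        [
            DoseEvent(time_s=t_remi, amount_mg=bolus_mg, route="intravenous",
                      drug="remifentanil"),
            DoseEvent(
                time_s=t_remi,
                amount_mg=infusion_rate_mg_s * (t_end - t_remi),
                route="intravenous",
                drug="remifentanil",
                infusion_duration_s=t_end - t_remi,
            ),
        ],
    )
    if antagonist is not None:
        system.set_antagonist_doses(
            ant_pk,
            [DoseEvent(time_s=t_ant, amount_mg=dose_mg, route="intranasal",
                       drug=antagonist)],
        )

    y0, baseline = _initial_state(system)
    grid = np.arange(0.0, t_end + 1.0, 1.0)
    rows = []
    y = y0
    t0 = 0.0
    for edge in (t_remi, t_ant, t_end):
        seg = grid[(grid >= t0) & (grid <= edge)]
        sol = solve_ivp(system.rhs, (t0, edge), y, method="LSODA", rtol=rtol,
                        atol=atol, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"validation protocol solver failure: {sol.message}")
        ys = sol.sol(seg)
        for j, tt in enumerate(seg):
            if tt == t0 and rows:
                continue
            rows.append(
                {
                    "time_s": tt,
                    "ventilation": system.ventilation(ys[:, j]),
                    "pa_co2": ys[PHYS0 + phys.I_PACO2, j],
                    "pa_o2": ys[PHYS0 + phys.I_PAO2, j],
                    "f_op": ys[I_FOP, j],
                    "f_ant": ys[I_FANT, j],
                }
            )
        y = sol.y[:, -1]
        t0 = edge
    frame = pd.DataFrame(rows)
    frame.attrs["baseline_ventilation"] = baseline
    frame.attrs["antagonist"] = antagonist
    return frame
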