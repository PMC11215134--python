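"""Biophase kinetics and kinetic competitive binding at the mu-opioid receptor.

Plasma concentrations (ng/mL) are converted to free effect-site units (pM),
which equilibrate with plasma through a first-order constant ``k_e0``.
Opioid and antagonist then compete for free receptor with mass-action
kinetics; the association rate carries a Hill-type concentration exponent
``n`` (units of ``k_on`` are pM^-n s^-1):

    df_i/dt = k_on,i * C_e,i**n_i * (1 - f_op - f_ant) - k_off,i * f_i

Opioid-bound receptor fraction ``f_op`` is the pharmacodynamic input to the
physiology module; antagonist-bound receptors are pharmacologically silent.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class BindingParameters(BaseModel):
    """Receptor kinetics plus biophase equilibration for one drug."""

    model_config = ConfigDict(extra="forbid")

    drug: str = ""
    k_on: float = Field(gt=0, description="association rate constant (pM^-n s^-1)")
    k_off: float = Field(gt=0, description="dissociation rate constant (s^-1)")
    n: float = Field(gt=0, description="concentration steepness exponent")
    k_e0: float = Field(gt=0, description="plasma-brain equilibration constant (s^-1)")
    fu: float = Field(default=1.0, gt=0, le=1.0, description="unbound fraction in plasma")
    mw: float = Field(default=300.0, gt=0, description="molar mass (g/mol, free base)")


class ReceptorState(BaseModel):
    """Fractions of mu-opioid receptors bound by opioid and antagonist."""

    model_config = ConfigDict(extra="forbid")

    f_op: float = Field(ge=0)
    f_ant: float = Field(ge=0)


def to_free_molar(conc_ng_ml, mw: float, fu: float = 1.0):
    """Convert a total plasma concentration (ng/mL) to free picomolar.

    ng/mL = ug/L, so molar = conc * 1e-6 / mw (mol/L) and
    pM = conc * fu * 1e6 / mw.
    """
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    return conc_ng_ml * fu * 1.0e6 / mw


def effect_site_rate(c_e, c_p_free, k_e0: float):
    """First-order biophase equilibration: dC_e/dt = k_e0 (C_p,free - C_e)."""
    return k_e0 * (c_p_free - c_e)


def receptor_rates(
    f_op: float,
    f_ant: float,
    c_e_op: float,
    c_e_ant: float,
    p_op: BindingParameters,
    p_ant: BindingParameters | None = None,
):
    """Competitive mass-action binding rates (df_op/dt, df_ant/dt)."""
    free = 1.0 - f_op - f_ant
    d_op = p_op.k_on * max(c_e_op, 0.0) ** p_op.n * free - p_op.k_off * f_op
    if p_ant is None:
        return d_op, 0.0
    d_ant = p_ant.k_on * max(c_e_ant, 0.0) ** p_ant.n * free - p_ant.k_off * f_ant
    return d_op, d_ant


def equilibrium_occupancy(c_e: float, p: BindingParameters) -> float:
    """Single-drug steady-state occupancy K/(1+K) with K = k_on C^n / k_off."""
    k = p.k_on * max(c_e, 0.0) ** p.n / p.k_off
    return k / (1.0 + k)


def scale_nalmefene(
    p_naloxone: BindingParameters, r_on: float, r_off: float
) -> BindingParameters:
    """Derive nalmefene receptor kinetics from a naloxone parameter set.

    The nalmefene/naloxone ratios of ``k_on`` and ``k_off`` measured in vitro
    are applied multiplicatively; the steepness ``n`` and the biophase
    constant ``k_e0`` are carried over unchanged (assumed shared given the
    drugs' similar physicochemistry).  ``fu`` and ``mw`` remain those of the
    input set and are normally overwritten from the bundle's nalmefene entry.
    """
    if r_on <= 0 or r_off <= 0:
        raise ValueError("scaling ratios must be positive")
    return p_naloxone.model_copy(
        update={
            "drug": "nalmefene",
            "k_on": p_naloxone.k_on * r_on,
            "k_off": p_naloxone.k_off * r_off,
        }
    )
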