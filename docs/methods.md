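# Methods

`opirescue` is a mechanistic pharmacokinetic/pharmacodynamic (PK/PD)
simulator of synthetic-opioid overdose and rescue by μ-opioid receptor
antagonists. A virtual subject is a coupled ordinary-differential-equation
system with four layers: plasma PK of opioid and antagonist, biophase
(effect-site) equilibration, kinetic competitive receptor binding, and a
cardiorespiratory feedback model whose terminal endpoint is cardiac arrest.
A virtual trial integrates this system for a population of subjects and
summarizes the percentage with cardiac arrest by bootstrap.

## Pharmacokinetics

Antagonists follow two-compartment disposition with linear elimination and
*parallel* zero-order and first-order absorption: a fraction `f0` of the
bioavailable dose enters the central compartment at a constant rate over a
duration `D2` starting at the dose time; the remaining `1 − f0` enters
first-order with rate constant `ka` after a lag `t_lag`. The lag applies
only to the first-order pathway; the zero-order input starts at the dose
time. This changes early concentrations, which is exactly the regime that
decides a rescue.

The intranasal/intramuscular nalmefene model carries an allometric exponent
on apparent clearance, `CL/F × (WT/74.7)^0.572`, and a proportional shift
(−34.9%) of the intranasal absorption rate constant under the
hypercapnic-challenge condition (mask breathing dries the nasal mucosa and
blunts the absorption enhancer). Intranasal doses are multiplied by the
relative bioavailability `FR = 0.834` versus the intramuscular reference;
the intramuscular bioavailable fraction is treated as 1.0. Overdose
simulations use the non-hypercapnic absorption parameters; the validation
protocol uses the shifted ones.

Profiles are evaluated in closed form (bi-exponential impulse response,
convolved analytically with the zero-order and first-order inputs, summed
over dose events); an independent ODE integration of the same system is
kept as a cross-check and the two agree to 0.1% in the tests. The terminal
half-life is `ln 2 / β` with `β` the slow eigenvalue of the disposition
matrix (`k10 = CL/Vc`, `k12 = Q/Vc`, `k21 = Q/Vp`); when the slow phase has
vanishing amplitude (the one-compartment limit `Q → 0`) the observable
central eigenvalue is returned instead.

Doses are booked in mg of the labelled salt (3 mg nalmefene HCl ≡ 2.7 mg
free base); because the population models were estimated with salt-basis
dosing and base-concentration observations, the apparent parameters absorb
the factor and no explicit conversion is applied in the PK layer. Molar
masses in the binding layer are free-base values, consistent with measured
plasma concentrations. Internal units: time s, amounts mg, concentrations
ng/mL.

Opioid PK (IV bolus/infusion) uses two-compartment models from the
parameter bundle. The shipped opioid models are synthetic, literature-
informed stand-ins (see *Parameter bundle* below); the carfentanil model is
constrained so that a bolus concentration halves in ≈45 min.

## Biophase and receptor binding

Free plasma concentration (ng/mL × `fu` × 10⁶/MW → pM) drives a first-order
effect compartment, `dCe/dt = ke0 (Cp,free − Ce)`, with `ke0 = 0.001774 s⁻¹`
shared by nalmefene and naloxone and `ke0 = 0.0218 s⁻¹` for remifentanil
(equilibration half-life 0.53 min). Opioid and antagonist compete for the
receptor with mass-action kinetics and a Hill-type concentration exponent on
the association step:

    df_i/dt = k_on,i · Ce_i^{n_i} · (1 − f_op − f_ant) − k_off,i · f_i

Occupancies remain in the simplex because the on-rates vanish at
`f_op + f_ant = 1`. Nalmefene kinetics are derived from naloxone's by
multiplying `k_on` and `k_off` by in-vitro nalmefene:naloxone ratios
(`r_on`, `r_off` in the bundle), keeping `n = 0.86` and `ke0` unchanged.
This single rule is how the package represents nalmefene's higher receptor
affinity; `scale_nalmefene` takes the ratios as explicit arguments so tests
never depend on their numeric values.

## Cardiorespiratory model

The published equation set behind the original cardiorespiratory component
is not reproduced here; the `physiology` module ships a compact
self-authored model designed to the same contracts (the parameter file is a
pluggable bundle, so a transcription of the original constants can replace
it). Structure:

* **Ventilatory drives.** Central chemoreflex (first-order, τ = 180 s,
  driven by arterial CO2 through a two-stage transport-delay chain, gain
  1.2 L·min⁻¹·mmHg⁻¹ above a 37.56 mmHg threshold), peripheral chemoreflex
  (τ = 30 s, gain 0.6, potentiated by hypoxia), and a tonic wakefulness
  drive (2.1 L/min). Minute ventilation is the sum of the three drives,
  each multiplied by its occupancy-dependent suppression factor. Alveolar
  ventilation is 70% of minute ventilation (fixed dead-space fraction).
* **Gas exchange and transport.** Alveolar balances for CO2 and O2 with
  the 863 mmHg STPD/BTPS factor; linear blood CO2 content
  (0.0065 L·L⁻¹·mmHg⁻¹); Hill-type O2 content (Hb capacity 0.197 L/L,
  P50 26 mmHg, h = 2.7); lumped tissue stores (CO2 store 0.35 L/mmHg,
  tissue O2 store 6 L blood-equivalent) with metabolic rates anchored so
  that the normocapnic baseline (PaCO2 = 40.28 mmHg, ventilation ≈ 7 L/min,
  PaO2 ≈ 103 mmHg) is an exact fixed point. Metabolism shuts down smoothly
  only in deep tissue hypoxia, which keeps all contents positive.
* **Hypoxic feedbacks.** The peripheral drive is stimulated by hypoxia
  (exponential potentiation below ~60 mmHg) while the *central* drive is
  depressed by it (sigmoid midpoint 30 mmHg). The central depression is the
  lethal positive feedback: without it, unbounded CO2 drive growth would
  always restore ventilation and sustained opioid suppression could not
  produce arrest.
* **Circulation.** A cardiac performance state `E ∈ [0, 1]` decays
  exponentially (rate 0.01 s⁻¹) in proportion to the systemic O2-delivery
  deficit below a critical level (0.35 L O2/min) and recovers (0.004 s⁻¹)
  when delivery is restored. Total blood flow is a normalized sigmoid of
  `E` — the heart compensates until performance is low, then flow
  collapses. Cardiac arrest is total flow reaching 0.01 L/min (inclusive),
  detected by solver events and by linear interpolation on exported traces;
  it terminates the subject's simulation. The sigmoid keeps early failure
  reversible: restoring oxygenation before flow has collapsed lets `E`
  recover, which is what makes the rescue race meaningful.

**Occupancy–drive coupling.** All three drives are multiplied by
`1 − f_op^γ / (f_op^γ + f50^γ)` (γ = 6). Antagonist-bound receptors have no
effect. The population presets differ only in `f50`: 0.665 for chronic
(tolerant) users, 0.64 for opioid-naive subjects. The steepness creates a
threshold: below it CO2 feedback compensates hypoventilation; above it
ventilation falls far enough that hypoxic central depression and
O2-delivery deficit take over and the subject spirals to arrest unless an
antagonist displaces the opioid in time.

**Hypercapnic challenge.** `set_hypercapnic` moves exactly the two CO2
parameters (arterial setpoint 40.28 → 45.30 mmHg, inspired CO2 0 →
34 mmHg); the validation-protocol runner additionally sets inspired O2 to
356 mmHg (50% O2 mixture). The model then finds its own elevated
equilibrium (≈20.5 L/min, PaCO2 ≈ 48 mmHg) — the printed 45.30 mmHg is an
initialization anchor of the original code, not an equilibrium constraint
of this model.

## Overdose simulation

The opioid is an IV bolus at t = 0 from the subject's pre-dose steady
state. Rescue is event-driven: at the first *downward* crossing of minute
ventilation through 40% of the subject's own baseline, the antagonist dose
is scheduled 60 s later (product-preparation delay). "n simultaneous
doses" are one administration of the summed amount. One rescue per
subject; later crossings are ignored. Integration uses LSODA with
rtol 10⁻⁶ / atol 10⁻⁸ (config values) and terminal events for trigger and
arrest; the horizon defaults to 4 h, beyond which neither arrests (which
occur within tens of minutes) nor late re-depression (the antagonist
half-life question) change the endpoint in this model.

The validation protocol reproduces the hypercapnic remifentanil challenge:
gas mixture from t = 0, remifentanil 0.5 µg/kg bolus plus 0.175 µg/kg/min
infusion from 10 min, one IN antagonist dose at 25 min, monitoring to
46 min, opioid-naive preset, remifentanil steepness 0.75, nalmefene
absorption shifted. The simulated nadir falls at 25.5–25.6 min with
recovery only in the antagonist arms, and the nalmefene arm recovers
faster than the naloxone arm at matched times.

## Virtual population

Antagonist PK parameters vary log-normally between subjects with the
reported %CV magnitudes (variance `ln(1 + CV²)`, median at the typical
value); the naloxone zero-order dose fraction (151 %CV) is sampled on the
logit scale with matched log-variance so it stays in [0, 1]. Body weight is
log-normal around the 74.7 kg median with a 20% CV (assumed; the weight
distribution is not reported). Binding parameters are drawn either from a
vendored table (`bundle_file` mode, expecting the published 2000-set
distributions) or, by default, log-normally around the bundle point
estimates with 40 %CV on `k_on`/`k_off` and 3 %CV on `n` — a stand-in for
the published bootstrap uncertainty distributions. Nalmefene binding sets
are derived row-wise from the naloxone sets, so the two antagonists share
uncertainty structure. Opioid PK is typical-value; opioid uncertainty
enters through the binding draws. Everything is deterministic given the
seed, and populations export/import losslessly as one-row-per-subject CSV.

The synthetic-concentration generator applies proportional residual error
(`obs = truth × (1 + ε)`, `ε ~ N(0, σ²)`, truncated at 0) with σ² = 0.111
(33.3 %CV) as the nalmefene default; it is never applied inside the
mechanistic simulation. The parameter-recovery check fits CL and Vc by
least squares on log-concentrations against a rich *intravenous* design:
the central volume is weakly identified under slow intranasal absorption,
and the check's purpose is simulator/estimator consistency, not the
clinical sampling scheme.

## Bootstrap

Trial uncertainty follows the published design: 2500 subsamples of 400
drawn from the 2000 subjects (with replacement by default; a flag switches
to without-replacement, and with m ≪ N the difference is negligible),
summarized by the median and the 2.5th/97.5th percentiles (linear-
interpolation empirical quantiles). Reduced-scale runs shrink `m`
proportionally.

## Parameter bundle and calibration

All constants live in a schema-validated YAML bundle in which every entry
carries a provenance string. The shipped default
(`bundles/default_synthetic.yaml`) mixes published values — the two
antagonist population-PK tables, naloxone steepness 0.86, the shared
antagonist `ke0`, the printed remifentanil binding set — with clearly
labelled SYNTHETIC stand-ins for everything the source tables do not print:
opioid PK, opioid and naloxone `k_on`/`k_off`, the nalmefene scaling
ratios, `fu`, and the whole physiology block.

The synthetic constants were calibrated once, during model construction,
to qualitative structure: the severity ordering of the four opioid/dose
conditions, a typical chronic subject at the arrest boundary for 1.63 mg
fentanyl, carfentanil harder to reverse than fentanyl (slower `k_off`),
and the validation-protocol nadir at the antagonist time. They were then
frozen. The published per-scenario incidence percentages are *not*
calibration targets; reproducing them quantitatively requires the original
repository's opioid/physiology constants and 2000-set binding
distributions, plugged in as a replacement bundle.

## What passing tests do and do not show

The test suite establishes internal correctness (closed-form vs ODE
agreement, mass balance, occupancy bounds, fixed-point stability,
bootstrap behaviour, recovery of generating parameters) and the
trial-level orderings that constitute the scientific claim structure:
incidence decreases monotonically with simultaneous IN naloxone doses;
one dose of IN nalmefene prevents at least as many arrests as one dose of
IN naloxone; opioid-naive populations fare worse than chronic users;
antagonists never harm. Because the default bundle is partly synthetic,
absolute incidence values are illustrative, not estimates of the published
ones, and agreement of orderings does not validate the model against
clinical overdose data. Real-data features not emulated: within-subject PK
variability, covariates beyond weight, delayed/repeated opioid exposure,
co-intoxicants, CPR or post-arrest physiology, and withdrawal effects.

## Numerical choices and limitations

Solver LSODA, rtol 10⁻⁶ / atol 10⁻⁸; event-based trigger/arrest detection
(no grid scanning); dense output sampled at 5 s for nadir bookkeeping and
1 s for exported traces. The occupancy power `Ce^n` uses clipped
non-negative concentrations; `ka → λ` degeneracies in the closed form use a
series branch. Steady states are solved by bracketed root finding on
arterial CO2 with drive/oxygen self-consistency iterated to convergence.
Reduced problem sizes used by the packaged checks: 100 subjects per arm for
ordering tests and 150 per arm in the acceptance script (full design:
2000), with the bootstrap resample scaled to n/5. Known limitations: fixed
dead-space fraction (overstates alveolar ventilation at very low tidal
volumes), no CO2 narcosis, single lumped tissue compartment, and a
phenomenological cardiac-performance state in place of an explicit
cardiovascular network.
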