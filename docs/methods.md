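# Methods

## Model overview

`fontansim` simulates the palliated single-ventricle (Fontan, total
cavopulmonary connection) circulation as a closed-loop 0D lumped-parameter
network coupled to a steady-state oxygen transport layer.  The circulation
has eight nodes, each carrying a compliance: a single systemic ventricle
and common atrium (time-varying elastance chambers), the aorta/systemic
arteries, upper-body (SVC) and lower-body (IVC) venous pools, the Fontan
conduit, the pulmonary arteries (the TCPC junction), and the pulmonary
veins.  Five parallel resistive systemic beds (upper body, abdominal
organs, kidneys, lower extremities, coronary) connect the aorta to the
venous pools; the coronary bed drains directly into the common atrium, as
coronary venous return does in a single-ventricle heart.  Both cavae drain
to the pulmonary artery — the SVC directly, the IVC through the conduit —
and two parallel pulmonary branches return blood to the pulmonary veins
and atrium.  There is no subpulmonary pump.

Three shunts can be attached: the conduit-to-atrium **fenestration**
(open by default), **venovenous collaterals** (VVC, lower-body veins to
pulmonary veins), and **aortopulmonary collaterals** (APC, aorta to
pulmonary arteries).  All follow a linear conductance law Q = g dP by
default; an orifice exponent is available for the fenestration.

### Governing equations

Each compartment obeys dV/dt = Q_in − Q_out with P = (V − V0)/C; edges are
resistive (Q = dP/R), inertial (L dQ/dt = dP − R Q, giving the flow its own
state), valve (smoothed diode, below) or shunt.  Because every flow leaves
one node and enters another, total blood volume is conserved *exactly* by
construction; the integrator's drift is only its truncation error
(asserted < 0.1 % per run, observed ~1e-15).

Chambers follow P = E(t)(V − V0) + K dV/dt.  E(t) interpolates between
diastolic and end-systolic elastance with a normalized double-Hill
activation (rising Hill exponent 1.9, relaxation exponent 21.9, time
scales 0.269/0.452 of the beat), the standard waveform for 0D heart
models; the normalization guarantees E reaches e_max exactly once per
beat.  The atrium uses a short, late-offset activation so atrial systole
precedes ventricular systole.  The viscoelastic coefficient K is realised
in the ODE as a series resistance on the chamber's port edges, which keeps
the right-hand side explicit; reported chamber pressures apply the K dV/dt
term to the computed net inflow.  The approximation is exact whenever only
one port conducts, i.e. essentially everywhere except the brief
valve-transition intervals.

Valves are smoothed diodes,
Q = (dP + sqrt(dP² + w²) − w) / (2 R_fwd) (+ leak term),
continuous and monotone with smoothing width w = 0.02 mmHg: exactly zero
at dP = 0, Ohmic when open, and carrying at most w/(2 R_fwd) retrograde
flow when closed.  Smoothness was chosen over event detection so a stiff
adaptive integrator (LSODA, rtol 1e-6, atol 1e-8 mL, max step 20 ms) can
integrate the system without restarts.

### Limit cycle and initial condition

A scenario is integrated beat by beat until the beat-start state changes
by less than 1e-4 (relative max-norm) over one beat, capped at 200 beats;
the converged beat is resampled at 1 ms.  The initial volumes distribute
blood over the compliances at fixed class pressures (70 mmHg arterial,
12 mmHg systemic venous, 11 mmHg Fontan pathway, 9.5/9 mmHg pulmonary
venous/atrial); these are a numerical starting point, not a physiologic
assertion, **but** their product with the compliances fixes the conserved
total blood volume and therefore selects the operating point.  Warm starts
(used to accelerate sweeps and calibration) always rescale the inherited
volumes to the scenario's own nominal total for this reason.  Results are
additionally memoized by a hash of the fully resolved configuration, so
identical scenarios return bit-identical outputs.

## Oxygen transport

Oxygen is advected on the beat-averaged flow field (the model reports one
saturation per scenario, so intra-beat transport is not resolved).  Every
node's saturation is the flow-weighted mean of its incoming streams, with
two special stream rules: pulmonary-capillary edges deliver blood at the
fixed end-capillary saturation (default 98 %, a calibration degree of
freedom), and systemic-bed edges deliver arterial content minus the tissue
extraction.  Total consumption VO2I x BSA is distributed over the beds in
proportion to flow, so all beds return the same venous saturation and the
Fick identity VO2I = COI x (CaO2 − CvO2) x 10 closes exactly, with COI the
index of tissue-perfusing systemic flow (aortic output minus APC
recirculation) and contents given by CaO2 = Hb x 1.36 x SaO2/100 +
PaO2 x 0.0031 (PaO2 = 100, PvO2 = 40 mmHg fixed; the dissolved term is
~1.5 % of content, so this choice is far below the saturation tolerance).
Mixing saturations rather than contents across streams ignores the
dissolved-O2 difference between arterial and venous streams
(≲0.2 mL/dL, i.e. ≪0.1 saturation point).

The fixed point is solved by damped successive substitution (damping 0.9)
from the configured initial saturations (97 %/60 %) to 1e-12; because the
system is linear in the saturations at fixed flows, a direct linear solve
is also provided and the two routes agree to 1e-9 (a standing property
test).  The substitution tolerance is tighter than strictly necessary so
that this cross-check is meaningful.  If the demanded VO2I drives any
saturation negative, the solver reports the largest supportable VO2I
(obtained from two linear solves, exploiting that the minimum saturation
is affine in VO2I).

## Pharmacology

Dobutamine maps dose to multipliers interpolated linearly between anchors
at 0, 5 and 10 ug/kg/min: ventricular e_max rises, the systemic resistance
aggregate falls, and the **coronary bed resistance falls steeply**
(metabolic coronary vasodilation: myocardial oxygen demand scales with
contractility and the dilated coronary bed returns desaturated blood
directly to the atrium).  This coronary response is the mechanism by which
inotropy desaturates arterial blood in the collateral-laden Fontan
circulation — linear VVC/fenestration conductances alone keep the venous
admixture fraction nearly constant as output rises and cannot reproduce
an arterial desaturation of several points.  The heart-rate multiplier is
1 (the drug model modifies contractility and vascular tone only) and the
VO2I multiplier calibrates to ~1: the venous-saturation rise under
dobutamine is fully accounted for by the systemic flow increase.

SVR/PVR magnification ratios multiply the respective aggregates; all bed
and pulmonary-branch resistances derive from the aggregates at topology
build time, so scaling and the dose response are multiplicative and
commute.

## Ventricular function indices

From the converged beat: EF = (EDV − ESV)/EDV; the end-systolic point
maximizes P/(V − V0); Ea = end-systolic pressure / stroke volume;
Ees is reported as the chamber's configured end-systolic elastance (the
simulated truth; a two-afterload estimate is provided and agrees within
2 %); SW is the shoelace area of the loop; PVA adds the potential-energy
triangle between the ESPVR through (V0, 0) and the end-systolic point
(Suga's framework); SW/PVA is the mechanical efficiency.

## Calibration

The compartment-level constants are not uniquely identifiable from three
scenario operating points, so the registry ships one calibrated, versioned
parameter set.  Structural values (compliances, bed flow fractions, TCPC
resistances, activation shapes) were fixed at textbook-plausible values
for an adolescent Fontan patient (BSA 1.63 m2, Hb 15 g/dL, HR 80,
VO2I 125 mL/min/m2); the free parameters — diastolic ventricular
elastance, fenestration/VVC conductance, the APC conductance, the
pulmonary end-capillary saturation, and the dobutamine e_max / coronary
multipliers — were then fitted by bounded least squares so that the three
reference scenarios reproduce their arterial/venous saturation pairs:
(96, 62) % without collaterals, (92, 54) % with VVC + APC, and (88, 58) %
with VVC + APC under dobutamine 10 ug/kg/min, at baseline SVR/PVR of
0.9/0.05 mmHg.s/mL.  `calibrate_registry` exposes the same bounded
derivative-free machinery at run time (Powell on squared relative
residuals, early exit when all targets are already inside tolerance).

## What the model does and does not emulate

The model is a 0D idealization: chained lumped compartments stand in for
spatially distributed arterial trees, so wave propagation, regional
pulmonary branch asymmetry, respiratory modulation, gravity and baroreflex
control are absent.  Oxygen transport assumes a flat pulmonary
end-capillary saturation (no diffusion limitation or V/Q scatter), uniform
per-flow tissue extraction, and no hemoglobin-dissociation dynamics.
Passing tests therefore demonstrate internal consistency with the stated
equations and the calibrated operating points — not patient-level
predictive accuracy.

## Known limitations

* **Ees/Ea vs SW/PVA under inotropy.**  With the standard definitions
  above, SW/PVA = 1/(1 + PE/SW) is a monotonically increasing function of
  Ees/Ea for near-ideal loops (PE/SW ≈ Ea/2Ees).  A simultaneous rise of
  ventriculoarterial coupling and fall of mechanical efficiency under
  dobutamine is therefore outside this model class; simulations across the
  full dose-table range confirm the two indices never move oppositely.
* **Net cardiac output under inotropy.**  Once the dobutamine saturation
  pair (arterial down to 88 %, venous up to ~58 %) is imposed, the Fick
  balance forces systemic bed flow up (the arteriovenous gap narrows at
  fixed VO2I) while the arterial-saturation pin caps the shunted fraction
  of output; caval return = bed flow − shunted flow then rises slightly
  with dose.  An APC large enough to flip the sign drags venous saturation
  far below its collateral-baseline target through aortic steal, so a
  simultaneous net-CO fall is likewise outside the calibrated model class.
  The acceptance suite asserts both direction claims as stated; those two
  assertions are expected to fail and are the suite's only red results.
* Net cardiac output is measured at the TCPC anastomosis (SVC inflow plus
  conduit outflow into the pulmonary artery, i.e. after the fenestration
  offtake).
* The dobutamine dose grid is anchored at {0, 5, 10} ug/kg/min; doses
  beyond 10 are a range error by design.
* The two pulmonary branches are symmetric; the conduit joins the common
  TCPC junction rather than the right branch specifically (with lumped 0D
  branches and no asymmetry data the distinction has no observable
  consequence).

## Problem sizes

Scenario integrations run ~5-60 beats of a 0.75 s cycle at 1 ms output
sampling (state dimension 8); sweeps cover 6 PVR ratios x 2 doses x 3
collateral configurations.  These sizes were chosen to keep every
quantity's numerical error at least an order of magnitude below the
acceptance tolerances.
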