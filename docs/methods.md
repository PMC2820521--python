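# Methods

## Scope and model form

`spinesim` models the signaling cascade of a single dendritic spine of
a D1-receptor-expressing striatal medium spiny neuron, from two
prescribed inputs — intracellular free Ca²⁺ and extracellular dopamine
— to one output, the concentration of AMPA receptors anchored in the
post-synaptic membrane. The spine is treated as a homogeneous,
well-mixed volume; concentrations (µM) are the state variables and all
dynamics are deterministic mass-action ODEs. The glutamate→calcium
machinery (NMDA/AMPA channel flux, VGCCs, IP₃-receptor store release)
is deliberately outside the model: calcium is an imposed waveform.

Only two reaction forms exist. A binding reaction A + B ⇌ AB carries
(kf, kb); an enzymatic reaction is always integrated as its two
elementary steps E + S ⇌ ES → E + P with (kf, kb, kcat). The
Michaelis–Menten rate law is never substituted, because the
quasi-steady-state assumption fails in exactly the regime this model
lives in: enzyme and substrate concentrations are comparable, and a
large fraction of several enzymes is dynamically sequestered in ES
complexes (see "Enzyme burial" below).

Parameter-table conventions: a row specifying (Kd, τ) maps to
kb = 1/τ, kf = kb/Kd, preserving Kd = kb/kf exactly; a row specifying
(Km, kcat) maps to kb = 4·kcat and kf = (kb + kcat)/Km, the default
convention of the GENESIS/Kinetikit simulator, preserving
Km = (kb + kcat)/kf exactly.

## The parameter tables

The packaged tables (`src/spinesim/data/*.csv`) are a synthetic
reconstruction: the topology follows the published block diagram of
the cascade and the receptor-trafficking state diagram literally, and
the structural counts are enforced exactly — 72 reactions, 132
table-level rate parameters, 8 free DARPP-32 phospho-states. Reactions
expanded over phospho-states (the DARPP-32 cube, trafficking
duplicates) share a parameter set identified by a `param_id` column; a
shared set counts once toward the 132. Since the concrete numeric
values of the original supplementary tables were not available, the
free rate constants were hand-calibrated — as roughly a third of the
original model's parameters were — against the documented qualitative
behaviors: direction of plasticity for weak/strong calcium and
dopamine input, knockout and fixation phenotypes, loop bistability,
and the basal-dopamine study. A provenance column distinguishes
literature-anchored magnitudes from hand-tuned ones; it does not
affect computation.

Initial concentrations sit in physiological ranges (DARPP-32 50 µM,
CaM 10 µM, CaMKII 8 µM, PKA 2.5 µM, PP1 = PP2A = PP2B = 2 µM,
AMPA receptors 4 µM across cytosolic and bulk pools, anchor 2 µM;
basal Ca 0.06 µM, tonic dopamine 0.01 µM).

## Inputs

Transients are alpha functions α(t) = ((t−t₀)/τ)·exp(1−(t−t₀)/τ),
normalized to a maximum of exactly 1 at t = t₀ + τ. The calcium
protocol is a train of 8 spikes at 100 Hz repeated six times at 10 s
intervals; spikes combine by a pointwise maximum, not summation,
matching the saturating calcium transients measured in these neurons.
The dopamine protocol is one transient per repetition, combined the
same way. Default time constants: τ_ca = 30 ms (spine calcium
transients decay within tens of ms), τ_da = 0.5 s (fast-scan
voltammetry places striatal dopamine transients at several hundred ms
to ~1 s; the upper part of that range is used, and it matters — see
"Signal transmission" below). Canonical amplitudes: weak calcium
1 µM, strong calcium 10 µM, dopamine 1 µM. Both inputs are implemented
as clamped species whose value is imposed as a function of time; they
participate in reactions as reactants but have zero derivative.

## Signal transmission: why the receptor stage integrates

A chain of binding equilibria is linear, and a linear time-invariant
stage transmits only the time-average of its input. Six 1-µM dopamine
transients of width ~1 s spread over 60 s carry a time-averaged signal
of only a few times the 0.01 µM tonic level, no matter how the rate
constants are chosen. The model therefore (i) uses the upper
literature value for τ_da, and (ii) gives the dopamine-bound receptor
a ~10 s residence time, so that receptor occupancy integrates the six
pulses into a sustained signal, while the downstream Golf/AC5 stages
track quickly. The remaining amplification is nonlinear: cooperative
double-cAMP binding to the PKA holoenzyme, and the positive feedback
loop below. A consequence of the integrating receptor is that the
model is only weakly sensitive to ±0.5 s shifts between calcium and
dopamine input: the adenylyl-cyclase response correctly ranks
dopamine-after-calcium > simultaneous > dopamine-before-calcium
(calcium inhibition of AC5 overlaps the rising cyclase activity in the
latter cases), but the resulting difference in the plasticity ratio is
below 0.1% and its ordering is not resolved. This is a known
limitation, consistent with the observation that the timing effect on
plasticity is weak in this class of model.

## Enzyme burial

With 50 µM DARPP-32 against enzymes at 0.3–2.5 µM, any enzymatic
reaction whose Km is far below the substrate concentration holds most
of its enzyme in the ES complex. This has three consequences that
shaped the calibration. First, enzymes acting on DARPP-32 need large
Km values (25–60 µM) or they are simply titrated away — most
dramatically, a small-Km Thr34 phosphorylation would bury ~95% of free
PKA catalytic subunit in complexes with DARPP-32 and flatten every
PKA-dependent response. Second, a clamped *free* enzyme concentration
is an infinite reservoir: ES complexes form from it without depleting
anything, so the flux grows linearly in substrate forever. For this
reason the subsystem analysis clamps cAMP and Ca (true baths) but
carries active Cdk5 and active calcineurin as conserved total pools.
Third, Ca-activated enzymes can ratchet: an ES complex formed from the
Ca-bound enzyme cannot release its Ca, so high-affinity Ca activation
plus low-Km catalysis traps activity far above the Ca-binding
equilibrium. The calcium-activated PP2A arm therefore uses a moderate
Ca affinity (Kd 1.7 µM, slow release) and a large catalytic Km.

## The PKA–PP2A–Thr75 positive feedback loop

The loop is: PKA phosphorylates (activates) a PP2A population; active
PP2A dephosphorylates DARPP-32 at Thr75; phospho-Thr75 DARPP-32 binds
and sequesters the PKA catalytic subunit (Kd 0.2 µM). Dephosphorylating
Thr75 therefore releases PKA, which activates more PP2A. Two further
ingredients make the loop switch-like rather than graded:

* PP1 is the phosphatase that deactivates PP2Ap, and PP1 itself is
  inhibited by PKA products (phospho-Thr34 DARPP-32 and phospho-I-1).
  In the deep-inhibition regime PP1 ∝ 1/PKA, so the active-PP2A level
  scales like PKA², and the Thr75 dephosphorylation rate as a function
  of free phospho-Thr75 p behaves like p/(1+p/K)² — non-monotone, which
  is what permits multiple intersections with the Cdk5
  phosphorylation arm.
* Cdk5 phosphorylation of Thr75 saturates in its substrate, while at
  very high Thr75 occupancy its substrate pool empties, anchoring the
  low-PKA branch.

In the isolated subsystem (PKA forms, PP2A forms, Thr75/Thr34 DARPP-32
states, PP1 and their complexes; cAMP and Ca clamped; Cdk5 and
calcineurin as parameter totals), the model has, at total active Cdk5
0.5 µM, exactly three steady states (stable–unstable–stable in active
PKA) for cAMP between ≈0.6 and ≈1.3 µM and a single stable state
outside that window. A quasi-static cAMP sweep jumps up at ≈1.4 µM and
down at ≈0.55 µM. The window's cAMP threshold rises with the Cdk5
level, and the Cdk5 threshold of PKA shutdown shifts monotonically
when the loop's dissociation constant or catalytic constants are
scaled up to ten-fold — the threshold behavior itself persists across
all tested variants.

Embedded in the full network the loop is not permanently bistable:
the PKA→PDE negative feedback lets cAMP, and with it the loop, relax
back after stimulation, so plasticity measured at 10 minutes decays
slowly rather than persisting indefinitely.

## Steady-state machinery

Steady states are found by damped Newton iteration on the rate
equations with one row per conservation law replaced by the law's
residual; the replaced rows are chosen by QR with column pivoting on
the conservation matrix so the substituted set is never
rank-deficient (a singular pivot set admits spurious pseudo-solutions).
Conservation laws come from the exact left null space of the
stoichiometric matrix (sympy, integer-scaled), seeded with
moiety-composition vectors so the basis reads as total-protein sums.
Accepted states satisfy max |dy/dt| < 10⁻¹⁰ µM/s. Stability is
classified from the eigenvalues of the Jacobian projected onto the
stoichiometric subspace, so the zero modes contributed by conservation
laws cannot blur the call; |Re λ| < 10⁻⁸ s⁻¹ is labelled marginal.
Seeds are the relaxed base state, relaxed low- and high-PKA biased
configurations, Newton starts interpolated between distinct solutions,
and — when exactly two attractors are found — a bisection of the basin
boundary whose midpoint, after a short relaxation toward the saddle,
seeds the search for the unstable state. Relaxations integrate with
LSODA at rtol 10⁻⁹ / atol 10⁻¹³ until the residual falls below
10⁻⁸ µM/s; slow transients near the fold otherwise masquerade as
extra states.

## Experiments

`pre_equilibrate` integrates under constant basal inputs until
max |dy/dt| < 10⁻⁹ µM/s. `run` integrates the stimulus protocols with
LSODA at rtol 10⁻⁸ / atol 10⁻¹² µM, bounding the step to 5 ms inside
stimulus-active windows so the solver cannot leap over a 10 ms spike.
Synaptic efficacy is the membrane-anchored receptor pool (both
phospho-anchored states plus the transient dephosphorylated anchored
state) at 600 s divided by its value at t = 0; a 2400 s evaluation is
available for persistence checks. Fixation experiments clamp the named
active species at their pre-equilibrated values; for CaMKII the frozen
interconversion reactions are removed along with the clamp, because a
clamped complex is a bath and the autophosphorylation cycle would
otherwise silently drain calmodulin into it. Knockouts clamp every
state carrying the protein at zero, keeping all reactions (their
fluxes vanish). Plasticity maps iterate ratio evaluations over
amplitude grids, recording per-cell solver failures as NaN.

## What the packaged conditions do and do not show

The packaged tables reproduce, under the study conditions: LTD for
weak calcium (ratio ≈ 0.98), LTP for strong calcium (≈ 1.02), LTP for
dopamine with or without weak calcium (≈ 1.10–1.13), no change under
dopamine depletion (1.000 ± 0.001), loss of calcium-LTP and flattened
dopamine dependence in the DARPP-32 knockout, LTP everywhere when PP1
is fixed, loss of dopamine dependence when PKA is fixed, loss of
calcium-LTP when CaMKII is fixed, abolition of the weak-calcium Thr75
rise when the CK1→Cdk5 step is removed, and a doubling of resting
active PKA and phospho-receptor at 0.25 µM tonic dopamine with
conversion of the weak-calcium+dopamine LTP to LTD. Two documented
behaviors are not reproduced: the plasticity-ratio ordering of the
±0.5 s timing conditions (a <0.1% tie, see above), and conversion of
the strong-calcium LTP to LTD at elevated tonic dopamine (the
CaMKII→Ser831 arm, which is insensitive to basal dopamine, keeps that
input slightly potentiating). Amplitude magnitudes are generally
smaller than in the original study; directions and topology are the
calibrated properties.

Because inputs are prescribed waveforms on a homogeneous volume, the
simulations say nothing about spatial gradients, stochastic effects at
single-spine copy numbers, receptor desensitization, or the upstream
glutamate-to-calcium transformation; passing tests constrain the
cascade between the imposed calcium/dopamine and the trafficking
readout only.

## Numerical choices

* LSODA throughout (the system is stiff during stimulus windows and
  mild elsewhere); analytic Jacobian assembled from the elementary
  steps.
* Tolerances: runs rtol 10⁻⁸ / atol 10⁻¹² µM; steady-state relaxations
  10⁻⁹ / 10⁻¹³.
* Degenerate inputs: zero-amplitude protocols are valid (constant
  basal); a zero pre-stimulus membrane pool raises an error from the
  ratio rather than returning infinity; knockouts of absent proteins
  raise.
* Deduplication of steady states at 10⁻⁶ relative max-norm distance.
* All stochastic choices (fixture generation) take explicit seeds;
  model simulation itself is deterministic.
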