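# spinesim

Kinetic simulation of dopamine- and calcium-dependent synaptic
plasticity in the dendritic spine of a D1-receptor-expressing striatal
medium spiny neuron.

Corticostriatal synapses are bidirectionally plastic: cortical
(glutamatergic) stimulation alone depresses them (LTD), while the same
stimulation paired with dopamine — or strong calcium influx on its own —
potentiates them (LTP). `spinesim` implements a mass-action kinetic
model of the intracellular cascade that links the two inputs,
intracellular Ca²⁺ and extracellular dopamine, to the model's output:
the number of AMPA receptors anchored in the post-synaptic membrane.

The network contains 72 reactions over ~110 molecular states and
includes the D1R–Golf–AC5–cAMP–PKA axis with its PKA→PDE negative
feedback, the Ca–CaM branches (CaMKII with Thr286 autophosphorylation,
calcineurin/PP2B, CaM-stimulated PDE), calcium- and PKA-activated
PP2A, the CK1→Cdk5 route, an 8-state phosphorylation model of DARPP-32
over {Thr34, Thr75, Ser137}, PP1 inhibition by phospho-Thr34 and
phospho-I-1, and serial Ser845→Ser831 AMPA receptor phosphorylation
with anchor-mediated membrane insertion and removal.

## Model

Every reaction takes one of two elementary forms, integrated as stiff
ODEs in µM and seconds (no Michaelis–Menten shortcut):

```
binding     A + B  ⇌  AB                 d[AB]/dt = kf[A][B] − kb[AB]
enzymatic   E + S  ⇌  ES  →  E + P       (kf, kb, kcat)
```

Where tables give (Kd, τ) the constants are kb = 1/τ, kf = kb/Kd;
where they give (Km, kcat), kb = 4·kcat and kf = (kb + kcat)/Km
(the GENESIS/Kinetikit convention). Inputs are prescribed waveforms
built from the normalized alpha function α(t) = (t/τ)·e^(1−t/τ)
(maximum exactly 1 at t = τ): calcium spike trains combined by a
pointwise maximum, one dopamine transient per repetition.

Synaptic efficacy is the ratio of membrane-anchored AMPA receptors
10 minutes after stimulation onset to the pre-stimulus resting level
(LTP > 1 > LTD). A steady-state engine (conservation-reduced Newton
iteration with Jacobian-eigenvalue stability classification) analyzes
the PKA–PP2A–phospho-Thr75 positive feedback loop, which is bistable
for intermediate cAMP and shows hysteresis under quasi-static sweeps.

## Worked example

```python
from spinesim import build_network
from spinesim.experiments import pre_equilibrate, run, plasticity_ratio
from spinesim.stimulus import CalciumProtocol, DopamineProtocol

net = build_network()                      # the 72-reaction spine model
rest = pre_equilibrate(net)                # resting state at basal inputs

for label, ca, da in [("weak Ca", 1.0, 0.0), ("strong Ca", 10.0, 0.0),
                      ("weak Ca + DA", 1.0, 1.0)]:
    tc = run(net, CalciumProtocol(ca_amp=ca),
             DopamineProtocol(da_amp=da), t_end=600.0, y0=rest)
    print(f"{label:14s} ratio = {plasticity_ratio(tc).ratio:.3f}")
```

prints

```
weak Ca        ratio = 0.977
strong Ca      ratio = 1.021
weak Ca + DA   ratio = 1.104
```

— weak calcium input (1 µM trains) depresses the synapse, strong
calcium (10 µM) or weak calcium paired with a 1 µM dopamine transient
potentiates it. The steady-state engine shows the underlying switch:

```python
from spinesim.steady_state import pka_pp2a_thr75_subsystem, find_steady_states

sub = pka_pp2a_thr75_subsystem(net, camp=0.8, cdk5=0.5)
for s in find_steady_states(sub):
    print(s.stability, round(s.value(sub.network, "PKAc"), 4))
```

```
stable 0.0268
unstable 0.048
stable 0.1751
```

— two stable PKA activity levels separated by an unstable state: the
loop is bistable at intermediate cAMP.

## Command line

A thin CLI wraps the library:

```
spine-sim equilibrate -o rest.csv
spine-sim simulate -c experiment.yaml -o run.csv
spine-sim map -o map.csv
spine-sim hysteresis -o hyst.csv
spine-sim bifurcate --camp-range 0.2,1.6,15 -o bif.csv
spine-sim robustness -o robust.csv
spine-sim export-sbml -o model.xml
```

All outputs are annotated CSV; the model itself can be exported as
SBML Level 3 for cross-checking in independent simulators.

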