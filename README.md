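# tesgroup

Group-level dose optimization for transcranial electrical stimulation (tES).

Weak scalp currents modulate cortical excitability in proportion to the
component of the induced electric field along the cortical surface normal
(En). Choosing which electrodes to use and how much current to drive through
each — the *montage* — is a dose-optimization problem: a personalized montage
needs an individual MRI-derived head model, which is often unavailable in
clinical practice. `tesgroup` implements and evaluates the alternative:
optimize one montage for a *pool* of heads and quantify how well it
transfers to a new individual, compared against personalized, standard
template and single-donor montages. It is aimed at researchers in
computational neurostimulation who want to prototype and stress-test group
dosing strategies without access to proprietary head-model cohorts.

## The model

For a head with lead-field **K** (cortical nodes x electrodes, V/m per mA,
columns bipolar against a fixed Cz reference), target field En^trg, node
weights w and currents I (mA, Cz implicit), the fitness is the normalised
error relative to no intervention:

    NERNI = ( ||w ⊙ En^trg||² − ||w ⊙ (K I) − w ⊙ En^trg||² ) / ||w ⊙ En^trg||²

NERNI = 1 is a perfect fit, 0 is no stimulation, and poor montages go
negative. The group objective is the arithmetic mean of NERNI over the pool.
Optimization is hybrid: a genetic algorithm searches electrode subsets
(max 8 electrodes) while SLSQP solves the concave inner current problem
under safety constraints (|I| ≤ 2 mA per electrode including the reference,
total injected current ≤ 4 mA, balanced currents). Group montages are
evaluated by leave-one-out transfer, and transfer performance is related to
MRI-free anatomical features (geodesic scalp perimeters, tissue volumes)
through regression models.

Synthetic cohorts of 4-shell spherical head models (analytic Legendre-series
forward solution, 10-10 electrode positions, lognormal anatomical jitter)
stand in for MRI-derived cohorts; see `docs/methods.md` for what they do and
do not emulate.

## Worked example

`examples/optimize_single_subject.py` builds one synthetic head with a
left-prefrontal target patch (En target 0.25 V/m, weight 10; 0 V/m,
weight 2 elsewhere) and optimizes a personalized montage:

```
subject sub-00: optimized in 11 generations
montage (mA):
   AF3: +0.900
    C5: -0.669
    F1: +0.433
    F5: +1.231
    F7: -1.040
   FC1: +0.291
   FC3: +0.635
   Fpz: -1.013
  implicit Cz return: -0.768
total injected (anodal) current: 3.490 mA
NERNI = 0.9633  (1 = perfect fit, 0 = no stimulation)
<En> on target = 0.2417 V/m (target level 0.25 V/m)
```

The optimizer places anodes over the target (F5, AF3, FC3, ...) and returns
current through surrounding cathodes, drives the target region to almost the
requested 0.25 V/m, and stays inside every safety bound. Smooth spherical
heads are easy to fit, hence the high NERNI; on folded cortex typical values
are an order of magnitude lower.

The other examples cover the transfer study (`group_vs_individual_transfer.py`:
personalized > group > single-donor ordering, paired statistics, and the
concave NERNI-vs-⟨En⟩ dose-response) and anatomical prediction
(`anatomy_prediction.py`). A thin CLI wraps the same functions:

```bash
tesgroup simulate-cohort --n-subjects 6 --seed 1 --out cohort/
tesgroup optimize --subject cohort/sub-00.h5 --out montage --seed 1
tesgroup run-all --out study/ --seed 1
```

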