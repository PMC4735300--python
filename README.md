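# orscreen

Receptor-optimized odorant ligand discovery and olfactory receptor neuron
(ORN) termination-kinetics analysis.

Insect odorant receptors (e.g. *Drosophila* Or42b) are activated by many
structurally related odorants, but responses differ sharply in their
*termination kinetics*: most activators evoke a phasic burst that returns
to baseline within seconds, while *prolonged activators* drive a tonic
response of tens of spikes per second lasting minutes after a 0.5 s pulse
— and mask the receptor's response to subsequent stimuli.  Finding new
ligands (and especially prolonged activators) for a receptor is a virtual
screening problem; quantifying the kinetics is a spike-train analysis
problem.  `orscreen` implements both halves for computational
neuroethologists and cheminformaticians:

1. **Ligand discovery (QSAR screen).**  From a panel of odorants with
   measured activity (spikes/s above spontaneous rate), compute molecular
   descriptors x ∈ R^p (RDKit open 2-D set, or ingest any precomputed
   matrix), standardize, and select a small informative subset S by greedy
   Sequential Forward Selection (SFS).  The default step criterion is a
   shrunken Fisher separation score
   J(S) = Σ_{j∈S} (μ⁺_j − μ⁻_j)² / Σ_{j∈S} σ̃²_j,
   with within-class variances σ̃² shrunk halfway toward their
   across-descriptor median; a leave-one-out nearest-positive ranking AUC
   is available as an alternative criterion and as the subset evaluation
   metric.  An ε-regression SVM with RBF kernel
   f(x) = Σ_i a_i exp(−γ‖x − x_i‖²) + b is trained on the selected
   subspace, validated by repeated random k-fold cross-validation (4-fold
   × 100 repeats by default; 5-fold × 20 also preset) with per-repeat
   ROC/AUC against the binary activator labels, then applied to a compound
   library after physicochemical filtering (MW < 325, elements limited to
   C, O, N, H, S), yielding a ranked candidate list.

2. **Termination kinetics.**  From spike-time tables, per-trial binned
   firing rates are averaged into a timecourse (mean ± s.e.m.); the
   baseline-subtracted excess rate yields the phasic peak, the half-decay
   time t½, the tonic plateau (median excess after 30 s), the response
   duration (first sustained return below threshold), a
   prolonged/transient classification (duration ≥ 30 s), and masking
   indices 1 − (exposed probe response / control probe response) for
   pre-exposure experiments.

3. **Synthetic data.**  Seeded generators produce descriptor panels with
   planted informative subspaces, screening libraries with planted
   actives, and inhomogeneous-Poisson spike trains (thinning) with
   transient/prolonged/masking structure plus machine-readable ground
   truth, so the whole pipeline is testable without downloads.

## Worked example

```python
import orscreen as o
from orscreen.model import ReceptorLigandModel, SpikeKineticsModel

records, matrix, truth = o.gen_training_set(o.ChemSimConfig(seed=1))
model = ReceptorLigandModel.from_records(records, matrix)
res = model.fit(target_size=3)
cv = res.cross_validate(k=4, repeats=100, seed=0)
print(res.summary(cv))
```

```
Receptor ligand model (SFS + RBF-SVR)
==============================================
molecules:            47 (14 active / 33 inactive)
descriptors kept:     200 (of 200 raw)
selected subset:      3 descriptors
  D0149, D0100, D0006
fitness (fisher_separation):
  2.8737 -> 2.8033 -> 2.6744
SVR hyperparameters:  C=1 gamma=0.333333 epsilon=0.1
cross-validation:     4-fold x 100 repeats, mean AUC = 0.9996
```

The panel has 47 molecules, 14 of them active; SFS recovered exactly the
three descriptors in which the generator planted the active cluster
(compare `truth.informative_idx`), and the cross-validated mean AUC of
0.9996 says out-of-fold regression scores rank actives above inactives
almost perfectly.  The same `res` object clusters the odorants in the
selected subspace (`res.cluster().to_newick()`) and screens libraries
(`res.screen(...)`).

```python
trains, _ = o.gen_spike_trains(o.SpikeSimConfig(seed=8), "prolonged")
print(SpikeKineticsModel(trains).fit().summary())
```

```
Spike kinetics: synthetic_prolonged @ 1e-2 (20 trials)
==============================================
baseline rate:   7.93 spikes/s (sem 0.12)
phasic peak:     232.12 spikes/s excess at t = 0.50 s
half-decay time: 5.00 s
tonic plateau:   60.00 spikes/s excess
duration:        220.00 s
classification:  prolonged activator
```

The simulated odorant had a planted 60 spikes/s plateau lasting 220 s —
both recovered to within a fraction of a percent, and the response is
classified as a prolonged activator.

A command-line interface mirrors the stages
(`orscreen simulate|descriptors|select|cluster|train|validate|screen|kinetics|all`);
see `orscreen --help`.

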