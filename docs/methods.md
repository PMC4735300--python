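# Methods

This note documents the models, estimators and design choices behind
`orscreen`, and what the synthetic-data tests do and do not establish
about real data.

## Ligand-discovery pipeline

### Descriptors and preprocessing

Molecules enter as SMILES in delimited compound tables.  The built-in
descriptor set is RDKit's open 2-D collection (~210 descriptors;
`open_2d3d` adds a handful of shape descriptors from a seeded ETKDG
conformer).  The pipeline is descriptor-set agnostic: any numeric
molecules × descriptors table can be ingested instead, which is how a
proprietary suite's output would be used.

Cleaning drops descriptors whose missing fraction exceeds
`max_missing_frac` (default 0.2) or whose observed spread is below 1e-12,
then imputes remaining gaps with the column median — robust,
deterministic, and free of any model fitting inside preprocessing.
Scaling standardizes each column by its mean and *population* standard
deviation (ddof = 0; the convention matters only for tiny panels) and
stores the (center, spread) pairs so screening libraries are transformed
with the training statistics, never their own.  Scaling is on by default
and can be disabled; distance-based selection and the RBF kernel both
assume comparable column scales, which is why it defaults on.

### Sequential Forward Selection

SFS grows a descriptor subset greedily: every remaining descriptor is
scored joined to the current subset and the argmax is accepted, ties
breaking toward the lowest column index so runs are bit-reproducible.
Stopping is by fixed size (default 13, a practical subset size for
receptor models) or by plateau (stop when the step improvement is below
`plateau_tol`, default 1e-4).

Two step criteria are registered:

* **`fisher_separation` (default).**  Between-class over within-class
  scatter summed over the subset, with per-descriptor within-class
  variances shrunk 50 % toward their across-descriptor median.  The
  shrinkage is essential with few positives: an unshrunk Fisher ratio is
  won by whichever of hundreds of noise descriptors happens to draw a
  tiny class variance.  The score is continuous, so informative
  descriptors keep being preferred after the classes already separate.
* **`loo_nearest_positive_auc`.**  Each molecule is scored by its
  distance to the nearest *other* positive in the subset subspace; the
  criterion is the AUC of separating negatives from positives by that
  distance.  It is bounded, threshold-free and interpretable — and it is
  the metric `subset_fitness` reports for any subset — but as a *step
  criterion* it is discrete (granularity 1/(n⁺·n⁻)) and saturates at 1.0,
  after which steps tie and, on small panels, single lucky noise
  descriptors can outscore genuinely informative ones.  On the default
  synthetic panel (47 molecules, 3 informative of 200 descriptors, 3-spread
  effect) the AUC criterion recovers the planted subspace in roughly a
  third of runs, the shrunken Fisher criterion in essentially all —
  which is why Fisher is the default.  The registry accepts user
  criteria.

The plateau stop rule pairs naturally with the bounded AUC criterion; the
Fisher ratio typically peaks at the single best descriptor and declines
as denominators accumulate, so with `fisher_separation` the intended
mode is `fixed_size` (the default).

With only a handful of positives — e.g. isolating descriptors that
gather the 4 prolonged activators among 14 activators — exact recovery
of a planted 2-descriptor sub-cluster is information-limited to roughly
85 % of panel draws at the default effect size; the test suite asserts a
recovery *rate* rather than pretending single-seed certainty.

### Clustering

Odorants are clustered in the scaled selected subspace by agglomerative
clustering (default average linkage, Euclidean distance; both
configurable).  Rows are sorted by molecule id before linkage so leaf
order is deterministic, and trees export to Newick with merge heights as
branch lengths.

### SVM and cross-validation

The receptor model is an ε-regression SVM (RBF kernel) fit on the scaled
selected subspace with activity values (spikes/s above spontaneous) as
targets.  Defaults C = 1, γ = 1/|S|, ε = 0.1; no tuning is performed by
default, though a small seeded grid search is available.  Training rows
are canonically sorted by molecule id before fitting, which makes the fit
exactly invariant to input row order.  Prediction uses the package's own
kernel expansion over the serialized support vectors, evaluated row-wise,
so (a) a model file round-trips bitwise and (b) chunked screening
reproduces unchunked scores exactly.  Model files are JSON with full
float precision and a format tag.

Validation bridges regression scores to the binary activator labels:
repeated random k-fold CV (fold sizes differ by at most one; each repeat
a fresh seeded shuffle; presets 4-fold × 100 and 5-fold × 20) collects
out-of-fold scores, computes one ROC/AUC per repeat from the pooled
out-of-fold scores, and averages AUCs across repeats.  The AUC is the
exact all-pairs Mann–Whitney probability (ties ½), computed by the rank
identity; the ROC step curve is emitted for plotting.

Two caveats, both measured and deliberate:

* Selecting descriptors on the full labelled panel and then
  cross-validating only the SVM inherits the classic selection-leakage
  optimism; on label-independent data the full pipeline's CV AUC is
  ~0.75, not 0.5.  CV here validates the *trained model given the
  subset* — the same scope as the workflow it reproduces.
* Even with a label-independent subset, the mean CV AUC of a *single*
  47-molecule panel scatters widely around chance (s.d. ≈ 0.08, with a
  mild pessimistic bias of small-sample CV ranking; a label-shuffle
  control is unbiased).  Null behavior is therefore assessed as an
  average over panel draws.

### Screening

Library filters: average-mass MW strictly < 325 with implicit hydrogens,
an exclusive element whitelist {C, O, N, H, S}, multi-fragment SMILES
rejected as `multifragment`, unparseable ones as `parse` (soft failures,
never hard errors).  Survivors are scored with the trained model (library
descriptors ingested or computed; molecules missing a selected descriptor
fail as `descriptor`) and ranked by descending score with id tie-breaks.
Processing is chunked with constant memory per chunk and chunk-size
invariant output.

## Termination kinetics

Spike trains (one row per spike: trial, odorant, dilution, onset,
stimulus duration, spike time) are binned per trial (default 1 s bins
over the recording window, default [−30, 300] s) and averaged across
trials; dispersion is the across-trial s.e.m.  Binned counts conserve the
total spike count exactly.  The baseline is the mean pre-stimulus rate
over a window relative to onset (default [−10, 0) s).

From the excess rate (mean − baseline), all times relative to onset:

* **peak** — maximum excess within 5 s of onset (bin-center time).  A
  peak not exceeding `peak_significance` (default 3) times its own
  s.e.m. is treated as no response: all fields undefined, not prolonged.
* **t½** — left edge of the first bin after the peak with excess below
  half-peak.
* **duration** — left edge of the first run of `persistence_bins`
  (default 3) consecutive bins with excess below the return threshold
  (default max(2 × baseline s.e.m., 0.1 × peak)); censored at the
  recording end if no such run occurs.
* **plateau** — median excess over [onset + 30 s, onset + duration];
  undefined when the response ends before the plateau window opens.
* **prolonged** — duration ≥ `prolonged_threshold` (default 30 s).

These estimator definitions (bin width, windows, thresholds) are this
package's choices, each config-exposed; they reproduce transient returns
of a few seconds and, for tonic responses, the planted plateau magnitude
and duration to within a few percent on matched simulations.

Masking quantifies suppression of probe responses after pre-exposure:
per probe time, excess = rate in a 2 s probe window minus the immediately
preceding 2 s pre-probe window (a tonic pre-exposure plateau common to
both subtracts out), and the masking index is 1 − exposed/control excess,
clipped at 1, undefined where the control excess is non-positive.

## Synthetic data

Chemical fixtures operate directly in descriptor space: iid standard
normal descriptors; actives (round(0.3 × 47) = 14 by default) shifted by
3 spreads in 3 planted informative dimensions; 4 prolonged actives
additionally shifted in 2 dedicated kinetics dimensions; activity
60 × (1 + 0.1 · noise) spikes/s for actives (the tonic excess magnitude),
0 for inactives.  Placeholder structures are small valid filter-passing
SMILES; screening libraries plant actives at the training centroid (same
planted dimensions for the same seed) and, optionally, a deterministic
fraction of filter-violating structures.  Spike fixtures draw
inhomogeneous Poisson trains by thinning (bin-free, so downstream bin
choices cannot bias them) from r(t) = baseline + peak·e^(−t/τ)
(+ plateau on [0, plateau_duration] for prolonged profiles); defaults:
baseline 8 spikes/s, peak 200, τ 4 s (transient 1.5 s), plateau
60 spikes/s for 220 s in a [−30, 300] s window, 0.5 s stimulus.  Masking
experiments superimpose transient probe responses (default probes at 15 s
and 30 s, 5 trials) whose gain is multiplied by `masking_gain` (default
0.1) after prolonged pre-exposure.  Every generator is deterministic
under a fixed seed and returns machine-readable ground truth.

What passing tests show — and don't.  The generators emulate the
*geometry* the pipeline exploits (a compact active class in a few
descriptor dimensions; Poisson spiking around piecewise-smooth rates).
Real descriptor matrices are correlated and heavy-tailed, real panels
have measurement error in the activity values, and real spike trains
show refractoriness and adaptation; none of these are modelled, so the
synthetic results bound what the pipeline can do under favorable,
controlled conditions rather than forecast performance on any particular
receptor.

## Numerical and reproducibility choices

All tie-breaks are deterministic (lowest column index in SFS; id order in
ranking and clustering).  The AUC rank identity equals the all-pairs
enumeration exactly (half-integer tied ranks are exact binary floats).
Matrices and spike tables round-trip through text with
`float_precision="round_trip"`.  Pipeline runs persist per-stage
artifacts with input hashes; `--resume` reuses a stage only when its
inputs hash identically and refuses stale mixes.  Delimited outputs carry
a header comment with the resolved config hash (output paths excluded)
and seed; JSON and Newick artifacts, which have no comment syntax, are
covered by the run manifest instead.

Problem sizes used by the test suite and acceptance script (47-molecule
panels, 200 descriptors, 5,000-compound libraries, 20-trial spike
simulations, 100-seed recovery sweeps) are desk-scale choices that keep a
full run in tens of seconds while leaving every statistical conclusion
comfortably powered.

## Known limitations

* The screen ranks by predicted agonism only; antagonists are not
  modelled (scores are unbounded reals and their negative tail is not
  calibrated against antagonism).
* No probability calibration, nested CV, or multi-receptor joint models.
* Kinetics estimation assumes a shared stimulus time and recording
  window across trials and does not model receptor biophysics; the
  prolonged/transient boundary (30 s) is a configurable convention, not
  a biological constant.
* 3-D descriptors use a single seeded conformer; no conformer ensembles.
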