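"""High-level modelling interface.

Two statsmodels-style pairs wrap the functional pipeline:

* :class:`ReceptorLigandModel` holds a compound panel (descriptor matrix,
  activity values, activator labels); ``fit()`` runs cleaning, scaling,
  Sequential Forward Selection and the RBF-SVR fit, returning a
  :class:`ReceptorLigandResults` that can cross-validate, cluster, predict
  and screen.
* :class:`SpikeKineticsModel` holds spike trains for one odorant;
  ``fit()`` bins the trials and extracts the termination-kinetics summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import kinetics as kin
from . import screening as scr
from . import selection as sel
from . import svm


class ReceptorLigandModel:
    """Receptor-optimized ligand model built from a compound panel.

    Parameters
    ----------
    matrix : DescriptorMatrix
        Raw (unscaled) molecules x descriptors table, computed or ingested.
    activity : array-like of float
        Measured activity per molecule (spikes/s above spontaneous).
    active_labels : array-like
        Binary activator labels (``active``/``inactive`` or bools).
    kinetics_labels : array-like, optional
        ``prolonged`` / ``transient`` / ``unknown`` per molecule.
    scale : bool
        Standardize descriptors before selection and fitting (default on).
    """

    def __init__(self, matrix, activity, active_labels, kinetics_labels=None,
                 scale=True, max_missing_frac=0.2):
        self.raw_matrix = matrix
        self.activity = np.asarray(activity, dtype=float)
        self.active_labels = sel._as_positive_mask(active_labels, matrix.n_molecules)
        self.kinetics_labels = (
            [str(v) for v in kinetics_labels] if kinetics_labels is not None else None
        )
        self.scale = scale
        self.max_missing_frac = max_missing_frac
        if self.activity.shape != (matrix.n_molecules,):
            raise ValueError("activity must have one value per molecule")

    @classmethod
    def from_records(cls, records, matrix, **kwargs):
        """Build from MoleculeRecords aligned with a descriptor matrix."""
        rows = matrix.rows_for_ids([r.id for r in records])
        m = matrix.take_rows(rows)
        activity = [r.activity if r.activity is not None else 0.0 for r in records]
        labels = [r.active_label == "active" for r in records]
        kin_labels = [r.kinetics_label for r in records]
        return cls(m, activity, labels, kinetics_labels=kin_labels, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, descriptor_columns=None, **kwargs):
        """Build from a tidy frame with id index, descriptor columns, and
        ``activity`` / ``active_label`` (/ ``kinetics_label``) columns."""
        meta = [c for c in ("activity", "active_label", "kinetics_label") if c in df.columns]
        if descriptor_columns is None:
            descriptor_columns = [c for c in df.columns if c not in meta]
        matrix = desc.DescriptorMatrix.from_frame(df[descriptor_columns])
        return cls(
            matrix,
            df["activity"].to_numpy(dtype=float),
            df["active_label"].to_numpy(),
            kinetics_labels=df["kinetics_label"] if "kinetics_label" in df.columns else None,
            **kwargs,
        )

    def prepare(self) -> desc.DescriptorMatrix:
        """Cleaned (and, by default, scaled) working matrix."""
        m = desc.clean_matrix(self.raw_matrix, self.max_missing_frac)
        return desc.scale_matrix(m) if self.scale else m

    def fit(self, target_size=13, stop_rule="fixed_size", plateau_tol=1e-4,
            hyperparams=None) -> "ReceptorLigandResults":
        work = self.prepare()
        subset = sel.sfs_select(
            work, self.active_labels, target_size=target_size,
            stop_rule=stop_rule, plateau_tol=plateau_tol,
        )
        trained = svm.train(work, subset, self.activity, hyperparams)
        return ReceptorLigandResults(self, work, subset, trained)


@dataclass
class ReceptorLigandResults:
    """Fitted subset + SVR with validation, clustering and screening."""

    model: ReceptorLigandModel
    matrix: desc.DescriptorMatrix  # cleaned/scaled working matrix
    subset: sel.DescriptorSubset
    trained: svm.TrainedModel

    def cross_validate(self, k=4, repeats=100, seed=0) -> svm.CVResult:
        return svm.cross_validate(
            self.matrix, self.subset, self.model.activity,
            self.model.active_labels, k=k, repeats=repeats, seed=seed,
            hyperparams=self.trained.hyperparams,
        )

    def predict(self, matrix: desc.DescriptorMatrix) -> np.ndarray:
        return svm.predict(self.trained, matrix)

    def fittedvalues(self) -> np.ndarray:
        return svm.predict(self.trained, self.matrix)

    def cluster(self, linkage="average", distance="euclidean") -> sel.OdorDendrogram:
        return sel.cluster_odorants(self.matrix, self.subset, linkage, distance)

    def kinetics_subset(self, target_size=13, **kwargs) -> sel.DescriptorSubset:
        if self.model.kinetics_labels is None:
            raise ValueError("model was built without kinetics labels")
        return sel.kinetics_subset(
            self.matrix, self.model.kinetics_labels, target_size=target_size, **kwargs
        )

    def screen(self, library, descriptors=None, **kwargs) -> scr.ScreenResult:
        return scr.screen(self.trained, library, descriptors=descriptors, **kwargs)

    def summary(self, cv: svm.CVResult | None = None) -> str:
        n_pos = int(self.model.active_labels.sum())
        hp = self.trained.hyperparams
        lines = [
            "Receptor ligand model (SFS + RBF-SVR)",
            "=" * 46,
            f"molecules:            {self.matrix.n_molecules}"
            f" ({n_pos} active / {self.matrix.n_molecules - n_pos} inactive)",
            f"descriptors kept:     {self.matrix.n_descriptors}"
            f" (of {self.model.raw_matrix.n_descriptors} raw)",
            f"selected subset:      {len(self.subset)} descriptors",
            f"  {', '.join(self.subset.selected)}",
            f"fitness ({self.subset.fitness_name}):",
            "  " + " -> ".join(f"{f:.4f}" for f in self.subset.fitness_trajectory),
            f"SVR hyperparameters:  C={hp.C:g} gamma={hp.gamma:.6g} epsilon={hp.epsilon:g}",
        ]
        if cv is not None:
            lines.append(
                f"cross-validation:     {cv.k}-fold x {cv.repeats} repeats, "
                f"mean AUC = {cv.mean_auc:.4f}"
            )
        return "\n".join(lines)

    def plot_roc(self, cv: svm.CVResult, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(cv.pooled_roc[:, 0], cv.pooled_roc[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"Pooled ROC, mean AUC = {cv.mean_auc:.3f}")
        return ax


class SpikeKineticsModel:
    """Termination-kinetics estimation for one odorant's spike trains."""

    def __init__(self, trials, bin_width=1.0, baseline_window=(-10.0, 0.0),
                 config: kin.KineticsConfig | None = None):
        if not trials:
            raise ValueError("SpikeKineticsModel needs at least one trial")
        self.trials = list(trials)
        self.bin_width = bin_width
        self.baseline_window = baseline_window
        self.config = config or kin.KineticsConfig()

    def fit(self) -> "SpikeKineticsResults":
        tc = kin.rate_timecourse(self.trials, self.bin_width, self.baseline_window)
        summary = kin.kinetics_summary(tc, self.config)
        return SpikeKineticsResults(self, tc, summary)


@dataclass
class SpikeKineticsResults:
    model: SpikeKineticsModel
    timecourse: kin.RateTimecourse
    kinetics: kin.KineticsSummary

    def summary(self) -> str:
        tr = self.model.trials[0]
        k = self.kinetics

        def fmt(v, unit):
            return f"{v:.2f} {unit}" if v is not None else "undefined"

        return "\n".join(
            [
                f"Spike kinetics: {tr.odorant} @ {tr.dilution}"
                f" ({self.timecourse.n_trials} trials)",
                "=" * 46,
                f"baseline rate:   {self.timecourse.baseline_rate:.2f} spikes/s"
                f" (sem {self.timecourse.baseline_sem:.2f})",
                f"phasic peak:     {fmt(k.peak_rate, 'spikes/s excess')} at t = {fmt(k.t_peak, 's')}",
                f"half-decay time: {fmt(k.t_half, 's')}",
                f"tonic plateau:   {fmt(k.plateau_rate, 'spikes/s excess')}",
                f"duration:        {fmt(k.duration, 's')}"
                + (" (censored at recording end)" if k.duration_censored else ""),
                f"classification:  {'prolonged activator' if k.prolonged else 'transient'}",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        tr = self.model.trials[0]
        k = self.kinetics
        return pd.DataFrame(
            [
                {
                    "odorant": tr.odorant,
                    "dilution": tr.dilution,
                    "n_trials": self.timecourse.n_trials,
                    "baseline_rate": self.timecourse.baseline_rate,
                    "peak_rate": k.peak_rate,
                    "t_peak": k.t_peak,
                    "t_half": k.t_half,
                    "plateau_rate": k.plateau_rate,
                    "duration": k.duration,
                    "prolonged": k.prolonged,
                }
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.timecourse
        ax.step(tc.bin_centers, tc.mean_rate, where="mid")
        ax.fill_between(
            tc.bin_centers, tc.mean_rate - tc.sem_rate, tc.mean_rate + tc.sem_rate,
            alpha=0.3, step="mid",
        )
        ax.axhline(tc.baseline_rate, ls="--", c="grey", lw=0.8)
        ax.axvline(tc.onset, c="k", lw=0.8)
        ax.set_xlabel("Time (s)")
        ax.set_ylabel("Firing rate (spikes/s)")
        return ax
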