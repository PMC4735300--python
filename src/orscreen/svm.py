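"""RBF-kernel support vector regression over a selected descriptor subspace.

The receptor model is an epsilon-regression SVM on the scaled, selected
descriptors: training targets are measured activity values (spikes/s above
spontaneous), while predictive ability is validated by ranking out-of-fold
regression scores against the binary activator labels with ROC/AUC, over
repeated random k-fold partitions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVR

from ._metrics import rank_auc, roc_points
from .descriptors import DescriptorMatrix, Scaling
from .selection import DescriptorSubset, _as_positive_mask

MODEL_FORMAT = "orscreen-svm/1"

#: CV presets: 4-fold x 100 repeats and 5-fold x 20 repeats
CV_PRESETS = {"fold4x100": (4, 100), "fold5x20": (5, 20)}


@dataclass
class Hyperparams:
    """RBF-SVR hyperparameters; ``gamma=None`` resolves to 1/n_descriptors."""

    C: float = 1.0
    gamma: float | None = None
    epsilon: float = 0.1

    def resolve(self, n_descriptors: int) -> "Hyperparams":
        g = self.gamma if self.gamma is not None else 1.0 / n_descriptors
        return Hyperparams(C=float(self.C), gamma=float(g), epsilon=float(self.epsilon))


def _subset_names(subset) -> list[str]:
    return list(subset.selected) if isinstance(subset, DescriptorSubset) else list(subset)


@dataclass
class TrainedModel:
    """Serializable RBF-SVR: support vectors, dual coefficients, intercept.

    Prediction is the package's own kernel expansion
    ``f(x) = sum_i a_i exp(-gamma ||x - sv_i||^2) + b`` over the stored
    payload, so a serialization round-trip reproduces scores bitwise.
    """

    descriptor_names: list[str]
    hyperparams: Hyperparams
    scaling: Scaling
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    training_hash: str
    kernel: str = "rbf"
    format: str = MODEL_FORMAT

    def predict_values(self, x_scaled: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x_scaled, dtype=float))
        k = np.exp(-self.hyperparams.gamma * cdist(x, self.support_vectors, "sqeuclidean"))
        # row-wise dot: scores are bitwise independent of batch size, so
        # chunked screening reproduces unchunked scores exactly
        scores = np.fromiter(
            (np.dot(row, self.dual_coef) for row in k), dtype=float, count=len(k)
        )
        return scores + self.intercept

    def save(self, path: str | Path) -> None:
        payload = {
            "format": self.format,
            "kernel": self.kernel,
            "hyperparams": {
                "C": self.hyperparams.C,
                "gamma": self.hyperparams.gamma,
                "epsilon": self.hyperparams.epsilon,
            },
            "descriptor_names": self.descriptor_names,
            "scaling": self.scaling.to_dict(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "training_hash": self.training_hash,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != MODEL_FORMAT:
            raise ValueError(f"unsupported model format {d.get('format')!r}")
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            hyperparams=Hyperparams(**d["hyperparams"]),
            scaling=Scaling.from_dict(d["scaling"]),
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            training_hash=d["training_hash"],
            kernel=d["kernel"],
        )


def train(
    m: DescriptorMatrix,
    subset,
    targets,
    hyperparams: Hyperparams | None = None,
) -> TrainedModel:
    """Fit the epsilon-regression RBF SVM on the scaled subset subspace.

    ``m`` must carry scaling metadata (train on the scaled matrix) so the
    stored model can transform raw screening libraries with the training
    statistics.  Rows are canonically ordered by molecule id before the fit,
    so the result is invariant to input row order.
    """
    names = _subset_names(subset)
    if m.n_molecules < 3:
        raise ValueError("train needs at least 3 molecules")
    if m.scaling is None:
        raise ValueError("train requires a scaled matrix (scaling metadata missing)")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (m.n_molecules,):
        raise ValueError("targets must have one value per molecule")
    if not np.isfinite(targets).all():
        raise ValueError("targets must be finite")

    hp = (hyperparams or Hyperparams()).resolve(len(names))
    order = np.argsort(np.asarray(m.molecule_ids, dtype=object))
    x = m.columns(names)[order]
    y = targets[order]
    svr = SVR(kernel="rbf", C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon, tol=1e-6)
    svr.fit(x, y)
    digest = hashlib.sha256()
    digest.update(",".join(sorted(m.molecule_ids)).encode())
    digest.update(np.ascontiguousarray(x).tobytes())
    digest.update(np.ascontiguousarray(y).tobytes())
    return TrainedModel(
        descriptor_names=names,
        hyperparams=hp,
        scaling=m.scaling.subset(names),
        support_vectors=svr.support_vectors_.copy(),
        dual_coef=svr.dual_coef_[0].copy(),
        intercept=float(svr.intercept_[0]),
        training_hash=digest.hexdigest(),
    )


def predict(model: TrainedModel, m: DescriptorMatrix) -> np.ndarray:
    """Score molecules (higher = stronger predicted agonism), input order.

    If ``m`` has no scaling metadata its values are taken as raw and the
    model's stored training scaling is applied; a matrix carrying scaling
    metadata is taken as already scaled.
    """
    missing = [n for n in model.descriptor_names if n not in m.descriptor_names]
    if missing:
        raise KeyError(f"matrix lacks selected descriptor(s): {missing}")
    x = m.columns(model.descriptor_names)
    if m.scaling is None:
        x = model.scaling.transform(x, model.descriptor_names)
    if m.n_molecules == 0:
        return np.zeros(0)
    return model.predict_values(x)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC step curve and all-pairs AUC (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    positive = _as_positive_mask(labels, scores.size)
    return roc_points(scores, positive), rank_auc(scores, positive)


@dataclass
class CVResult:
    """Repeated k-fold cross-validation outcome."""

    k: int
    repeats: int
    seed: int
    molecule_ids: list[str]
    fold_assignments: np.ndarray  # (repeats, n) fold index per molecule
    oof_scores: np.ndarray  # (repeats, n) out-of-fold prediction
    aucs: np.ndarray  # (repeats,)
    mean_auc: float
    pooled_roc: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"repeat": np.arange(self.repeats), "auc": self.aucs})

    def save(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# k={self.k} repeats={self.repeats} seed={self.seed} "
                     f"mean_auc={self.mean_auc!r}\n")
            df.to_csv(fh, index=False)


def cross_validate(
    m: DescriptorMatrix,
    subset,
    targets,
    labels,
    k: int = 4,
    repeats: int = 100,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
) -> CVResult:
    """Repeated random k-fold CV with per-repeat ROC/AUC.

    Each repeat draws a fresh seeded shuffle, splits molecules into k folds
    whose sizes differ by at most one, collects out-of-fold regression
    scores, and computes one AUC from the pooled out-of-fold scores against
    the binary labels.  ``mean_auc`` averages the per-repeat AUCs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = m.n_molecules
    if k > n:
        raise ValueError("k cannot exceed the number of molecules")
    targets = np.asarray(targets, dtype=float)
    positive = _as_positive_mask(labels, n)
    if positive.sum() == 0 or (~positive).sum() == 0:
        raise ValueError("cross_validate requires both classes present")

    rng = np.random.default_rng(seed)
    fold_assignments = np.zeros((repeats, n), dtype=int)
    oof = np.zeros((repeats, n))
    aucs = np.zeros(repeats)
    for r in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, test_rows in enumerate(folds):
            fold_assignments[r, test_rows] = f
            train_rows = np.setdiff1d(perm, test_rows)
            model = train(m.take_rows(train_rows), subset, targets[train_rows], hyperparams)
            oof[r, test_rows] = predict(model, m.take_rows(test_rows))
        aucs[r] = rank_auc(oof[r], positive)
    pooled = roc_points(oof.ravel(), np.tile(positive, repeats))
    return CVResult(
        k=k,
        repeats=repeats,
        seed=seed,
        molecule_ids=list(m.molecule_ids),
        fold_assignments=fold_assignments,
        oof_scores=oof,
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        pooled_roc=pooled,
    )


def grid_search(
    m: DescriptorMatrix,
    subset,
    targets,
    labels,
    grid: Sequence[Hyperparams] | None = None,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Optional small seeded grid search by mean CV AUC (off by default)."""
    names = _subset_names(subset)
    g0 = 1.0 / len(names)
    if grid is None:
        grid = [
            Hyperparams(C=c, gamma=g, epsilon=0.1)
            for c in (0.1, 1.0, 10.0)
            for g in (0.1 * g0, g0, 10.0 * g0)
        ]
    rows = []
    for hp in grid:
        cv = cross_validate(m, subset, targets, labels, k=k, repeats=repeats,
                            seed=seed, hyperparams=hp)
        rows.append({"C": hp.C, "gamma": hp.resolve(len(names)).gamma,
                     "epsilon": hp.epsilon, "mean_auc": cv.mean_auc})
    table = pd.DataFrame(rows)
    best = table["mean_auc"].idxmax()
    best_hp = grid[int(best)]
    return best_hp, table
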