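"""Sequential Forward Selection of a receptor-optimized descriptor subset.

The greedy loop grows a descriptor subset one column at a time, each step
adding the descriptor that maximizes a subset fitness.  The default fitness
rewards compactness of the active class in the selected subspace: each
molecule is scored by its distance to the nearest *other* positive, and the
fitness is the AUC of separating negatives (far from the active cluster)
from positives (inside it).  The same machinery, restricted to activators,
isolates descriptors that gather prolonged (tonic) activators together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage

from ._metrics import rank_auc
from .descriptors import DescriptorMatrix


def _as_positive_mask(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError(f"labels must have one entry per molecule ({n})")
    if labels.dtype.kind in "bi":
        return labels.astype(bool)
    mask = np.zeros(n, dtype=bool)
    for i, v in enumerate(labels):
        s = str(v)
        if s in ("positive", "active", "prolonged", "True", "1"):
            mask[i] = True
        elif s in ("negative", "inactive", "transient", "False", "0"):
            mask[i] = False
        else:
            raise ValueError(f"unrecognized label {v!r}")
    return mask


def _nearest_positive(d2: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Per-molecule distance to the nearest positive other than itself."""
    pos_idx = np.where(positive)[0]
    sub = d2[:, pos_idx]  # fancy indexing copies
    sub[pos_idx, np.arange(pos_idx.size)] = np.inf  # exclude self
    return np.sqrt(sub.min(axis=1))


def _fitness_from_sqdist(d2: np.ndarray, positive: np.ndarray) -> float:
    """LOO nearest-positive distance AUC from a squared-distance matrix."""
    nearest = _nearest_positive(d2, positive)
    # small distance should rank positive above negative
    return rank_auc(-nearest, positive)


#: shrinkage weight pulling per-descriptor within-class variances toward
#: their across-descriptor median in the Fisher score
FISHER_SHRINKAGE = 0.5


def _fisher_terms(x: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-descriptor Fisher numerators and shrunken denominators."""
    num = (x[positive].mean(axis=0) - x[~positive].mean(axis=0)) ** 2
    den = x[positive].var(axis=0) + x[~positive].var(axis=0)
    den = (1 - FISHER_SHRINKAGE) * den + FISHER_SHRINKAGE * np.median(den)
    return num, den


def fisher_separation(m: DescriptorMatrix, labels, subset: Sequence[str]) -> float:
    """Shrunken Fisher separation of the classes in a descriptor subset.

    Between-class scatter over within-class scatter, summed over the
    subset's descriptors, with per-descriptor within-class variances
    shrunk halfway toward their across-descriptor median.  The shrinkage
    keeps small-sample variance estimates from dominating the ratio — with
    a handful of positives, a raw Fisher score is won by whichever noise
    descriptor happens to draw a tiny class variance.  Continuous and
    unbounded; higher = better separated.
    """
    if len(subset) == 0:
        raise ValueError("fisher_separation: empty subset")
    positive = _as_positive_mask(labels, m.n_molecules)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("fisher_separation needs at least 2 molecules per class")
    num, den = _fisher_terms(m.values, positive)
    idx = m.column_index(subset)
    return float(num[idx].sum() / den[idx].sum())


def subset_fitness(
    m: DescriptorMatrix, labels, subset: Sequence[str]
) -> float:
    """Leave-one-out nearest-positive ranking AUC of a descriptor subset.

    Range [0, 1]; 0.5 is chance, higher means the positive class is more
    compact and separated in the selected (scaled) subspace.
    """
    if len(subset) == 0:
        raise ValueError("subset_fitness: empty subset")
    positive = _as_positive_mask(labels, m.n_molecules)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("subset_fitness needs at least 2 molecules per class")
    x = m.columns(subset)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return _fitness_from_sqdist(d2, positive)


FITNESS_REGISTRY: dict[str, Callable[[DescriptorMatrix, object, Sequence[str]], float]] = {
    "fisher_separation": fisher_separation,
    "loo_nearest_positive_auc": subset_fitness,
}


@dataclass
class DescriptorSubset:
    """Ordered greedily selected descriptor names with the fitness trace."""

    selected: list[str]
    fitness_trajectory: list[float]
    fitness_name: str = "fisher_separation"
    target_size: int = 13

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate descriptors in subset")
        if len(self.selected) != len(self.fitness_trajectory):
            raise ValueError("trajectory length must match subset length")

    def __len__(self) -> int:
        return len(self.selected)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected": self.selected,
                    "fitness_trajectory": self.fitness_trajectory,
                    "fitness_name": self.fitness_name,
                    "target_size": self.target_size,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorSubset":
        return cls(**json.loads(Path(path).read_text()))


def sfs_select(
    m: DescriptorMatrix,
    labels,
    target_size: int = 13,
    stop_rule: str = "fixed_size",
    plateau_tol: float = 1e-4,
    fitness: str = "fisher_separation",
) -> DescriptorSubset:
    """Greedy Sequential Forward Selection of descriptors.

    At each step every remaining descriptor is evaluated joined to the
    current subset and the fitness argmax is accepted; ties break toward
    the lowest column index, making runs reproducible.
    ``stop_rule='plateau'`` stops before an accepted step would improve
    fitness by less than ``plateau_tol``.

    The default fitness is the shrunken Fisher separation
    (:func:`fisher_separation`): it is continuous, so informative
    descriptors keep being preferred after the classes already separate.
    The rank-based :func:`subset_fitness` is available as
    ``fitness='loo_nearest_positive_auc'`` but saturates at 1.0 and, being
    discrete, is prone to ties and to single lucky noise descriptors on
    small panels.
    """
    if stop_rule not in ("fixed_size", "plateau"):
        raise ValueError(f"unknown stop rule {stop_rule!r}")
    if fitness not in FITNESS_REGISTRY:
        raise ValueError(f"unknown fitness {fitness!r}; options: {sorted(FITNESS_REGISTRY)}")
    if target_size > m.n_descriptors:
        raise ValueError(
            f"target_size {target_size} exceeds {m.n_descriptors} descriptors"
        )
    positive = _as_positive_mask(labels, m.n_molecules)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("sfs_select needs at least 2 molecules per class")
    if fitness == "fisher_separation":
        selected, trajectory = _sfs_fisher(m, positive, target_size, stop_rule, plateau_tol)
    else:
        selected, trajectory = _sfs_loo_auc(m, positive, target_size, stop_rule, plateau_tol)
    return DescriptorSubset(
        [m.descriptor_names[j] for j in selected],
        trajectory,
        fitness_name=fitness,
        target_size=target_size,
    )


def _sfs_fisher(m, positive, target_size, stop_rule, plateau_tol):
    num_j, den_j = _fisher_terms(m.values, positive)
    remaining = list(range(m.n_descriptors))
    selected: list[int] = []
    trajectory: list[float] = []
    num = den = 0.0
    while len(selected) < target_size and remaining:
        best_j, best_fit = -1, -np.inf
        for j in remaining:  # ascending index: first max wins ties
            f = (num + num_j[j]) / (den + den_j[j])
            if f > best_fit:
                best_fit, best_j = f, j
        if stop_rule == "plateau" and trajectory and best_fit - trajectory[-1] < plateau_tol:
            break
        selected.append(best_j)
        trajectory.append(float(best_fit))
        num += num_j[best_j]
        den += den_j[best_j]
        remaining.remove(best_j)
    return selected, trajectory


def _sfs_loo_auc(m, positive, target_size, stop_rule, plateau_tol):
    """AUC-fitness greedy with an incrementally updated distance matrix."""
    x = m.values
    n = m.n_molecules
    d2_current = np.zeros((n, n))
    remaining = list(range(m.n_descriptors))
    selected: list[int] = []
    trajectory: list[float] = []
    while len(selected) < target_size and remaining:
        best_j, best_fit, best_d2 = -1, -np.inf, None
        for j in remaining:
            diff = x[:, j][:, None] - x[:, j][None, :]
            d2 = d2_current + diff * diff
            f = _fitness_from_sqdist(d2, positive)
            if f > best_fit:
                best_fit, best_j, best_d2 = f, j, d2
        if stop_rule == "plateau" and trajectory and best_fit - trajectory[-1] < plateau_tol:
            break
        selected.append(best_j)
        trajectory.append(float(best_fit))
        d2_current = best_d2
        remaining.remove(best_j)
    return selected, trajectory


def kinetics_subset(
    m: DescriptorMatrix,
    kinetics_labels,
    target_size: int = 13,
    stop_rule: str = "fixed_size",
    plateau_tol: float = 1e-4,
) -> DescriptorSubset:
    """SFS restricted to activators, positives = prolonged activators.

    ``kinetics_labels`` holds, per molecule of ``m``, one of
    ``prolonged`` / ``transient`` / ``unknown``; molecules labelled
    ``unknown`` (non-activators) are excluded from the selection.
    """
    kinetics_labels = [str(v) for v in kinetics_labels]
    if len(kinetics_labels) != m.n_molecules:
        raise ValueError("kinetics_labels must have one entry per molecule")
    rows = [i for i, v in enumerate(kinetics_labels) if v in ("prolonged", "transient")]
    labels = [kinetics_labels[i] == "prolonged" for i in rows]
    if sum(labels) < 2:
        raise ValueError("kinetics_subset needs at least 2 prolonged activators")
    if len(labels) - sum(labels) < 2:
        raise ValueError("kinetics_subset needs at least 2 transient activators")
    sub = m.take_rows(rows)
    return sfs_select(
        sub, np.asarray(labels), target_size=target_size,
        stop_rule=stop_rule, plateau_tol=plateau_tol,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering of odorants in the selected subspace

@dataclass
class OdorDendrogram:
    """Agglomerative clustering of odorants in a descriptor subspace."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    leaf_ids: list[str]
    leaf_order: list[int] = field(default_factory=list)
    linkage_name: str = "average"
    distance_name: str = "euclidean"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..n_clusters) aligned to ``leaf_ids``."""
        return fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.merges, self.leaf_ids)
        return str(tree).strip()

    def save_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def cluster_odorants(
    m: DescriptorMatrix,
    subset: DescriptorSubset | Sequence[str],
    linkage: str = "average",
    distance: str = "euclidean",
) -> OdorDendrogram:
    """Agglomerative clustering of molecules in the selected subspace.

    Rows are ordered by molecule id before clustering so leaf ordering is
    deterministic regardless of input order.
    """
    names = subset.selected if isinstance(subset, DescriptorSubset) else list(subset)
    if len(names) == 0:
        raise ValueError("cluster_odorants: empty descriptor subset")
    if m.n_molecules < 2:
        raise ValueError("cluster_odorants needs at least 2 molecules")
    order = np.argsort(np.asarray(m.molecule_ids, dtype=object))
    ms = m.take_rows(order)
    x = ms.columns(names)
    z = scipy_linkage(x, method=linkage, metric=distance)
    return OdorDendrogram(
        merges=z,
        leaf_ids=list(ms.molecule_ids),
        leaf_order=[int(i) for i in leaves_list(z)],
        linkage_name=linkage,
        distance_name=distance,
    )
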