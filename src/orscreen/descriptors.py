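"""Compound tables and molecular descriptor matrices.

A compound panel (odorants with measured receptor activity) enters as a
delimited table with a ``smiles`` column; descriptors are computed with
RDKit's open 2-D descriptor collection, or ingested pre-computed from a
numeric table.  Cleaning drops uninformative columns and imputes, scaling
stores the training statistics so screening libraries can be transformed
into the same space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ACTIVE_LABELS = ("active", "inactive", "unknown")
KINETICS_LABELS = ("transient", "prolonged", "unknown")

#: spread below which a raw column counts as constant
ZERO_SPREAD = 1e-12


@dataclass
class MoleculeRecord:
    """One compound: structure plus optional activity annotations.

    ``activity`` is the evoked firing-rate increase above spontaneous
    activity (spikes/s); ``kinetics_label`` distinguishes transient from
    prolonged (tonic) activators.
    """

    id: str
    smiles: str
    name: str | None = None
    activity: float | None = None
    active_label: str = "unknown"
    kinetics_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"molecule {self.id!r}: empty SMILES")
        if self.active_label not in ACTIVE_LABELS:
            raise ValueError(f"molecule {self.id!r}: bad active_label {self.active_label!r}")
        if self.kinetics_label not in KINETICS_LABELS:
            raise ValueError(f"molecule {self.id!r}: bad kinetics_label {self.kinetics_label!r}")


@dataclass
class Scaling:
    """Per-descriptor (center, spread) pairs keyed by descriptor name."""

    names: list[str]
    center: np.ndarray
    spread: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if not (len(self.names) == self.center.size == self.spread.size):
            raise ValueError("scaling names/center/spread length mismatch")

    def _index(self, names: Sequence[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"no scaling stored for descriptor(s) {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def subset(self, names: Sequence[str]) -> "Scaling":
        idx = self._index(names)
        return Scaling(list(names), self.center[idx].copy(), self.spread[idx].copy())

    def transform(self, values: np.ndarray, names: Sequence[str]) -> np.ndarray:
        idx = self._index(names)
        return (np.asarray(values, dtype=float) - self.center[idx]) / self.spread[idx]

    def inverse(self, values: np.ndarray, names: Sequence[str]) -> np.ndarray:
        idx = self._index(names)
        return np.asarray(values, dtype=float) * self.spread[idx] + self.center[idx]

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaling":
        return cls(list(d["names"]), np.array(d["center"]), np.array(d["spread"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Scaling":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors numeric table with scaling metadata."""

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    scaling: Scaling | None = None
    provenance: str = "ingested"
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.molecule_ids)} molecules x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("duplicate molecule ids")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"descriptor(s) not in matrix: {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def columns(self, names: Sequence[str]) -> np.ndarray:
        return self.values[:, self.column_index(names)]

    def take_rows(self, rows: Sequence[int]) -> "DescriptorMatrix":
        rows = np.asarray(rows, dtype=int)
        return DescriptorMatrix(
            [self.molecule_ids[i] for i in rows],
            list(self.descriptor_names),
            self.values[rows].copy(),
            scaling=self.scaling,
            provenance=self.provenance,
        )

    def rows_for_ids(self, ids: Sequence[str]) -> np.ndarray:
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        missing = [m for m in ids if m not in pos]
        if missing:
            raise KeyError(f"molecule id(s) not in matrix: {missing}")
        return np.array([pos[m] for m in ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "ingested") -> "DescriptorMatrix":
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            provenance=provenance,
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep=sep)
        if self.scaling is not None:
            self.scaling.save(_sidecar(path))

    @classmethod
    def read_csv(cls, path: str | Path, sep: str | None = None) -> "DescriptorMatrix":
        if sep is None:
            sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                         float_precision="round_trip")
        m = cls.from_frame(df)
        side = _sidecar(path)
        if side.exists():
            m.scaling = Scaling.load(side)
        return m


def _sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".scaling.json")


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


# ---------------------------------------------------------------------------
# compound table I/O

_OPTIONAL_COLUMNS = ("name", "activity", "active_label", "kinetics_label")


def parse_compounds(path: str | Path, sep: str | None = None) -> list[MoleculeRecord]:
    """Read a compound table (header: at least ``id`` and ``smiles``)."""
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "smiles": str}, comment="#")
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"compound table {path}: missing required column {col!r}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate molecule id {dup.iloc[0]!r} in {path}")
    records: list[MoleculeRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        smiles = d["smiles"]
        if not isinstance(smiles, str) or not smiles.strip():
            raise ValueError(f"{path}: missing SMILES in row {row_number}")
        kwargs: dict = {}
        for col in _OPTIONAL_COLUMNS:
            if col in d and not pd.isna(d[col]):
                kwargs[col] = d[col]
        if "activity" in kwargs:
            kwargs["activity"] = float(kwargs["activity"])
        records.append(MoleculeRecord(id=str(d["id"]), smiles=smiles.strip(), **kwargs))
    return records


def write_compounds(records: Iterable[MoleculeRecord], path: str | Path, sep: str = ",") -> None:
    rows = [
        {
            "id": r.id,
            "smiles": r.smiles,
            "name": r.name,
            "activity": r.activity,
            "active_label": r.active_label,
            "kinetics_label": r.kinetics_label,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# descriptor computation

DESCRIPTOR_SETS = ("open_2d", "open_2d3d")


def available_descriptors(descriptor_set: str = "open_2d") -> list[str]:
    names = [name for name, _ in Descriptors.descList]
    if descriptor_set == "open_2d":
        return names
    if descriptor_set == "open_2d3d":
        from rdkit.Chem import Descriptors3D

        return names + sorted(_descriptors3d_fns(Descriptors3D))
    raise ValueError(f"unknown descriptor set {descriptor_set!r}")


def _descriptors3d_fns(mod) -> dict:
    wanted = (
        "Asphericity",
        "Eccentricity",
        "InertialShapeFactor",
        "NPR1",
        "NPR2",
        "PMI1",
        "PMI2",
        "PMI3",
        "RadiusOfGyration",
        "SpherocityIndex",
    )
    return {n: getattr(mod, n) for n in wanted if hasattr(mod, n)}


def compute_descriptors(
    mols: Sequence[MoleculeRecord], descriptor_set: str = "open_2d"
) -> DescriptorMatrix:
    """Compute the open descriptor collection for each molecule.

    Descriptor failures (including non-finite outputs, or 3-D descriptors on
    molecules that cannot be embedded) become missing values; those columns
    are handled later by :func:`clean_matrix`.
    """
    if descriptor_set not in DESCRIPTOR_SETS:
        raise ValueError(f"unknown descriptor set {descriptor_set!r}")
    names = available_descriptors("open_2d")
    fns_2d = Descriptors.descList
    fns_3d: dict = {}
    if descriptor_set == "open_2d3d":
        from rdkit.Chem import AllChem, Descriptors3D

        fns_3d = _descriptors3d_fns(Descriptors3D)
        names = names + sorted(fns_3d)

    rows = np.full((len(mols), len(names)), np.nan)
    for i, rec in enumerate(mols):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for molecule {rec.id!r}: {rec.smiles!r}")
        for j, (_, fn) in enumerate(fns_2d):
            try:
                v = float(fn(mol))
            except Exception:
                continue
            if np.isfinite(v):
                rows[i, j] = v
        if fns_3d:
            molh = Chem.AddHs(mol)
            try:
                ok = AllChem.EmbedMolecule(molh, randomSeed=20160201) == 0
            except Exception:
                ok = False
            if ok:
                for j, nm in enumerate(sorted(fns_3d), start=len(fns_2d)):
                    try:
                        v = float(fns_3d[nm](molh))
                    except Exception:
                        continue
                    if np.isfinite(v):
                        rows[i, j] = v
    return DescriptorMatrix(
        [r.id for r in mols], names, rows, provenance="computed"
    )


# ---------------------------------------------------------------------------
# cleaning and scaling

def clean_matrix(m: DescriptorMatrix, max_missing_frac: float = 0.2) -> DescriptorMatrix:
    """Drop unusable descriptors and impute the remaining missing values.

    A descriptor is dropped when its missing fraction exceeds
    ``max_missing_frac`` or when its spread over the observed values is
    below ``ZERO_SPREAD``.  Remaining missing cells get the column median.
    """
    v = m.values
    n = m.n_molecules
    keep: list[int] = []
    drop_log: list[tuple[str, str]] = []
    for j, name in enumerate(m.descriptor_names):
        col = v[:, j]
        missing = np.isnan(col)
        frac = missing.sum() / max(n, 1)
        if frac > max_missing_frac:
            drop_log.append((name, f"missing_frac={frac:.3f}>{max_missing_frac}"))
            continue
        observed = col[~missing]
        if observed.size == 0 or float(np.std(observed)) < ZERO_SPREAD:
            drop_log.append((name, "zero_spread"))
            continue
        keep.append(j)
    if not keep:
        raise ValueError("clean_matrix: all descriptors dropped")
    out = v[:, keep].copy()
    for jj in range(out.shape[1]):
        col = out[:, jj]
        miss = np.isnan(col)
        if miss.any():
            col[miss] = np.median(col[~miss])
    for name, reason in drop_log:
        logger.info("clean_matrix: dropped %s (%s)", name, reason)
    return DescriptorMatrix(
        list(m.molecule_ids),
        [m.descriptor_names[j] for j in keep],
        out,
        provenance=m.provenance,
        drop_log=drop_log,
    )


def scale_matrix(m: DescriptorMatrix) -> DescriptorMatrix:
    """Center each column and divide by its population standard deviation."""
    v = m.values
    if np.isnan(v).any():
        raise ValueError("scale_matrix: matrix contains missing values; clean it first")
    center = v.mean(axis=0)
    spread = v.std(axis=0)  # population convention (ddof=0)
    if (spread < ZERO_SPREAD).any():
        bad = [m.descriptor_names[j] for j in np.where(spread < ZERO_SPREAD)[0]]
        raise ValueError(f"scale_matrix: zero-spread descriptor(s) {bad}; clean it first")
    scaling = Scaling(list(m.descriptor_names), center, spread)
    return DescriptorMatrix(
        list(m.molecule_ids),
        list(m.descriptor_names),
        (v - center) / spread,
        scaling=scaling,
        provenance=m.provenance,
        drop_log=list(m.drop_log),
    )


def apply_scaling(m: DescriptorMatrix, scaling: Scaling) -> DescriptorMatrix:
    """Transform a raw matrix with previously stored (training) statistics."""
    sub = scaling.subset(m.descriptor_names)
    return DescriptorMatrix(
        list(m.molecule_ids),
        list(m.descriptor_names),
        (m.values - sub.center) / sub.spread,
        scaling=sub,
        provenance=m.provenance,
    )
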