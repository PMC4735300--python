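"""Physicochemical library filtering and ranked virtual screening.

The screen mirrors the discovery workflow: keep only small molecules
(MW < 325, average atomic masses, implicit hydrogens included) built from
the element whitelist {C, O, N, H, S}, score the survivors with the trained
receptor model, and emit a ranked candidate list.  The library is processed
in chunks so arbitrarily large SMILES collections stream through with
constant memory per chunk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from .descriptors import DescriptorMatrix, MoleculeRecord, compute_descriptors
from .svm import TrainedModel, predict

DEFAULT_MW_MAX = 325.0
DEFAULT_ELEMENTS = frozenset({"C", "O", "N", "H", "S"})


@dataclass
class FilterDecision:
    passed: bool
    reason: str  # empty when passed
    mw: float | None = None


def filter_library(
    mols: Sequence[MoleculeRecord],
    mw_max: float = DEFAULT_MW_MAX,
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS,
) -> list[FilterDecision]:
    """Per-molecule pass/fail against the MW bound and element whitelist.

    Molecular weight uses average atomic masses with implicit hydrogens;
    the bound is strict (``mw < mw_max``).  Any atom outside the whitelist
    disqualifies; multi-fragment SMILES (salts/mixtures) fail with reason
    ``multifragment``; unparseable SMILES fail with reason ``parse``.
    """
    out: list[FilterDecision] = []
    for rec in mols:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            out.append(FilterDecision(False, "parse"))
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            out.append(FilterDecision(False, "multifragment"))
            continue
        mw = float(RDDescriptors.MolWt(mol))
        bad_element = None
        for atom in mol.GetAtoms():
            if atom.GetSymbol() not in allowed_elements:
                bad_element = atom.GetSymbol()
                break
            if atom.GetTotalNumHs() > 0 and "H" not in allowed_elements:
                bad_element = "H"
                break
        if bad_element is not None:
            out.append(FilterDecision(False, f"element {bad_element}", mw))
        elif not mw < mw_max:
            out.append(FilterDecision(False, f"mw {mw:.2f} >= {mw_max:g}", mw))
        else:
            out.append(FilterDecision(True, "", mw))
    return out


@dataclass
class ScreenResult:
    """Ranked screening output plus the rejected compounds."""

    table: pd.DataFrame  # columns: rank, id, smiles, score, mw, passed, reason
    library_size: int
    n_passed: int

    @property
    def ranked(self) -> pd.DataFrame:
        return self.table[self.table["passed"]].reset_index(drop=True)

    @property
    def rejected(self) -> pd.DataFrame:
        return self.table[~self.table["passed"]].reset_index(drop=True)

    def save(self, path: str | Path, rejected_path: str | Path | None = None) -> None:
        self.ranked.to_csv(path, sep="\t", index=False)
        if rejected_path is not None:
            self.rejected.to_csv(rejected_path, sep="\t", index=False)


def screen(
    model: TrainedModel,
    library: Sequence[MoleculeRecord],
    descriptors: DescriptorMatrix | None = None,
    descriptor_set: str = "open_2d",
    mw_max: float = DEFAULT_MW_MAX,
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS,
    chunk_size: int = 10_000,
) -> ScreenResult:
    """Filter, score and rank a compound library.

    Descriptors for passing molecules are taken from ``descriptors``
    (an ingested matrix keyed by molecule id) when given, otherwise
    computed from structure.  Ranks run 1..n_passed by descending score,
    ties broken by id; failed molecules carry their fail reason instead.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    frames: list[pd.DataFrame] = []
    for start in range(0, len(library), chunk_size):
        chunk = list(library[start:start + chunk_size])
        frames.append(
            _screen_chunk(model, chunk, descriptors, descriptor_set, mw_max, allowed_elements)
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = _empty_screen_frame()
    passed = table[table["passed"]].sort_values(
        ["score", "id"], ascending=[False, True], kind="mergesort"
    )
    passed = passed.assign(rank=np.arange(1, len(passed) + 1))
    failed = table[~table["passed"]].assign(rank=np.nan)
    out = pd.concat([passed, failed], ignore_index=True)
    out = out[["rank", "id", "smiles", "score", "mw", "passed", "reason"]]
    out["rank"] = out["rank"].astype("Int64")
    return ScreenResult(table=out, library_size=len(library), n_passed=len(passed))


def _empty_screen_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=str),
            "smiles": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "mw": pd.Series(dtype=float),
            "passed": pd.Series(dtype=bool),
            "reason": pd.Series(dtype=str),
        }
    )


def _screen_chunk(model, chunk, descriptors, descriptor_set, mw_max, allowed_elements):
    decisions = filter_library(chunk, mw_max=mw_max, allowed_elements=allowed_elements)
    rows = [
        {
            "id": rec.id,
            "smiles": rec.smiles,
            "score": np.nan,
            "mw": dec.mw if dec.mw is not None else np.nan,
            "passed": dec.passed,
            "reason": dec.reason,
        }
        for rec, dec in zip(chunk, decisions)
    ]
    passing_idx = [i for i, dec in enumerate(decisions) if dec.passed]
    if passing_idx:
        passing = [chunk[i] for i in passing_idx]
        if descriptors is not None:
            ids = [r.id for r in passing]
            try:
                sub = descriptors.take_rows(descriptors.rows_for_ids(ids))
            except KeyError as exc:
                raise KeyError(f"library descriptor matrix incomplete: {exc}") from exc
        else:
            sub = compute_descriptors(passing, descriptor_set=descriptor_set)
        x = sub.columns(model.descriptor_names)
        bad = np.isnan(x).any(axis=1)
        for local, i in enumerate(passing_idx):
            if bad[local]:
                rows[i]["passed"] = False
                rows[i]["reason"] = "descriptor"
        good = ~bad
        if good.any():
            scores = predict(model, sub.take_rows(np.where(good)[0]))
            for s, i in zip(scores, [passing_idx[j] for j in np.where(good)[0]]):
                rows[i]["score"] = float(s)
    if not rows:
        return _empty_screen_frame()
    df = pd.DataFrame(rows)
    return df.astype({"score": float, "mw": float, "passed": bool})
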