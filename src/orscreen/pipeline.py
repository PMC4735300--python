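"""End-to-end orchestration: train/validate, screen, kinetics runs.

A run is driven by a single config (YAML file or dict).  Every stage
persists its artifact under the run's output directory together with a
manifest of input hashes, so a rerun with ``resume=True`` skips stages
whose inputs are unchanged and refuses to mix stale artifacts with
changed inputs.  Output tables carry a header comment with the resolved
config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import descriptors as desc
from . import kinetics as kin
from . import screening as scr
from . import selection as sel
from . import svm
from .simulate import (
    ChemSimConfig,
    SpikeSimConfig,
    gen_library,
    gen_masking_experiment,
    gen_spike_trains,
    gen_training_set,
)

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Invalid input data (CLI exit code 3)."""


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "orscreen_run",
    "log_level": "INFO",
    "descriptors": {
        "compounds": None,
        "matrix": None,
        "descriptor_set": "open_2d",
        "max_missing_frac": 0.2,
        "scale": True,
    },
    "selection": {"target_size": 13, "stop_rule": "fixed_size", "plateau_tol": 1e-4},
    "svm": {"C": 1.0, "gamma": None, "epsilon": 0.1},
    "cv": {"k": 4, "repeats": 100, "seed": 0},
    "cluster": {"linkage": "average", "distance": "euclidean"},
    "screen": {
        "model": None,
        "library": None,
        "descriptors": None,
        "mw_max": 325.0,
        "elements": "C,O,N,H,S",
        "chunk_size": 10000,
    },
    "kinetics": {
        "spikes": None,
        "bin_width": 1.0,
        "baseline": (-10.0, 0.0),
        "prolonged_threshold": 30.0,
        "masking": None,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class RunConfig:
    """Resolved run configuration with a stable content hash."""

    def __init__(self, data: dict | None = None):
        self.data = _merge(_DEFAULTS, data or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls(raw)

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        payload = {k: v for k, v in self.data.items() if k not in ("outdir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def snapshot(self) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        path = self.outdir / "config.resolved.yaml"
        path.write_text(yaml.safe_dump(self.data, sort_keys=True))
        return path


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_hash(cfg: RunConfig, stage: str, input_files: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(cfg.data.get(stage, {}), sort_keys=True, default=str).encode())
    h.update(str(cfg.seed).encode())
    for p in input_files:
        h.update(_file_hash(p).encode())
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: dict = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def fresh(self, stage: str, inputs_hash: str, artifact: Path, resume: bool) -> bool:
        """True when the persisted artifact can be reused."""
        entry = self.data.get(stage)
        if entry is None or not Path(entry["artifact"]).exists():
            return False
        if entry["inputs"] != inputs_hash:
            if resume:
                raise ConfigError(
                    f"stage {stage!r}: inputs changed since the persisted artifact was "
                    "written; refusing to resume — rerun without --resume for a clean run"
                )
            return False
        return resume

    def record(self, stage: str, inputs_hash: str, artifact: Path) -> None:
        self.data[stage] = {"inputs": inputs_hash, "artifact": str(artifact)}
        self.path.write_text(json.dumps(self.data, indent=1))


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# orscreen config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False, sep=sep)


def _load_panel(cfg: RunConfig):
    dcfg = cfg["descriptors"]
    if dcfg["compounds"] is None:
        raise ConfigError("descriptors.compounds path is required")
    try:
        records = desc.parse_compounds(dcfg["compounds"])
    except (ValueError, OSError) as exc:
        raise DataError(str(exc)) from exc
    if dcfg["matrix"] is not None:
        matrix = desc.DescriptorMatrix.read_csv(dcfg["matrix"])
        matrix = matrix.take_rows(matrix.rows_for_ids([r.id for r in records]))
    else:
        matrix = desc.compute_descriptors(records, dcfg["descriptor_set"])
    return records, matrix


def run_train_validate(cfg: RunConfig, resume: bool = False) -> dict[str, Path]:
    """descriptors -> SFS -> cluster -> SVR -> repeated CV; persisted artifacts.

    Returns a dict of artifact paths: matrix, subset, dendrogram, model,
    cv_report, roc.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot()
    manifest = Manifest(out)
    records, raw = _load_panel(cfg)
    labels = np.array([r.active_label == "active" for r in records])
    activity = np.array([r.activity if r.activity is not None else 0.0 for r in records])
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise DataError("training panel needs at least 2 actives and 2 inactives")

    dcfg = cfg["descriptors"]
    input_files = [Path(dcfg["compounds"])]
    if dcfg["matrix"]:
        input_files.append(Path(dcfg["matrix"]))

    artifacts: dict[str, Path] = {}

    # stage: prepared (cleaned + scaled) matrix
    matrix_path = out / "matrix.csv"
    h = _stage_hash(cfg, "descriptors", input_files)
    if manifest.fresh("matrix", h, matrix_path, resume):
        logger.info("matrix: reusing persisted artifact")
        work = desc.DescriptorMatrix.read_csv(matrix_path)
    else:
        work = desc.clean_matrix(raw, dcfg["max_missing_frac"])
        if dcfg["scale"]:
            work = desc.scale_matrix(work)
        work.to_csv(matrix_path)
        manifest.record("matrix", h, matrix_path)
    artifacts["matrix"] = matrix_path

    # stage: SFS subset
    subset_path = out / "subset.json"
    h = _stage_hash(cfg, "selection", input_files)
    if manifest.fresh("subset", h, subset_path, resume):
        logger.info("subset: reusing persisted artifact")
        subset = sel.DescriptorSubset.load(subset_path)
    else:
        scfg = cfg["selection"]
        subset = sel.sfs_select(
            work, labels, target_size=int(scfg["target_size"]),
            stop_rule=scfg["stop_rule"], plateau_tol=float(scfg["plateau_tol"]),
        )
        subset.save(subset_path)
        manifest.record("subset", h, subset_path)
    artifacts["subset"] = subset_path

    # stage: dendrogram
    tree_path = out / "dendrogram.nwk"
    h = _stage_hash(cfg, "cluster", input_files + [subset_path])
    if manifest.fresh("dendrogram", h, tree_path, resume):
        logger.info("dendrogram: reusing persisted artifact")
    else:
        ccfg = cfg["cluster"]
        dendro = sel.cluster_odorants(work, subset, ccfg["linkage"], ccfg["distance"])
        dendro.save_newick(tree_path)
        manifest.record("dendrogram", h, tree_path)
    artifacts["dendrogram"] = tree_path

    # stage: SVR model
    model_path = out / "model.json"
    h = _stage_hash(cfg, "svm", input_files + [subset_path])
    if manifest.fresh("model", h, model_path, resume):
        logger.info("model: reusing persisted artifact")
        trained = svm.TrainedModel.load(model_path)
    else:
        vcfg = cfg["svm"]
        hp = svm.Hyperparams(
            C=float(vcfg["C"]),
            gamma=None if vcfg["gamma"] is None else float(vcfg["gamma"]),
            epsilon=float(vcfg["epsilon"]),
        )
        trained = svm.train(work, subset, activity, hp)
        trained.save(model_path)
        manifest.record("model", h, model_path)
    artifacts["model"] = model_path

    # stage: repeated cross-validation
    report_path = out / "cv_report.csv"
    roc_path = out / "roc.tsv"
    h = _stage_hash(cfg, "cv", input_files + [subset_path])
    if manifest.fresh("cv", h, report_path, resume):
        logger.info("cv: reusing persisted artifact")
    else:
        cvcfg = cfg["cv"]
        cv = svm.cross_validate(
            work, subset, activity, labels,
            k=int(cvcfg["k"]), repeats=int(cvcfg["repeats"]), seed=int(cvcfg["seed"]),
            hyperparams=trained.hyperparams,
        )
        _write_table(cv.to_frame(), report_path, cfg)
        _write_table(
            pd.DataFrame(cv.pooled_roc, columns=["fpr", "tpr"]), roc_path, cfg, sep="\t"
        )
        logger.info("cv: mean AUC %.4f over %d repeats", cv.mean_auc, cv.repeats)
        manifest.record("cv", h, report_path)
    artifacts["cv_report"] = report_path
    artifacts["roc"] = roc_path
    return artifacts


def run_screen(cfg: RunConfig) -> dict[str, Path]:
    """Filter + score + rank a library with a persisted model artifact."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot()
    scfg = cfg["screen"]
    model_path = scfg["model"] or (out / "model.json")
    if not Path(model_path).exists():
        raise ConfigError(f"screen: model artifact {model_path} not found")
    if scfg["library"] is None:
        raise ConfigError("screen.library path is required")
    trained = svm.TrainedModel.load(model_path)
    try:
        library = desc.parse_compounds(scfg["library"])
    except (ValueError, OSError) as exc:
        raise DataError(str(exc)) from exc
    lib_matrix = (
        desc.DescriptorMatrix.read_csv(scfg["descriptors"])
        if scfg["descriptors"]
        else None
    )
    elements = frozenset(str(scfg["elements"]).split(","))
    result = scr.screen(
        trained, library, descriptors=lib_matrix,
        mw_max=float(scfg["mw_max"]), allowed_elements=elements,
        chunk_size=int(scfg["chunk_size"]),
    )
    n_failed = result.library_size - result.n_passed
    logger.info(
        "screen: %d/%d passed filters (%d rejected)",
        result.n_passed, result.library_size, n_failed,
    )
    for reason, count in result.rejected["reason"].value_counts().items():
        logger.info("screen: attrition %-16s %d", reason, count)
    ranked_path = out / "ranked.tsv"
    rejected_path = out / "rejected.tsv"
    _write_table(result.ranked, ranked_path, cfg, sep="\t")
    _write_table(result.rejected, rejected_path, cfg, sep="\t")
    return {"ranked": ranked_path, "rejected": rejected_path}


def run_kinetics(cfg: RunConfig) -> dict[str, Path]:
    """Timecourses + kinetics summaries (one row per odorant x dilution)."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot()
    kcfg = cfg["kinetics"]
    if kcfg["spikes"] is None:
        raise ConfigError("kinetics.spikes path is required")
    try:
        trials = kin.read_spike_trains(kcfg["spikes"])
    except (ValueError, OSError) as exc:
        raise DataError(str(exc)) from exc
    if not trials:
        raise DataError("kinetics: no trials in spike table")
    kconfig = kin.KineticsConfig(prolonged_threshold=float(kcfg["prolonged_threshold"]))
    baseline = tuple(float(v) for v in kcfg["baseline"])
    groups: dict[tuple[str, str], list[kin.SpikeTrain]] = {}
    for tr in trials:
        groups.setdefault((tr.odorant, tr.dilution), []).append(tr)

    summaries = []
    artifacts: dict[str, Path] = {}
    for (odorant, dilution), g in groups.items():
        tc = kin.rate_timecourse(g, float(kcfg["bin_width"]), baseline)
        summary = kin.kinetics_summary(tc, kconfig)
        tc_path = out / f"timecourse_{odorant}_{dilution}.csv"
        _write_table(tc.to_frame(), tc_path, cfg)
        artifacts[f"timecourse_{odorant}_{dilution}"] = tc_path
        summaries.append(
            {
                "odorant": odorant,
                "dilution": dilution,
                "n_trials": tc.n_trials,
                "baseline_rate": tc.baseline_rate,
                "peak_rate": summary.peak_rate,
                "t_peak": summary.t_peak,
                "t_half": summary.t_half,
                "plateau_rate": summary.plateau_rate,
                "duration": summary.duration,
                "prolonged": summary.prolonged,
            }
        )
    summary_path = out / "kinetics_summary.csv"
    _write_table(pd.DataFrame(summaries), summary_path, cfg)
    artifacts["summary"] = summary_path

    mcfg = kcfg.get("masking")
    if mcfg:
        exposed = kin.read_spike_trains(mcfg["exposed"])
        control = kin.read_spike_trains(mcfg["control"])
        probe_times = [float(t) for t in mcfg.get("probe_times", (15.0, 30.0))]
        profile = kin.masking_profile_from_trains(exposed, control, probe_times)
        masking_path = out / "masking.csv"
        _write_table(profile.to_frame(), masking_path, cfg)
        artifacts["masking"] = masking_path
        logger.info("masking: mean index %.3f", profile.mean_index)
    return artifacts


def run_simulate(cfg: RunConfig, what: str) -> dict[str, Path]:
    """Write synthetic fixtures in the same formats the pipeline reads."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot()
    seed = cfg.seed
    artifacts: dict[str, Path] = {}
    if what == "chem":
        records, matrix, truth = gen_training_set(ChemSimConfig(seed=seed))
        desc.write_compounds(records, out / "compounds.csv")
        matrix.to_csv(out / "descriptors.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "informative_idx": truth.informative_idx.tolist(),
                    "kinetics_idx": truth.kinetics_idx.tolist(),
                    "active_ids": truth.active_ids,
                    "prolonged_ids": truth.prolonged_ids,
                }
            )
        )
        artifacts = {
            "compounds": out / "compounds.csv",
            "descriptors": out / "descriptors.csv",
            "ground_truth": out / "ground_truth.json",
        }
    elif what == "library":
        records, matrix, truth = gen_library(ChemSimConfig(seed=seed), fail_fraction=0.1)
        desc.write_compounds(records, out / "library.csv")
        matrix.to_csv(out / "library_descriptors.csv")
        (out / "library_ground_truth.json").write_text(
            json.dumps({"active_ids": truth.active_ids, "fail_ids": truth.fail_ids})
        )
        artifacts = {
            "library": out / "library.csv",
            "descriptors": out / "library_descriptors.csv",
            "ground_truth": out / "library_ground_truth.json",
        }
    elif what in ("spikes", "spikes_transient"):
        profile = "prolonged" if what == "spikes" else "transient"
        scfg = SpikeSimConfig(seed=seed)
        if profile == "transient":
            scfg = SpikeSimConfig(seed=seed, decay_tau=1.5)
        trains, _ = gen_spike_trains(scfg, profile)
        kin.write_spike_trains(trains, out / "spikes.csv")
        artifacts = {"spikes": out / "spikes.csv"}
    elif what == "masking":
        scfg = SpikeSimConfig(seed=seed)
        exposed, control, truth = gen_masking_experiment(scfg, "prolonged")
        kin.write_spike_trains(exposed, out / "spikes_exposed.csv")
        kin.write_spike_trains(control, out / "spikes_control.csv")
        artifacts = {
            "exposed": out / "spikes_exposed.csv",
            "control": out / "spikes_control.csv",
        }
    else:
        raise ConfigError(f"unknown simulation target {what!r}")
    return artifacts
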