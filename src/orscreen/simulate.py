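"""Synthetic fixtures for every stage of the pipeline.

Chemical fixtures operate directly in descriptor space: a minority active
class is shifted away from the bulk in a few planted informative
dimensions embedded among many uninformative standard-normal ones, with a
prolonged-kinetics sub-cluster planted in dedicated dimensions.  Spike
fixtures are inhomogeneous Poisson processes drawn by thinning from an
explicit rate function (phasic exponential decay, optional tonic plateau),
returned alongside the exact rate function so estimators can be checked
against ground truth.  Every generator is fully deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .descriptors import DescriptorMatrix, MoleculeRecord
from .kinetics import SPIKE_TIME_RESOLUTION, SpikeTrain

# valid small structures cycled through as placeholder SMILES; all pass the
# MW/element filters so chemistry plumbing works end to end
_PLACEHOLDER_SMILES = (
    "CCO", "CCC", "CC(C)O", "CCOC(C)=O", "CCCO", "CCCC", "COC", "CC(C)=O",
    "CCN", "CCS", "OCCO", "CC(N)=O",
)
# structures violating the screen filters (heavy alkane; halogenated ring)
_FAIL_SMILES = ("C" * 24, "Clc1ccccc1")

ACTIVITY_SCALE = 60.0  # spikes/s, tonic excess magnitude used for active labels


@dataclass
class ChemSimConfig:
    """Training-set generator settings (desk-scale stand-in for the
    47-odor receptor panel)."""

    n_molecules: int = 47
    active_fraction: float = 0.3
    n_descriptors: int = 200
    n_informative: int = 3
    effect_size: float = 3.0  # centroid shift of actives, in spread units
    n_prolonged: int = 4
    n_kinetics_descriptors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_kinetics_descriptors > self.n_descriptors:
            raise ValueError("informative + kinetics descriptors exceed total")
        n_active = self.n_active
        if not (2 <= n_active <= self.n_molecules - 2):
            raise ValueError("need between 2 and n_molecules-2 actives")
        if self.n_prolonged > n_active:
            raise ValueError("more prolonged actives than actives")

    @property
    def n_active(self) -> int:
        return int(round(self.active_fraction * self.n_molecules))


@dataclass
class ChemGroundTruth:
    informative_idx: np.ndarray
    kinetics_idx: np.ndarray
    active_ids: list[str]
    prolonged_ids: list[str]
    fail_ids: list[str] = field(default_factory=list)


def _structure_rng(cfg: ChemSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Planted descriptor indices, derived only from the seed so a library
    generated with the same config shares the training set's geometry."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    idx = rng.choice(cfg.n_descriptors, cfg.n_informative + cfg.n_kinetics_descriptors,
                     replace=False)
    return idx[: cfg.n_informative], idx[cfg.n_informative:]


def gen_training_set(
    cfg: ChemSimConfig,
) -> tuple[list[MoleculeRecord], DescriptorMatrix, ChemGroundTruth]:
    """Panel of molecules with planted active / prolonged structure.

    Descriptors are iid standard normal; actives are shifted by
    ``effect_size`` in the informative dimensions, prolonged actives
    additionally in the kinetics dimensions.  Actives carry activity
    ~ 60 spikes/s (the tonic excess magnitude), inactives 0.
    """
    informative_idx, kinetics_idx = _structure_rng(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n, d = cfg.n_molecules, cfg.n_descriptors
    x = rng.standard_normal((n, d))
    active_rows = np.sort(rng.choice(n, cfg.n_active, replace=False))
    prolonged_rows = active_rows[: cfg.n_prolonged]
    x[np.ix_(active_rows, informative_idx)] += cfg.effect_size
    x[np.ix_(prolonged_rows, kinetics_idx)] += cfg.effect_size

    width = len(str(n - 1))
    records: list[MoleculeRecord] = []
    prolonged_set = set(prolonged_rows.tolist())
    active_set = set(active_rows.tolist())
    for i in range(n):
        is_active = i in active_set
        activity = (
            max(0.0, ACTIVITY_SCALE * (1 + 0.1 * rng.standard_normal()))
            if is_active
            else 0.0
        )
        records.append(
            MoleculeRecord(
                id=f"mol{i:0{width}d}",
                smiles=_PLACEHOLDER_SMILES[i % len(_PLACEHOLDER_SMILES)],
                activity=activity,
                active_label="active" if is_active else "inactive",
                kinetics_label=(
                    "prolonged" if i in prolonged_set
                    else "transient" if is_active else "unknown"
                ),
            )
        )
    matrix = DescriptorMatrix(
        [r.id for r in records],
        [f"D{j:04d}" for j in range(d)],
        x,
        provenance="ingested",
    )
    truth = ChemGroundTruth(
        informative_idx=informative_idx,
        kinetics_idx=kinetics_idx,
        active_ids=[records[i].id for i in active_rows],
        prolonged_ids=[records[i].id for i in prolonged_rows],
    )
    return records, matrix, truth


def gen_library(
    cfg: ChemSimConfig,
    n_library: int = 5000,
    n_planted_active: int = 50,
    fail_fraction: float = 0.0,
) -> tuple[list[MoleculeRecord], DescriptorMatrix, ChemGroundTruth]:
    """Screening library with planted actives, sharing the training-set
    geometry (same planted descriptor indices for the same seed).

    ``fail_fraction`` of the records deterministically receive structures
    that violate the screen filters, exercising filter logic end to end.
    """
    informative_idx, kinetics_idx = _structure_rng(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    x = rng.standard_normal((n_library, cfg.n_descriptors))
    active_rows = np.sort(rng.choice(n_library, n_planted_active, replace=False))
    x[np.ix_(active_rows, informative_idx)] += cfg.effect_size
    n_fail = int(round(fail_fraction * n_library))
    fail_rows = np.sort(rng.choice(n_library, n_fail, replace=False)) if n_fail else np.array([], dtype=int)
    fail_set = set(fail_rows.tolist())

    width = len(str(max(n_library - 1, 1)))
    records = []
    for i in range(n_library):
        if i in fail_set:
            smiles = _FAIL_SMILES[i % len(_FAIL_SMILES)]
        else:
            smiles = _PLACEHOLDER_SMILES[i % len(_PLACEHOLDER_SMILES)]
        records.append(MoleculeRecord(id=f"lib{i:0{width}d}", smiles=smiles))
    matrix = DescriptorMatrix(
        [r.id for r in records],
        [f"D{j:04d}" for j in range(cfg.n_descriptors)],
        x,
        provenance="ingested",
    )
    truth = ChemGroundTruth(
        informative_idx=informative_idx,
        kinetics_idx=kinetics_idx,
        active_ids=[records[i].id for i in active_rows],
        prolonged_ids=[],
        fail_ids=[records[i].id for i in fail_rows],
    )
    return records, matrix, truth


# ---------------------------------------------------------------------------
# spike-train simulation

@dataclass
class SpikeSimConfig:
    """Inhomogeneous-Poisson spike generator settings.

    Defaults mirror the recorded response regime: ~8 spikes/s spontaneous
    rate, a strong phasic transient after a 0.5 s pulse at t = 0, and for
    prolonged activators a ~60 spikes/s tonic plateau lasting ~220 s inside
    a 300 s recording.
    """

    baseline_rate: float = 8.0  # spikes/s
    peak_excess: float = 200.0  # spikes/s, phasic amplitude at onset
    decay_tau: float = 4.0  # s (transient odorants: typically 1.5)
    plateau_excess: float = 60.0  # spikes/s
    plateau_duration: float = 220.0  # s
    stimulus_duration: float = 0.5  # s
    t0: float = 0.0
    window: tuple[float, float] = (-30.0, 300.0)
    n_trials: int = 20
    masking_gain: float = 0.1  # probe gain after prolonged pre-exposure
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "peak_excess", "plateau_excess"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.window[0] <= self.t0 <= self.window[1]):
            raise ValueError("window must cover the stimulus")


PROFILES = ("transient", "prolonged", "baseline")


def response_rate_function(
    cfg: SpikeSimConfig, profile: str
) -> Callable[[np.ndarray], np.ndarray]:
    """Exact trial rate r(t): baseline + phasic decay (+ tonic plateau)."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    tau = cfg.decay_tau

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, cfg.baseline_rate)
        if profile != "baseline":
            post = t >= cfg.t0
            r = r + np.where(post, cfg.peak_excess * np.exp(-(t - cfg.t0) / tau), 0.0)
            if profile == "prolonged":
                in_plateau = post & (t <= cfg.t0 + cfg.plateau_duration)
                r = r + np.where(in_plateau, cfg.plateau_excess, 0.0)
        return r

    return rate


def _thin_poisson(
    rate: Callable[[np.ndarray], np.ndarray],
    bound: float,
    window: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One inhomogeneous-Poisson realization by thinning a homogeneous
    process at ``bound``; thinning is bin-free, so downstream bin-width
    choices cannot bias the fixtures."""
    t_start, t_end = window
    n = rng.poisson(bound * (t_end - t_start))
    t = np.sort(rng.uniform(t_start, t_end, n))
    keep = rng.uniform(0.0, bound, n) < rate(t)
    t = t[keep]
    if t.size > 1:  # enforce distinct spike times at recording resolution
        t = t[np.r_[True, np.diff(t) >= SPIKE_TIME_RESOLUTION]]
    return t


def gen_spike_trains(
    cfg: SpikeSimConfig,
    profile: str,
    odorant: str | None = None,
) -> tuple[list[SpikeTrain], Callable[[np.ndarray], np.ndarray]]:
    """Seeded spike trains for one odorant profile, plus the true rate."""
    rate = response_rate_function(cfg, profile)
    bound = cfg.baseline_rate + cfg.peak_excess + cfg.plateau_excess
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    odorant = odorant or f"synthetic_{profile}"
    trains = []
    for trial in range(cfg.n_trials):
        times = _thin_poisson(rate, bound, cfg.window, rng)
        trains.append(
            SpikeTrain(
                trial_id=f"trial{trial:03d}",
                odorant=odorant,
                dilution="1e-2",
                t0=cfg.t0,
                stimulus_duration=cfg.stimulus_duration,
                spike_times=times,
                window=cfg.window,
            )
        )
    return trains, rate


@dataclass
class MaskingGroundTruth:
    probe_times: np.ndarray
    gains: np.ndarray  # planted multiplicative probe gain, exposed condition
    planted_index: np.ndarray  # 1 - gain


def gen_masking_experiment(
    cfg: SpikeSimConfig,
    pre_exposure: str,
    probe_times: Sequence[float] = (15.0, 30.0),
    probe_tau: float = 1.5,
    n_trials: int = 5,
) -> tuple[list[SpikeTrain], list[SpikeTrain], MaskingGroundTruth]:
    """Paired exposed/control probe experiment.

    Control: transient pre-exposure at t0 plus full-gain transient probe
    responses at each probe time.  Exposed: when ``pre_exposure`` is
    ``prolonged``, the pre-exposure response carries its tonic plateau and
    every probe response is scaled by ``masking_gain``; when ``transient``,
    the exposed condition is constructed identically to control.
    """
    if pre_exposure not in ("transient", "prolonged"):
        raise ValueError(f"unknown pre-exposure {pre_exposure!r}")
    probe_times = np.asarray(probe_times, dtype=float)
    gain = cfg.masking_gain if pre_exposure == "prolonged" else 1.0

    def make_rate(kind: str, probe_gain: float) -> Callable[[np.ndarray], np.ndarray]:
        pre = response_rate_function(cfg, kind)

        def rate(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            r = pre(t)
            for tp in probe_times:
                post = t >= tp
                r = r + np.where(
                    post, probe_gain * cfg.peak_excess * np.exp(-(t - tp) / probe_tau), 0.0
                )
            return r

        return rate

    exposed_rate = make_rate(pre_exposure, gain)
    control_rate = make_rate("transient", 1.0)
    bound = cfg.baseline_rate + cfg.plateau_excess + cfg.peak_excess * (1 + len(probe_times))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    def draw(rate_fn, tag):
        trains = []
        for trial in range(n_trials):
            times = _thin_poisson(rate_fn, bound, cfg.window, rng)
            trains.append(
                SpikeTrain(
                    trial_id=f"{tag}{trial:03d}",
                    odorant=f"masking_{tag}",
                    dilution="1e-2",
                    t0=cfg.t0,
                    stimulus_duration=cfg.stimulus_duration,
                    spike_times=times,
                    window=cfg.window,
                )
            )
        return trains

    exposed = draw(exposed_rate, "exposed")
    control = draw(control_rate, "control")
    truth = MaskingGroundTruth(
        probe_times=probe_times,
        gains=np.full(probe_times.size, gain),
        planted_index=1.0 - np.full(probe_times.size, gain),
    )
    return exposed, control, truth
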