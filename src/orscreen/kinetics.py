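"""Firing-rate timecourses and termination-kinetics statistics.

Olfactory receptor neuron responses to a brief odor pulse are summarized
from spike times: per-trial binned rates averaged across trials give the
timecourse; from its baseline-subtracted excess we extract the phasic peak,
the half-decay time, the tonic plateau, and the response duration.  An
odorant is a *prolonged activator* when its excess firing outlasts a
configurable threshold (default 30 s after onset); masking by pre-exposure
is quantified as the fractional loss of probe-evoked excess relative to a
control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SPIKE_TIME_RESOLUTION = 1e-6  # s; spikes closer than this count as duplicates


@dataclass
class SpikeTrain:
    """Spike times (s) from one trial, with stimulus timing and window."""

    trial_id: str
    odorant: str
    dilution: str
    t0: float  # stimulus onset, s
    stimulus_duration: float  # s (0.5 s standard pulse)
    spike_times: np.ndarray
    window: tuple[float, float] = (-30.0, 300.0)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        t_start, t_end = self.window
        if not (t_start <= self.t0 <= t_end):
            raise ValueError(f"trial {self.trial_id}: stimulus outside recording window")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < SPIKE_TIME_RESOLUTION):
                raise ValueError(f"trial {self.trial_id}: spike times not sorted/unique")
            if self.spike_times[0] < t_start or self.spike_times[-1] > t_end:
                raise ValueError(f"trial {self.trial_id}: spikes outside recording window")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class RateTimecourse:
    """Across-trial mean firing rate in uniform bins, with s.e.m."""

    bin_edges: np.ndarray  # s, len n_bins + 1
    mean_rate: np.ndarray  # spikes/s per bin
    sem_rate: np.ndarray  # spikes/s per bin, across trials
    n_trials: int
    baseline_rate: float  # spikes/s, strictly pre-stimulus
    baseline_sem: float
    onset: float  # stimulus onset, s

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def excess(self) -> np.ndarray:
        return self.mean_rate - self.baseline_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_left": self.bin_edges[:-1],
                "t_right": self.bin_edges[1:],
                "mean_rate": self.mean_rate,
                "sem_rate": self.sem_rate,
            }
        )


def rate_timecourse(
    trials: Sequence[SpikeTrain],
    bin_width: float = 1.0,
    baseline_window: tuple[float, float] = (-10.0, 0.0),
) -> RateTimecourse:
    """Bin each trial, average rates across trials, estimate the baseline.

    ``baseline_window`` is relative to stimulus onset and must be strictly
    pre-stimulus.  Total binned spike count is conserved exactly:
    ``sum(mean_rate * bin_width) * n_trials == total spikes``.
    """
    if not trials:
        raise ValueError("rate_timecourse needs at least 1 trial")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t_start, t_end = trials[0].window
    onset = trials[0].t0
    for tr in trials:
        if abs(tr.window[0] - t_start) > 1e-3 or abs(tr.window[1] - t_end) > 1e-3:
            raise ValueError("trials must share a common recording window")
        if abs(tr.t0 - onset) > 1e-3:
            raise ValueError("trials must share stimulus timing")
    if baseline_window[1] > 0:
        raise ValueError("baseline window must be strictly pre-stimulus")
    b_lo, b_hi = onset + baseline_window[0], onset + baseline_window[1]
    if b_lo < t_start - 1e-9:
        raise ValueError("baseline window outside recording window")

    n_bins = int(np.ceil((t_end - t_start) / bin_width - 1e-9))
    edges = t_start + bin_width * np.arange(n_bins + 1)
    edges[-1] = t_end  # final bin may be partial
    widths = np.diff(edges)
    rates = np.empty((len(trials), n_bins))
    base = np.empty(len(trials))
    for i, tr in enumerate(trials):
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        rates[i] = counts / widths
        in_base = np.count_nonzero(
            (tr.spike_times >= b_lo) & (tr.spike_times < b_hi)
        )
        base[i] = in_base / (b_hi - b_lo)
    mean_rate = rates.mean(axis=0)
    if len(trials) > 1:
        sem = rates.std(axis=0, ddof=1) / np.sqrt(len(trials))
        baseline_sem = float(base.std(ddof=1) / np.sqrt(len(trials)))
    else:
        sem = np.zeros(n_bins)
        baseline_sem = 0.0
    return RateTimecourse(
        bin_edges=edges,
        mean_rate=mean_rate,
        sem_rate=sem,
        n_trials=len(trials),
        baseline_rate=float(base.mean()),
        baseline_sem=baseline_sem,
        onset=onset,
    )


@dataclass
class KineticsConfig:
    """Estimator thresholds, all in seconds / spikes per second."""

    peak_window: float = 5.0  # search for the phasic peak within this much of onset
    peak_significance: float = 3.0  # peak must exceed this many of its own s.e.m.
    plateau_start: float = 30.0  # tonic plateau window starts here (post-onset)
    return_threshold: float | None = None  # default max(2*baseline_sem, 0.1*peak)
    persistence_bins: int = 3  # consecutive sub-threshold bins ending the response
    prolonged_threshold: float = 30.0  # duration >= this => prolonged activator


@dataclass
class KineticsSummary:
    """Termination-kinetics statistics of one odorant response.

    All times are relative to stimulus onset; rates are excess over the
    pre-stimulus baseline.  Fields are ``None`` when undefined (e.g. no
    evoked response, or the response ended before the plateau window).
    """

    peak_rate: float | None
    t_peak: float | None
    t_half: float | None
    plateau_rate: float | None
    duration: float | None
    prolonged: bool
    duration_censored: bool = False  # response outlasted the recording


def kinetics_summary(
    tc: RateTimecourse,
    config: KineticsConfig | None = None,
) -> KineticsSummary:
    """Extract peak, half-decay, plateau and duration from a timecourse."""
    cfg = config or KineticsConfig()
    onset = tc.onset
    if tc.bin_edges[-1] - onset < 10.0:
        raise ValueError("timecourse must cover at least 10 s post-stimulus")
    excess = tc.excess
    centers = tc.bin_centers
    left = tc.bin_edges[:-1]

    post = left >= onset - 1e-9
    peak_region = post & (left < onset + cfg.peak_window)
    if not peak_region.any() or excess[peak_region].max() <= 0:
        return KineticsSummary(None, None, None, None, None, prolonged=False)
    peak_idx = int(np.flatnonzero(peak_region)[np.argmax(excess[peak_region])])
    peak = float(excess[peak_idx])
    # reject peaks indistinguishable from baseline fluctuation (non-activator)
    if peak <= cfg.peak_significance * tc.sem_rate[peak_idx]:
        return KineticsSummary(None, None, None, None, None, prolonged=False)
    t_peak = float(centers[peak_idx] - onset)

    below_half = np.flatnonzero((np.arange(excess.size) > peak_idx) & (excess < peak / 2))
    t_half = float(left[below_half[0]] - onset) if below_half.size else None

    thr = cfg.return_threshold
    if thr is None:
        thr = max(2.0 * tc.baseline_sem, 0.1 * peak)
    post_idx = np.flatnonzero(post)
    sub = excess[post_idx] < thr
    duration = None
    censored = False
    w = cfg.persistence_bins
    for j in range(sub.size - w + 1):
        if sub[j:j + w].all():
            duration = float(left[post_idx[j]] - onset)
            break
    if duration is None:
        duration = float(tc.bin_edges[-1] - onset)
        censored = True
    # never report the response as ending before its peak
    duration = max(duration, t_peak)

    plateau = None
    if duration > cfg.plateau_start:
        in_plateau = post & (left >= onset + cfg.plateau_start) & (left < onset + duration)
        if in_plateau.any():
            plateau = float(np.median(excess[in_plateau]))
    return KineticsSummary(
        peak_rate=peak,
        t_peak=t_peak,
        t_half=t_half,
        plateau_rate=plateau,
        duration=duration,
        prolonged=duration >= cfg.prolonged_threshold,
        duration_censored=censored,
    )


# ---------------------------------------------------------------------------
# masking by pre-exposure

@dataclass
class MaskingProfile:
    """Probe-response suppression after pre-exposure, per probe time.

    ``index = 1 - exposed_excess / control_excess`` (clipped to <= 1):
    0 means no suppression, 1 means the probe response is fully abolished.
    Probes where the control excess is non-positive are flagged undefined.
    """

    probe_times: np.ndarray
    exposed_excess: np.ndarray
    control_excess: np.ndarray
    masking_index: np.ndarray  # NaN where undefined
    defined: np.ndarray

    @property
    def mean_index(self) -> float:
        d = self.masking_index[self.defined]
        return float(d.mean()) if d.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_time": self.probe_times,
                "exposed_excess": self.exposed_excess,
                "control_excess": self.control_excess,
                "masking_index": self.masking_index,
                "defined": self.defined,
            }
        )


def probe_excess(
    trials: Sequence[SpikeTrain],
    probe_times: Sequence[float],
    probe_window: float = 2.0,
    pre_window: float = 2.0,
) -> np.ndarray:
    """Probe-evoked change in rate at each probe time, averaged over trials.

    Excess = rate in [tp, tp + probe_window) minus rate in the immediately
    preceding [tp - pre_window, tp) window; any tonic pre-exposure plateau
    common to both windows subtracts out.
    """
    probe_times = np.asarray(probe_times, dtype=float)
    out = np.zeros(probe_times.size)
    for p, tp in enumerate(probe_times):
        vals = []
        for tr in trials:
            t = tr.spike_times
            n_probe = np.count_nonzero((t >= tp) & (t < tp + probe_window))
            n_pre = np.count_nonzero((t >= tp - pre_window) & (t < tp))
            vals.append(n_probe / probe_window - n_pre / pre_window)
        out[p] = float(np.mean(vals))
    return out


def masking_profile(
    exposed_excess,
    control_excess,
    probe_times,
) -> MaskingProfile:
    """Masking index per probe from matched exposed/control excess responses."""
    exposed = np.asarray(exposed_excess, dtype=float)
    control = np.asarray(control_excess, dtype=float)
    probe_times = np.asarray(probe_times, dtype=float)
    if not (exposed.shape == control.shape == probe_times.shape):
        raise ValueError("probe times and responses must be matched in length")
    defined = control > 0
    index = np.full(probe_times.size, np.nan)
    index[defined] = np.minimum(1.0, 1.0 - exposed[defined] / control[defined])
    return MaskingProfile(probe_times, exposed, control, index, defined)


def masking_profile_from_trains(
    exposed_trials: Sequence[SpikeTrain],
    control_trials: Sequence[SpikeTrain],
    probe_times: Sequence[float],
    probe_window: float = 2.0,
    pre_window: float = 2.0,
) -> MaskingProfile:
    e = probe_excess(exposed_trials, probe_times, probe_window, pre_window)
    c = probe_excess(control_trials, probe_times, probe_window, pre_window)
    return masking_profile(e, c, probe_times)


# ---------------------------------------------------------------------------
# spike-train I/O (long-format delimited text, one spike per row)

_SPIKE_COLUMNS = ["trial_id", "odorant", "dilution", "t0", "duration", "spike_time_s"]


def write_spike_trains(trials: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = []
    for tr in trials:
        for t in tr.spike_times:
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "odorant": tr.odorant,
                    "dilution": tr.dilution,
                    "t0": tr.t0,
                    "duration": tr.stimulus_duration,
                    "spike_time_s": t,
                    "t_start": tr.window[0],
                    "t_end": tr.window[1],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path}: missing column(s) {missing}")
    trials = []
    for (trial_id, odorant, dilution), g in df.groupby(
        ["trial_id", "odorant", "dilution"], sort=False
    ):
        window = (-30.0, 300.0)
        if "t_start" in g.columns and "t_end" in g.columns:
            window = (float(g["t_start"].iloc[0]), float(g["t_end"].iloc[0]))
        trials.append(
            SpikeTrain(
                trial_id=str(trial_id),
                odorant=str(odorant),
                dilution=str(dilution),
                t0=float(g["t0"].iloc[0]),
                stimulus_duration=float(g["duration"].iloc[0]),
                spike_times=np.sort(g["spike_time_s"].to_numpy(dtype=float)),
                window=window,
            )
        )
    return trials
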