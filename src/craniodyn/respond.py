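"""Stimulus-responsive neuron detection and regional summaries.

A neuron counts as responsive to an orientation when its mean ΔF/F over
that orientation's stimulus windows exceeds the baseline mean plus
``k_sd`` (default 3) baseline standard deviations, with the baseline taken
from the pre-stimulus windows.  Frame indexing is 0-based, half-open,
floor-rounded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CalciumDataset, RegionMap, StimulusSchedule

__all__ = [
    "DetectionParams",
    "ResponsiveSet",
    "trial_windows",
    "detect_responsive",
    "region_counts",
    "region_time_normalize",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds and windows.

    ``stim_window`` is the stimulus window Δt in seconds; ``baseline_window``
    the pre-onset baseline length (defaults to Δt); ``k_sd`` the SD
    multiplier.  ``pooled_baseline=True`` pools pre-stimulus windows of all
    trials into a single per-neuron baseline (stabilizes the SD estimate);
    ``False`` pools only the trials of the orientation under test.
    """

    stim_window: float = 2.0
    baseline_window: float | None = None
    k_sd: float = 3.0
    pooled_baseline: bool = True

    def __post_init__(self) -> None:
        if self.stim_window <= 0:
            raise ValueError("stim_window must be positive")
        if self.baseline_window is not None and self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")

    @property
    def baseline_length(self) -> float:
        return self.stim_window if self.baseline_window is None else self.baseline_window


@dataclass(frozen=True)
class ResponsiveSet:
    """Per-neuron × per-orientation responsiveness decisions.

    Stores the baseline statistics used so each decision is exactly
    reproducible: ``flags[n, j]`` ⇔ stim mean of neuron n for orientation
    ``orientations[j]`` > ``baseline_mean[n] + k_sd * baseline_sd[n]``
    (strict inequality; under the per-orientation baseline mode the stored
    stats are per orientation).
    """

    orientations: np.ndarray
    flags: np.ndarray  # (n_neurons, n_orientations) bool
    stim_means: np.ndarray  # (n_neurons, n_orientations)
    baseline_mean: np.ndarray  # (n_neurons,) or (n_neurons, n_orientations)
    baseline_sd: np.ndarray
    k_sd: float

    @property
    def union(self) -> np.ndarray:
        """Responsive to at least one orientation."""
        return self.flags.any(axis=1)

    @property
    def n_responsive(self) -> int:
        return int(self.union.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.flags,
            columns=[f"responsive_{int(o)}" for o in self.orientations])
        frame.insert(0, "neuron", np.arange(len(frame)))
        frame["responsive_any"] = self.union
        bmean = np.atleast_2d(self.baseline_mean.T).T
        bsd = np.atleast_2d(self.baseline_sd.T).T
        frame["baseline_mean"] = bmean.mean(axis=1)
        frame["baseline_sd"] = bsd.mean(axis=1)
        return frame


def trial_windows(
    schedule: StimulusSchedule,
    frame_rate: float,
    params: DetectionParams | None = None,
) -> list[tuple[slice, slice]]:
    """Per-trial (stimulus frames, baseline frames) as half-open slices.

    Stimulus frames are ``[floor(onset·rate), floor((onset+Δt)·rate))``;
    baseline frames cover the ``baseline_length`` seconds immediately
    before onset with the same convention.
    """
    params = params or DetectionParams()
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    blen = params.baseline_length
    if schedule.onsets[0] < blen:
        raise ValueError(
            f"first onset at {schedule.onsets[0]} s leaves no room for a "
            f"{blen} s baseline window")
    windows = []
    for onset in schedule.onsets:
        s0 = int(np.floor(onset * frame_rate))
        s1 = int(np.floor((onset + params.stim_window) * frame_rate))
        b0 = int(np.floor((onset - blen) * frame_rate))
        windows.append((slice(s0, s1), slice(b0, s0)))
    return windows


def detect_responsive(
    dataset: CalciumDataset, params: DetectionParams | None = None
) -> ResponsiveSet:
    """Apply the baseline-mean + k·SD criterion per neuron and orientation.

    The baseline SD uses the population (divide-by-N) convention and ties
    at the threshold resolve to *not responsive* (strict ``>``), so a
    constant trace is never responsive.
    """
    params = params or DetectionParams()
    windows = trial_windows(dataset.schedule, dataset.frame_rate, params)
    traces = dataset.traces
    orientations = dataset.schedule.unique_orientations
    n = dataset.n_neurons

    stim_frames_by_ori: dict[float, np.ndarray] = {}
    base_frames_by_ori: dict[float, np.ndarray] = {}
    for ori in orientations:
        trials = dataset.schedule.trials_of(ori)
        stim_frames_by_ori[ori] = np.concatenate(
            [np.arange(windows[t][0].start, windows[t][0].stop) for t in trials])
        base_frames_by_ori[ori] = np.concatenate(
            [np.arange(windows[t][1].start, windows[t][1].stop) for t in trials])

    stim_means = np.column_stack(
        [traces[:, stim_frames_by_ori[o]].mean(axis=1) for o in orientations])

    if params.pooled_baseline:
        all_base = np.concatenate([base_frames_by_ori[o] for o in orientations])
        if len(all_base) < 2:
            raise ValueError("need at least 2 baseline frames")
        bvals = traces[:, all_base]
        bmean = bvals.mean(axis=1)
        bsd = bvals.std(axis=1)  # ddof=0
        thresh = (bmean + params.k_sd * bsd)[:, None]
    else:
        bmean = np.column_stack(
            [traces[:, base_frames_by_ori[o]].mean(axis=1) for o in orientations])
        bsd = np.column_stack(
            [traces[:, base_frames_by_ori[o]].std(axis=1) for o in orientations])
        thresh = bmean + params.k_sd * bsd

    flags = stim_means > thresh
    return ResponsiveSet(
        orientations=orientations,
        flags=flags,
        stim_means=stim_means,
        baseline_mean=bmean,
        baseline_sd=bsd,
        k_sd=params.k_sd,
    )


def region_counts(
    rset: ResponsiveSet, dataset: CalciumDataset, regions: RegionMap
) -> pd.Series:
    """Count union-responsive neurons per region (index = region name)."""
    labels = dataset.regions
    if np.any((labels < 0) | (labels >= regions.n_regions)):
        raise ValueError("dataset has labels outside the region map")
    counts = np.bincount(labels[rset.union], minlength=regions.n_regions)
    return pd.Series(counts, index=list(regions.names), name="n_responsive")


def region_time_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each region's day-series by its own maximum across days.

    ``table`` is days × regions (rows indexed by day).  All-zero regions
    stay zero; every nonzero region peaks at exactly 1.
    """
    maxima = table.max(axis=0)
    safe = maxima.replace(0, 1.0)
    return table.div(safe, axis=1)
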