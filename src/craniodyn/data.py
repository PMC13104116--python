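"""Core data containers for calcium-imaging sessions and their I/O.

The pipeline works on three kinds of objects:

* :class:`RegionMap` — a rectangular parcellation of the imaged cortical
  sheet into named regions (a stand-in for an atlas registration).
* :class:`StimulusSchedule` — drifting-grating trial timing: onsets,
  orientation labels, stimulus duration and inter-stimulus intervals.
* :class:`CalciumDataset` — the ΔF/F trace matrix of one recording session
  together with neuron positions, region labels, the stimulus schedule and
  (for synthetic sessions) generative ground truth.

Datasets round-trip through HDF5 (h5py); region maps and schedules also
serialize to plain CSV tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RegionMap",
    "StimulusSchedule",
    "GroundTruth",
    "CalciumDataset",
]

BACKGROUND = -1


@dataclass(frozen=True)
class RegionMap:
    """Rectangular tiling of a cortical sheet into ``n_regions`` regions.

    Regions are axis-aligned rectangles that tile the sheet exactly; every
    in-sheet position maps to exactly one region, positions outside the
    sheet map to :data:`BACKGROUND` (-1).  Region ids are contiguous from 0.
    """

    width: float
    height: float
    rects: np.ndarray  # (K, 4): x0, y0, x1, y1
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        rects = np.asarray(self.rects, dtype=float)
        object.__setattr__(self, "rects", rects)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("sheet dimensions must be positive")
        if rects.ndim != 2 or rects.shape[1] != 4:
            raise ValueError("rects must be a (K, 4) array")
        if len(self.names) != len(rects):
            raise ValueError("one name per region required")
        areas = (rects[:, 2] - rects[:, 0]) * (rects[:, 3] - rects[:, 1])
        if np.any(areas <= 0):
            raise ValueError("every region must have nonzero area")

    @property
    def n_regions(self) -> int:
        return len(self.rects)

    def region_of(self, positions: np.ndarray) -> np.ndarray:
        """Map (n, 2) positions in µm to region ids (-1 = background).

        Rectangles are half-open ``[x0, x1) × [y0, y1)`` except along the
        far sheet edges, which are closed so the tiling covers the sheet.
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        x, y = pos[:, 0], pos[:, 1]
        out = np.full(len(pos), BACKGROUND, dtype=int)
        for rid, (x0, y0, x1, y1) in enumerate(self.rects):
            hi_x = x < x1 if x1 < self.width else x <= x1
            hi_y = y < y1 if y1 < self.height else y <= y1
            inside = (x >= x0) & hi_x & (y >= y0) & hi_y
            out[inside & (out == BACKGROUND)] = rid
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": np.arange(self.n_regions),
                "name": list(self.names),
                "x0": self.rects[:, 0],
                "y0": self.rects[:, 1],
                "x1": self.rects[:, 2],
                "y1": self.rects[:, 3],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# sheet_width={self.width} sheet_height={self.height}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#").split()
            meta = dict(kv.split("=") for kv in header)
            frame = pd.read_csv(fh)
        rects = frame[["x0", "y0", "x1", "y1"]].to_numpy(dtype=float)
        return cls(
            width=float(meta["sheet_width"]),
            height=float(meta["sheet_height"]),
            rects=rects,
            names=tuple(frame["name"].astype(str)),
        )


@dataclass(frozen=True)
class StimulusSchedule:
    """Trial timing of a drifting-grating session.

    ``onsets`` are stimulus-start times in seconds (strictly increasing),
    ``orientations`` the grating orientation of each trial in degrees,
    ``duration`` the common stimulus length and ``isi`` the inter-stimulus
    interval following each trial.
    """

    onsets: np.ndarray
    orientations: np.ndarray
    duration: float
    isi: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        oris = np.asarray(self.orientations, dtype=float)
        isi = np.asarray(self.isi, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "orientations", oris)
        object.__setattr__(self, "isi", isi)
        if not (len(onsets) == len(oris) == len(isi)):
            raise ValueError("onsets, orientations and isi must align")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def unique_orientations(self) -> np.ndarray:
        return np.unique(self.orientations)

    def trials_of(self, orientation: float) -> np.ndarray:
        return np.flatnonzero(np.isclose(self.orientations, orientation))

    @property
    def end_time(self) -> float:
        return float(self.onsets[-1] + self.duration + self.isi[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "onset_s": self.onsets,
                "orientation_deg": self.orientations,
                "duration_s": self.duration,
                "isi_s": self.isi,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StimulusSchedule":
        return cls(
            onsets=frame["onset_s"].to_numpy(dtype=float),
            orientations=frame["orientation_deg"].to_numpy(dtype=float),
            duration=float(frame["duration_s"].iloc[0]),
            isi=frame["isi_s"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generative ground truth carried by synthetic sessions."""

    preferred_orientation: np.ndarray  # degrees, per neuron
    responsive: np.ndarray  # bool, per neuron
    community: np.ndarray  # int, per neuron

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "preferred_orientation",
            np.asarray(self.preferred_orientation, dtype=float))
        object.__setattr__(self, "responsive", np.asarray(self.responsive, dtype=bool))
        object.__setattr__(self, "community", np.asarray(self.community, dtype=int))


@dataclass
class CalciumDataset:
    """One recording session: ΔF/F traces plus session metadata.

    ``traces`` is (n_neurons, n_frames) ΔF/F at ``frame_rate`` Hz,
    ``positions`` (n_neurons, 2) in µm on the imaged sheet, ``regions``
    the per-neuron region id (referencing a :class:`RegionMap`).
    """

    traces: np.ndarray
    frame_rate: float
    positions: np.ndarray
    regions: np.ndarray
    schedule: StimulusSchedule
    ground_truth: GroundTruth | None = None
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.regions = np.asarray(self.regions, dtype=int)
        if self.traces.ndim != 2:
            raise ValueError("traces must be (n_neurons, n_frames)")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        n = self.traces.shape[0]
        if self.positions.shape != (n, 2) or self.regions.shape != (n,):
            raise ValueError("positions/regions must align with traces")
        last_needed = self.schedule.onsets[-1] + self.schedule.duration
        if last_needed * self.frame_rate > self.n_frames:
            raise ValueError("recording ends before the last trial window")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces, compression="gzip")
            f.attrs["frame_rate"] = self.frame_rate
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("regions", data=self.regions)
            sched = f.create_group("schedule")
            sched.create_dataset("onsets", data=self.schedule.onsets)
            sched.create_dataset("orientations", data=self.schedule.orientations)
            sched.create_dataset("isi", data=self.schedule.isi)
            sched.attrs["duration"] = self.schedule.duration
            if self.ground_truth is not None:
                gt = f.create_group("ground_truth")
                gt.create_dataset(
                    "preferred_orientation",
                    data=self.ground_truth.preferred_orientation)
                gt.create_dataset("responsive", data=self.ground_truth.responsive)
                gt.create_dataset("community", data=self.ground_truth.community)
            if self.region_map is not None:
                rm = f.create_group("region_map")
                rm.attrs["width"] = self.region_map.width
                rm.attrs["height"] = self.region_map.height
                rm.create_dataset("rects", data=self.region_map.rects)
                rm.create_dataset(
                    "names",
                    data=np.array(self.region_map.names, dtype=h5py.string_dtype()))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CalciumDataset":
        with h5py.File(path, "r") as f:
            schedule = StimulusSchedule(
                onsets=f["schedule/onsets"][:],
                orientations=f["schedule/orientations"][:],
                duration=float(f["schedule"].attrs["duration"]),
                isi=f["schedule/isi"][:],
            )
            ground_truth = None
            if "ground_truth" in f:
                ground_truth = GroundTruth(
                    preferred_orientation=f["ground_truth/preferred_orientation"][:],
                    responsive=f["ground_truth/responsive"][:],
                    community=f["ground_truth/community"][:],
                )
            region_map = None
            if "region_map" in f:
                region_map = RegionMap(
                    width=float(f["region_map"].attrs["width"]),
                    height=float(f["region_map"].attrs["height"]),
                    rects=f["region_map/rects"][:],
                    names=tuple(n.decode() for n in f["region_map/names"][:]),
                )
            return cls(
                traces=f["traces"][:],
                frame_rate=float(f.attrs["frame_rate"]),
                positions=f["positions"][:],
                regions=f["regions"][:],
                schedule=schedule,
                ground_truth=ground_truth,
                region_map=region_map,
            )

    def traces_to_csv(self, path: str | Path) -> None:
        """CSV fallback for small sessions (≤ 1e6 cells·frames)."""
        if self.traces.size > 1_000_000:
            raise ValueError("CSV fallback limited to 1e6 cells x frames; use HDF5")
        pd.DataFrame(self.traces).to_csv(path, index_label="neuron")

    def replace(self, **kwargs) -> "CalciumDataset":
        return dataclasses.replace(self, **kwargs)
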