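"""Synthetic mesoscale recording generator.

Everything the analysis pipeline consumes can be generated here with known
ground truth: drifting-grating calcium-imaging sessions across recovery
timepoints, per-animal longitudinal morphology series with an injected
cross-modal lag, and binary cell images with analytically known Sholl
profiles.

Generative model of a session
-----------------------------
Layer-2/3 neurons are placed uniformly on a parcellated cortical sheet.
A ground-truth responsive subset receives, during each 2-s stimulus window,
a boxcar drive scaled by a von Mises orientation-tuning curve on the
doubled angle (period 180°, concentration ``kappa``; ``kappa`` → ∞ gives a
neuron responding to a single orientation, ``kappa`` = 0 an untuned one).
Correlated population activity comes from community-shared Gaussian
factors: one factor per community (amplitude ``within_noise``) plus one
global factor shared by all neurons (amplitude ``between_noise``).  Drive
plus shared factors are convolved with a causal single-exponential calcium
kernel (unit gain at steady state, decay ``decay_tau`` ≈ GCaMP6f), and
white observation noise is added last.  Shared-factor amplitudes are
defined as post-kernel trace standard deviations, so pairwise correlations
are controlled directly by the stated amplitudes.

Communities are assigned per *region* (contiguous blocks of region ids),
so neuron-level community structure projects onto region-level networks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data import CalciumDataset, GroundTruth, RegionMap, StimulusSchedule

__all__ = [
    "SessionParams",
    "RecoveryScenario",
    "RecoveryResult",
    "make_atlas",
    "build_schedule",
    "simulate_session",
    "simulate_recovery",
    "morphology_series",
    "simulate_cell_image",
    "LongitudinalSeries",
]


# Longitudinal series live conceptually in the longitudinal module but are
# defined here to avoid a circular import; re-exported there.
@dataclass(frozen=True)
class LongitudinalSeries:
    """Per-animal, per-modality values at measured post-operative days."""

    animal: str
    modality: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if len(days) != len(values):
            raise ValueError("days and values must align")
        if len(days) < 2:
            raise ValueError("need at least two measured days")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "modality": self.modality,
                "day": self.days,
                "value": self.values,
            }
        )


@dataclass(frozen=True)
class SessionParams:
    """Parameters of one synthetic drifting-grating session.

    The stimulus protocol defaults mirror the study conditions: four
    orientations (0°, 45°, 90°, 135°), three sets of eight repeats each
    (96 trials), 2-s stimuli with 8–10-s inter-stimulus intervals, 20-Hz
    acquisition.
    """

    n_neurons: int = 200
    frame_rate: float = 20.0
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    n_sets: int = 3
    reps_per_set: int = 8
    stim_duration: float = 2.0
    isi_range: tuple[float, float] = (8.0, 10.0)
    kappa: float = 3.0
    response_amplitude: float = 1.5
    responsive_fraction: float = 0.3
    n_communities: int = 3
    within_noise: float = 0.25
    between_noise: float = 0.05
    obs_noise: float = 0.1
    decay_tau: float = 0.7
    pre_onset: float = 4.0  # lead-in before the first trial (≥ baseline window)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_sets < 1 or self.reps_per_set < 1:
            raise ValueError("n_sets and reps_per_set must be positive")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] < 0:
            raise ValueError("isi_range must satisfy 0 <= lo <= hi")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if self.obs_noise <= 0:
            raise ValueError("observation noise SD must be positive")
        if self.within_noise < 0 or self.between_noise < 0:
            raise ValueError("shared-noise amplitudes must be nonnegative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")

    @property
    def trials_per_orientation(self) -> int:
        return self.n_sets * self.reps_per_set

    @property
    def n_trials(self) -> int:
        return len(self.orientations) * self.trials_per_orientation


def make_atlas(
    n_regions: int = 19,
    width: float = 2000.0,
    height: float = 2000.0,
    seed: int | None = None,
) -> RegionMap:
    """Tile a ``width`` × ``height`` µm sheet into ``n_regions`` rectangles.

    The sheet is split into columns, each carrying an (as even as possible)
    share of row-wise regions; the union of regions equals the sheet.  The
    layout is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators but does not affect the tiling.

    Region names default to ``R01 … RK``.
    """
    del seed  # layout is deterministic
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if width <= 0 or height <= 0:
        raise ValueError("sheet dimensions must be positive")
    n_cols = max(1, round(math.sqrt(n_regions)))
    base, extra = divmod(n_regions, n_cols)
    rows_per_col = [base + (1 if c < extra else 0) for c in range(n_cols)]
    if min(rows_per_col) < 1:
        raise ValueError("n_regions incompatible with column layout")
    if width / n_cols < 1.0 or height / max(rows_per_col) < 1.0:
        raise ValueError(
            f"cannot tile a {width}x{height} um sheet into {n_regions} regions "
            "of at least 1 um extent")
    rects = []
    x_edges = np.linspace(0.0, width, n_cols + 1)
    for c, n_rows in enumerate(rows_per_col):
        y_edges = np.linspace(0.0, height, n_rows + 1)
        for r in range(n_rows):
            rects.append((x_edges[c], y_edges[r], x_edges[c + 1], y_edges[r + 1]))
    names = tuple(f"R{i + 1:02d}" for i in range(n_regions))
    return RegionMap(width=width, height=height, rects=np.asarray(rects), names=names)


def build_schedule(params: SessionParams, seed: int | None = None) -> StimulusSchedule:
    """Randomized grating schedule: orientations shuffled within each set,
    inter-stimulus intervals drawn uniformly from ``isi_range``."""
    rng = np.random.default_rng(seed)
    per_set = np.repeat(np.asarray(params.orientations, dtype=float),
                        params.reps_per_set)
    orientations = np.concatenate(
        [rng.permutation(per_set) for _ in range(params.n_sets)])
    n = len(orientations)
    isi = rng.uniform(params.isi_range[0], params.isi_range[1], size=n)
    onsets = np.empty(n)
    t = params.pre_onset
    for i in range(n):
        onsets[i] = t
        t += params.stim_duration + isi[i]
    return StimulusSchedule(
        onsets=onsets, orientations=orientations,
        duration=params.stim_duration, isi=isi)


def _tuning(orientation: np.ndarray, preferred: np.ndarray, kappa: float) -> np.ndarray:
    """Von Mises tuning on the doubled angle, normalized to peak 1.

    ``g(θ) = exp(κ (cos 2(θ − θ_pref) − 1))`` so that g(θ_pref) = 1 for any
    κ and κ = 0 gives a flat (untuned) response.
    """
    delta = np.deg2rad(orientation - preferred)
    return np.exp(kappa * (np.cos(2.0 * delta) - 1.0))


def _exp_kernel_filter(x: np.ndarray, tau: float, frame_rate: float) -> np.ndarray:
    """Causal single-exponential calcium kernel with unit steady-state gain.

    Implemented as the recursion ``y[t] = (1-a) x[t] + a y[t-1]`` with
    ``a = exp(-1 / (tau * frame_rate))``; a boxcar drive of amplitude A
    therefore rises toward A with time constant ``tau``.
    """
    a = math.exp(-1.0 / (tau * frame_rate))
    return lfilter([1.0 - a], [1.0, -a], x, axis=-1)


def _smoothing_gain(tau: float, frame_rate: float) -> float:
    """Std-dev gain of the exponential kernel applied to white noise."""
    a = math.exp(-1.0 / (tau * frame_rate))
    return math.sqrt((1.0 - a) ** 2 / (1.0 - a**2))


def region_communities(n_regions: int, n_communities: int) -> np.ndarray:
    """Assign regions to communities as contiguous, near-equal blocks."""
    if n_communities < 1 or n_communities > n_regions:
        raise ValueError("need 1 <= n_communities <= n_regions")
    return np.concatenate(
        [np.full(len(chunk), c) for c, chunk in
         enumerate(np.array_split(np.arange(n_regions), n_communities))])


def simulate_session(
    params: SessionParams,
    schedule: StimulusSchedule | None = None,
    regions: RegionMap | None = None,
    seed: int | None = None,
) -> CalciumDataset:
    """Simulate one session; ground truth is recorded on the dataset.

    Neuron communities are inherited from their region (contiguous region
    blocks), so community structure is visible at both the neuron and the
    region level.
    """
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = make_atlas()
    if schedule is None:
        schedule = build_schedule(params, seed=rng.integers(2**31))

    n = params.n_neurons
    positions = np.column_stack(
        [rng.uniform(0, regions.width, n), rng.uniform(0, regions.height, n)])
    region_of = regions.region_of(positions)
    reg_comm = region_communities(regions.n_regions, params.n_communities)
    community = reg_comm[region_of]

    responsive = rng.random(n) < params.responsive_fraction
    preferred = rng.choice(np.asarray(params.orientations, dtype=float), size=n)

    n_frames = int(math.ceil((schedule.end_time + 1.0) * params.frame_rate))
    drive = np.zeros((n, n_frames))
    amp = params.response_amplitude * _tuning(
        schedule.orientations[:, None], preferred[None, :], params.kappa)
    for t in range(schedule.n_trials):
        f0 = int(math.floor(schedule.onsets[t] * params.frame_rate))
        f1 = int(math.floor((schedule.onsets[t] + schedule.duration)
                            * params.frame_rate))
        drive[responsive, f0:f1] += amp[t, responsive, None]

    # Shared factors: one per community plus one global; amplitudes are
    # post-kernel SDs, so pre-scale by the inverse smoothing gain.
    gain = _smoothing_gain(params.decay_tau, params.frame_rate)
    shared = np.zeros((n, n_frames))
    if params.within_noise > 0:
        comm_factors = rng.standard_normal((params.n_communities, n_frames))
        shared += (params.within_noise / gain) * comm_factors[community]
    if params.between_noise > 0:
        shared += (params.between_noise / gain) * rng.standard_normal(n_frames)

    traces = _exp_kernel_filter(drive + shared, params.decay_tau, params.frame_rate)
    if params.obs_noise > 0:
        traces += params.obs_noise * rng.standard_normal((n, n_frames))

    return CalciumDataset(
        traces=traces,
        frame_rate=params.frame_rate,
        positions=positions,
        regions=region_of,
        schedule=schedule,
        ground_truth=GroundTruth(
            preferred_orientation=preferred,
            responsive=responsive,
            community=community,
        ),
        region_map=regions,
    )


@dataclass(frozen=True)
class RecoveryScenario:
    """Designed post-operative recovery trajectory.

    Encodes (a) one calcium session per imaging timepoint whose
    :class:`SessionParams` may vary by day (``overrides``) and (b)
    per-animal longitudinal morphology series: a microglial-intensity bump
    peaking at ``micro_peak_day`` and a neuronal-intensity curve equal to
    the microglial curve delayed by ``lag_days``, both with multiplicative
    measurement noise.

    Defaults follow the study's design: eight timepoints (days 1, 4, 7,
    10, 14, 21, 28, 56), microglial peak near day 10 and a neuronal delay
    of 4 days (peak near day 14).
    """

    days: tuple[int, ...] = (1, 4, 7, 10, 14, 21, 28, 56)
    session: SessionParams = field(default_factory=lambda: SessionParams(n_neurons=190))
    overrides: dict[int, dict] = field(default_factory=dict)
    n_regions: int = 19
    sheet_size: tuple[float, float] = (2000.0, 2000.0)
    n_animals: int = 3
    micro_peak_day: float = 10.0
    micro_amplitude: float = 1.0
    micro_width: float = 6.0
    baseline_level: float = 1.0
    lag_days: float = 4.0
    morph_noise_sd: float = 0.05  # relative (multiplicative) noise
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if days[0] < 1 or days[-1] > 56:
            raise ValueError("days must lie within [1, 56]")
        if self.lag_days < 0:
            raise ValueError("lag_days must be nonnegative")
        if self.micro_peak_day + self.lag_days > 56:
            raise ValueError(
                "lag pushes the delayed neuronal curve outside the 56-day window")
        if self.morph_noise_sd < 0:
            raise ValueError("morph_noise_sd must be nonnegative")
        unknown = set(self.overrides) - set(self.days)
        if unknown:
            raise ValueError(f"overrides reference unknown days: {sorted(unknown)}")

    def session_params_for(self, day: int) -> SessionParams:
        return replace(self.session, **self.overrides.get(day, {}))

    def micro_curve(self, day: np.ndarray | float) -> np.ndarray:
        """Ground-truth microglial-intensity curve (Gaussian bump)."""
        d = np.asarray(day, dtype=float)
        return self.baseline_level + self.micro_amplitude * np.exp(
            -((d - self.micro_peak_day) ** 2) / (2.0 * self.micro_width**2))

    def neuro_curve(self, day: np.ndarray | float) -> np.ndarray:
        """Neuronal-intensity curve: the microglial curve delayed by lag."""
        return self.micro_curve(np.asarray(day, dtype=float) - self.lag_days)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "days": list(self.days),
            "session": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in self.session.__dict__.items()},
            "overrides": {str(k): v for k, v in self.overrides.items()},
            "n_regions": self.n_regions,
            "sheet_size": list(self.sheet_size),
            "n_animals": self.n_animals,
            "micro_peak_day": self.micro_peak_day,
            "micro_amplitude": self.micro_amplitude,
            "micro_width": self.micro_width,
            "baseline_level": self.baseline_level,
            "lag_days": self.lag_days,
            "morph_noise_sd": self.morph_noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RecoveryScenario":
        payload = json.loads(Path(path).read_text())
        session_kwargs = payload.pop("session", {})
        for key in ("orientations", "isi_range"):
            if key in session_kwargs:
                session_kwargs[key] = tuple(session_kwargs[key])
        payload["session"] = SessionParams(**session_kwargs)
        payload["days"] = tuple(payload["days"])
        payload["sheet_size"] = tuple(payload["sheet_size"])
        payload["overrides"] = {int(k): v for k, v in
                                payload.get("overrides", {}).items()}
        return cls(**payload)


@dataclass
class RecoveryResult:
    """Output of :func:`simulate_recovery`."""

    sessions: dict[int, CalciumDataset]
    series: list[LongitudinalSeries]
    atlas: RegionMap
    scenario: RecoveryScenario

    def series_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.series], ignore_index=True)


def morphology_series(
    scenario: RecoveryScenario, rng: np.random.Generator | None = None
) -> list[LongitudinalSeries]:
    """Per-animal microglial and neuronal intensity series at the scenario
    timepoints, with multiplicative Gaussian measurement noise."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    days = np.asarray(scenario.days, dtype=int)
    out: list[LongitudinalSeries] = []
    for a in range(scenario.n_animals):
        animal = f"A{a + 1}"
        for modality, curve in (
            ("microglial_intensity", scenario.micro_curve),
            ("neuronal_intensity", scenario.neuro_curve),
        ):
            clean = curve(days)
            noisy = clean * (1.0 + scenario.morph_noise_sd
                             * rng.standard_normal(len(days)))
            out.append(LongitudinalSeries(
                animal=animal, modality=modality, days=days, values=noisy))
    return out


def simulate_recovery(
    scenario: RecoveryScenario, include_sessions: bool = True
) -> RecoveryResult:
    """Generate one calcium session per timepoint plus morphology series.

    All randomness flows from ``scenario.seed`` (independent child streams
    per day and for the morphology series).  ``include_sessions=False``
    produces only the longitudinal series (cheap).
    """
    root = np.random.SeedSequence(scenario.seed)
    n_days = len(scenario.days)
    children = root.spawn(n_days + 1)
    w, h = scenario.sheet_size
    atlas = make_atlas(scenario.n_regions, width=w, height=h)
    sessions: dict[int, CalciumDataset] = {}
    if include_sessions:
        for day, child in zip(scenario.days, children[:n_days]):
            rng = np.random.default_rng(child)
            params = scenario.session_params_for(day)
            schedule = build_schedule(params, seed=rng.integers(2**31))
            sessions[day] = simulate_session(
                params, schedule, atlas, seed=rng.integers(2**31))
    series = morphology_series(scenario, np.random.default_rng(children[-1]))
    return RecoveryResult(sessions=sessions, series=series,
                          atlas=atlas, scenario=scenario)


def disruption_scenario(
    trough_day: int = 21,
    depth: float = 0.40,
    width: float = 6.0,
    base_between: float = 0.05,
    seed: int = 0,
    **scenario_kwargs,
) -> RecoveryScenario:
    """Scenario whose between-community coupling peaks at ``trough_day``.

    Raising the global (between-community) shared-noise amplitude blurs the
    community structure of the functional network, so the designed
    modularity trajectory has its trough at ``trough_day``: the per-day
    between amplitude is ``base_between + depth·exp(−(d−trough)²/2σ²)``.
    """
    days = scenario_kwargs.pop("days", RecoveryScenario.days)
    overrides = {
        int(d): {"between_noise": float(
            base_between + depth * math.exp(
                -((d - trough_day) ** 2) / (2.0 * width**2)))}
        for d in days
    }
    return RecoveryScenario(days=tuple(days), overrides=overrides,
                            seed=seed, **scenario_kwargs)


def simulate_cell_image(
    n_processes: int,
    process_length: float,
    soma_radius: float,
    image_size: tuple[int, int] = (256, 256),
    pixel_size: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Binary star-shaped cell: disk soma plus straight 1-px rays.

    Rays start at the image center and extend to ``soma_radius +
    process_length`` µm, at random but well-separated angles, so the Sholl
    intersection count is analytically known: 1 inside the soma (the whole
    circle lies in the disk), ``n_processes`` between the soma edge and the
    ray tips, 0 beyond.

    Rays are rasterized as densely sampled nearest-pixel polylines, a
    gap-free rasterization: every point of the continuous ray has its
    nearest pixel set, so a circle crossing a ray always meets a ray pixel.

    Returns ``(mask, center)`` with ``center`` in pixel (row, col).
    """
    if n_processes < 0:
        raise ValueError("n_processes must be nonnegative")
    if soma_radius < pixel_size:
        raise ValueError("soma_radius must be at least one pixel")
    if n_processes > 0 and process_length <= 0:
        raise ValueError("process_length must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_size
    center = (h // 2, w // 2)
    tip_px = (soma_radius + process_length) / pixel_size
    if (center[0] + tip_px >= h or center[0] - tip_px < 0
            or center[1] + tip_px >= w or center[1] - tip_px < 0):
        raise ValueError("rays exceed image bounds; enlarge image or shrink cell")

    mask = np.zeros(image_size, dtype=bool)
    rr, cc = np.ogrid[:h, :w]
    soma_px = soma_radius / pixel_size
    mask[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= soma_px**2] = True

    if n_processes > 0:
        # jittered equal spacing: distinct angles with a guaranteed minimum
        # gap of 0.7x the nominal spacing, so rays stay resolvable just
        # outside the soma even for 12 processes
        rotation = rng.uniform(0.0, 2 * np.pi)
        jitter = rng.uniform(-0.15, 0.15, n_processes)
        angles = rotation + 2 * np.pi * (np.arange(n_processes) + jitter) / n_processes
        # stop half a pixel short of the nominal tip so rounding never
        # pushes a ray pixel past the tip radius
        ts = np.arange(0.0, tip_px - 0.5 + 0.125, 0.25)
        for ang in angles:
            rows = np.rint(center[0] + ts * np.sin(ang)).astype(int)
            cols = np.rint(center[1] + ts * np.cos(ang)).astype(int)
            mask[rows, cols] = True
    return mask, center
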