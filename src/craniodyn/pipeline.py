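"""End-to-end recovery analysis over a simulated post-operative scenario.

Runs the full chain — session simulation, responsive-neuron detection,
orientation decoding, neuron- and region-level functional networks,
modularity against the fixed day-1 partition (and a per-day re-optimized
alternative) — for every timepoint, then the longitudinal stage: baseline
normalization, daily interpolation and cross-modal lag correlations
between microglial intensity, neuronal intensity and network modularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode as dec
from . import longitudinal as lng
from . import network as net
from . import respond as rsp
from .synth import LongitudinalSeries, RecoveryResult, RecoveryScenario, simulate_recovery

__all__ = ["PipelineReport", "run_recovery_analysis"]


@dataclass
class PipelineReport:
    """Per-day metrics plus cross-modal lag-correlation results."""

    per_day: pd.DataFrame
    region_counts: pd.DataFrame  # days × regions, raw
    region_counts_normalized: pd.DataFrame
    lag_results: dict[str, lng.LagCorrelationResult]
    day1_partition: np.ndarray
    scenario: RecoveryScenario

    def modularity_series(self, column: str = "modularity_day1_partition"
                          ) -> LongitudinalSeries:
        return LongitudinalSeries(
            animal="population", modality="modularity",
            days=self.per_day["day"].to_numpy(),
            values=self.per_day[column].to_numpy())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_day.to_csv(outdir / "per_day_metrics.csv", index=False)
        self.region_counts.to_csv(outdir / "region_counts.csv")
        self.region_counts_normalized.to_csv(
            outdir / "region_counts_normalized.csv")
        for name, res in self.lag_results.items():
            res.grid.to_csv(outdir / f"lag_{name}.csv", index=False)


def _mean_daily(series: list[LongitudinalSeries], modality: str) -> lng.DailySeries:
    """Average a modality across animals on the measured grid, then
    interpolate to daily resolution."""
    group = [s for s in series if s.modality == modality]
    if not group:
        raise ValueError(f"no series for modality {modality!r}")
    days = group[0].days
    values = np.mean([s.values for s in group], axis=0)
    return lng.interpolate_daily(
        LongitudinalSeries(animal="mean", modality=modality,
                           days=days, values=values))


def run_recovery_analysis(
    scenario: RecoveryScenario,
    run_decoding: bool = True,
    responsive_only_regions: bool = False,
    k_clusters: int = 3,
    max_lag: int = 20,
    result: RecoveryResult | None = None,
) -> PipelineReport:
    """Execute the full pipeline on a recovery scenario.

    ``responsive_only_regions`` restricts region-mean traces to detected
    responsive neurons (all neurons by default, which keeps every region
    populated in small simulations).  Modularity is reported both against
    the day-1 spectral partition carried to every day and against a per-day
    greedy re-optimization.
    """
    if result is None:
        result = simulate_recovery(scenario)
    atlas = result.atlas
    days = list(result.sessions)

    det_params = rsp.DetectionParams()
    mod_params = net.ModularityParams()

    region_nets: dict[int, net.FunctionalNetwork] = {}
    rsets: dict[int, rsp.ResponsiveSet] = {}
    for day in days:
        ds = result.sessions[day]
        rsets[day] = rsp.detect_responsive(ds, det_params)
        region_nets[day] = net.region_network(
            ds, atlas, responsive_only=responsive_only_regions,
            rset=rsets[day])

    day1 = days[0]
    part1 = net.spectral_partition(region_nets[day1], k=k_clusters,
                                   seed=scenario.seed)

    rows = []
    counts_by_day = {}
    for day in days:
        ds = result.sessions[day]
        rset = rsets[day]
        rnet = region_nets[day]
        counts_by_day[day] = rsp.region_counts(rset, ds, atlas)

        responsive_idx = np.flatnonzero(rset.union)
        row: dict[str, float] = {
            "day": day,
            "n_neurons": ds.n_neurons,
            "n_responsive": rset.n_responsive,
        }
        if len(responsive_idx) >= 2:
            nnet = net.connectivity_matrix(
                ds.traces[responsive_idx], nodes=tuple(responsive_idx))
            row["mean_connectivity"] = net.mean_connectivity(nnet)
            row["strong_ratio"] = net.strong_ratio(nnet)
        else:
            row["mean_connectivity"] = np.nan
            row["strong_ratio"] = np.nan

        if set(rnet.nodes) == set(region_nets[day1].nodes):
            row["modularity_day1_partition"] = net.modularity(
                rnet, part1, mod_params)
        else:  # region set changed; day-1 partition not transferable
            row["modularity_day1_partition"] = np.nan
        reopt = net.greedy_partition(rnet, mod_params)
        row["modularity_reoptimized"] = net.modularity(rnet, reopt, mod_params)

        if run_decoding:
            feats = dec.trial_features(ds)
            row["decoding_accuracy"] = dec.decoding_accuracy(
                feats, seed=scenario.seed).accuracy
        rows.append(row)

    per_day = pd.DataFrame(rows)
    region_counts = pd.DataFrame(counts_by_day).T
    region_counts.index.name = "day"
    region_norm = rsp.region_time_normalize(region_counts)

    normalized = lng.normalize_to_baseline(result.series,
                                           baseline_day=int(days[0]))
    micro = _mean_daily(normalized, "microglial_intensity")
    neuro = _mean_daily(normalized, "neuronal_intensity")
    lag_results = {
        "micro_vs_neuro": lng.lag_correlation(micro, neuro, max_lag=max_lag),
    }
    mod_vals = per_day["modularity_day1_partition"].to_numpy()
    if np.all(np.isfinite(mod_vals)):
        mod_daily = lng.interpolate_daily(LongitudinalSeries(
            animal="population", modality="modularity",
            days=np.asarray(days), values=mod_vals))
        lag_results["neuro_vs_modularity"] = lng.lag_correlation(
            neuro, mod_daily, max_lag=max_lag)
        lag_results["micro_vs_modularity"] = lng.lag_correlation(
            micro, mod_daily, max_lag=max_lag)

    return PipelineReport(
        per_day=per_day,
        region_counts=region_counts,
        region_counts_normalized=region_norm,
        lag_results=lag_results,
        day1_partition=part1.labels,
        scenario=scenario,
    )
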