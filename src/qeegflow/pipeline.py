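"""End-to-end orchestration of the quantitative-EEG response analysis.

One call chains: preprocessing -> spectral / entropy features ->
connectivity -> GLOBAL aggregation -> trajectory clustering per
metric x band -> baseline-subtracted statistics (mixed model, Friedman,
Wilcoxon post hocs, BH) -> tidy CSV report.  Fully deterministic given
the configuration seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity, connectivity, preprocess, spectral, stats, trajectories
from .bands import BandScheme
from .complexity import ComplexityConfig
from .preprocess import EpochArray, RawRecording

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    target_hz: float = 200.0
    line_hz: float = 60.0
    highpass_hz: float = 1.0
    epoch_s: float = 5.0
    half_bandwidth_hz: float = 1.0
    pe: ComplexityConfig = field(default_factory=ComplexityConfig)
    k: int = 5
    kmeans_seed: int = 0
    n_init: int = 50
    scheme: BandScheme = field(default_factory=BandScheme)
    #: metrics whose subject-channel trajectories are clustered
    trajectory_metrics: tuple = ("rel_power", "perm_entropy", "spec_entropy")


@dataclass
class AnalysisReport:
    features: pd.DataFrame
    connectivity: pd.DataFrame
    cluster_summary: pd.DataFrame
    lmm: pd.DataFrame
    friedman: pd.DataFrame
    wilcoxon: pd.DataFrame
    kappa: pd.DataFrame | None = None

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "features.csv", index=False)
        self.connectivity.to_csv(outdir / "connectivity.csv", index=False)
        self.cluster_summary.to_csv(outdir / "clusters.csv", index=False)
        self.lmm.to_csv(outdir / "lmm.csv", index=False)
        self.friedman.to_csv(outdir / "friedman.csv", index=False)
        self.wilcoxon.to_csv(outdir / "wilcoxon.csv", index=False)
        if self.kappa is not None:
            self.kappa.to_csv(outdir / "kappa.csv", index=False)


def features_for_epochs(ep: EpochArray, cfg: PipelineConfig) -> pd.DataFrame:
    """All channel-level feature rows (plus GLOBAL) for one recording:
    4 relative powers, 5 ratios, 2 entropies x 5 bands."""
    est = spectral.multitaper_psd(ep, cfg.half_bandwidth_hz)
    parts = []
    rel = spectral.relative_band_power(est, cfg.scheme)
    parts.append(rel)
    parts.append(spectral.band_ratios(rel))
    for band in cfg.scheme.all_names:
        parts.append(complexity.band_limited_pe(ep, band, cfg.pe, cfg.scheme))
        parts.append(complexity.spectral_entropy(est, band, cfg.scheme))
    return pd.concat(parts, ignore_index=True)


def connectivity_for_epochs(ep: EpochArray, cfg: PipelineConfig) -> pd.DataFrame:
    """Pair and GLOBAL coherence/wPLI rows for one recording."""
    cs = connectivity.cross_spectra(ep, cfg.half_bandwidth_hz)
    pair_rows = pd.concat(
        [connectivity.coherence(cs, scheme=cfg.scheme),
         connectivity.wpli(cs, scheme=cfg.scheme)],
        ignore_index=True,
    )
    glob = connectivity.global_connectivity(pair_rows, n_channels=len(ep.montage))
    return pd.concat([pair_rows, glob], ignore_index=True)


def connectivity_as_features(conn: pd.DataFrame) -> pd.DataFrame:
    """GLOBAL connectivity rows reshaped into feature-table layout so the
    longitudinal statistics treat them like any other metric."""
    g = conn[conn["pair"] == "GLOBAL"]
    return pd.DataFrame({
        "subject": g.subject, "channel": "GLOBAL", "timepoint": g.timepoint,
        "metric": g.method, "band": g.band, "value": g.value,
    })


def _metric_band_pairs(features: pd.DataFrame, metrics) -> list:
    pairs = features[features.metric.isin(metrics)][["metric", "band"]]
    return list(pairs.drop_duplicates().itertuples(index=False, name=None))


def run_pipeline(
    cohort,
    cfg: PipelineConfig | None = None,
    ratings: pd.DataFrame | None = None,
    with_connectivity: bool = True,
) -> AnalysisReport:
    """Analyze a SyntheticCohort (or any {(subject, timepoint): RawRecording}
    mapping exposed as ``cohort.recordings``)."""
    cfg = cfg or PipelineConfig()
    feature_parts, conn_parts = [], []
    for (subject, tp), rec in sorted(cohort.recordings.items()):
        ep = preprocess.preprocess_recording(
            rec, target_hz=cfg.target_hz, line_hz=cfg.line_hz,
            highpass_hz=cfg.highpass_hz, epoch_s=cfg.epoch_s,
        )
        feature_parts.append(features_for_epochs(ep, cfg))
        if with_connectivity:
            conn_parts.append(connectivity_for_epochs(ep, cfg))
        log.info("features done: %s %s", subject, tp)
    features = pd.concat(feature_parts, ignore_index=True)
    conn = (pd.concat(conn_parts, ignore_index=True)
            if conn_parts else pd.DataFrame(columns=connectivity.CONNECTIVITY_COLUMNS))
    stats_features = features
    if with_connectivity:
        stats_features = pd.concat(
            [features, connectivity_as_features(conn)], ignore_index=True
        )

    # trajectory clustering per metric x band
    summaries = []
    for metric, band in _metric_band_pairs(features, cfg.trajectory_metrics):
        tm = trajectories.build_trajectories(features, metric, band)
        sol = trajectories.kmeans_trajectories(
            tm, k=cfg.k, seed=cfg.kmeans_seed, n_init=cfg.n_init
        )
        summaries.append(trajectories.cluster_summary(sol, tm))
    cluster_summary = pd.concat(summaries, ignore_index=True)

    # baseline-referenced statistics per metric x band
    delta = stats.delta_from_baseline(stats_features)
    lmm_rows, fried_rows, wil_rows = [], [], []
    for metric, band in _metric_band_pairs(stats_features, stats_features.metric.unique()):
        try:
            res = stats.fit_lmm(delta, metric, band)
        except ValueError:
            continue
        t = res.table.copy()
        t.insert(0, "metric", metric)
        t.insert(1, "band", band)
        t["subject_var"] = res.subject_var
        t["residual_var"] = res.residual_var
        t["converged"] = res.converged
        lmm_rows.append(t)
        fr = stats.friedman_from_features(stats_features, metric, band)
        fried_rows.append(dict(metric=metric, band=band,
                               statistic=fr.statistic, p=fr.p, n=fr.n))
        for w in stats.wilcoxon_posthoc(delta, metric, band):
            wil_rows.append(dict(metric=metric, band=band,
                                 timepoint=w.extra["timepoint"],
                                 statistic=w.statistic, p=w.p,
                                 p_bh=w.extra["p_bh"], n=w.n))
    report = AnalysisReport(
        features=features,
        connectivity=conn,
        cluster_summary=cluster_summary,
        lmm=pd.concat(lmm_rows, ignore_index=True),
        friedman=pd.DataFrame(fried_rows),
        wilcoxon=pd.DataFrame(wil_rows),
    )
    if ratings is not None:
        rows = []
        for w in ("linear", "quadratic"):
            k = stats.weighted_kappa(ratings, w)
            rows.append(dict(weighting=w, kappa=k.statistic, n=k.n))
        report.kappa = pd.DataFrame(rows)
    return report
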