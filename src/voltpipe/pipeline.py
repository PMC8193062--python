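"""End-to-end orchestration: movie → ROIs → spikes → events → statistics.

``run_pipeline`` executes the full analysis on either simulated preset
cohorts (with ground-truth scoring) or recorded movie stacks, writing CSV
tables and a JSON run manifest when an output directory is given.  All
randomness flows from one seed, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .movie import Movie, Trace, read_movie, smooth_trace, compute_dff
from .segmentation import segment_movie, extract_traces, ROISet
from .simulate import SimConfig, GroundTruth, preset, simulate_cohort, PRESET_NAMES
from .spikes import SpikeTrain, detect_spikes
from .waveforms import APWaveformSet, extract_waveforms
from .events import (
    EventAnnotation,
    FiringStats,
    detect_plateaus,
    detect_bursts,
    classify_events,
    compute_firing_stats,
)
from .stats import DetectionScore, score_detection, match_rois

__all__ = ["PipelineConfig", "NeuronResult", "PipelineResult", "run_pipeline"]

log = logging.getLogger("voltpipe")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``preset``/``sim_config``/``movie_paths`` selects the
    input.  Detector and segmentation defaults follow the package-wide
    defaults documented in each module.
    """

    preset: str | None = None
    scale: float = 1.0
    sim_config: SimConfig | None = None
    movie_paths: list[str] | None = None
    seed: int = 0
    # denoising
    spatial_sigma_px: float = 1.0
    temporal_window_frames: int = 3
    # segmentation
    components_per_neuron: int = 3
    max_components: int = 60
    mu: float = 0.5
    min_quality: float = 0.2
    mask_threshold: float = 0.5
    expected_neurons: int | None = None  # required for recorded movies
    # traces
    baseline_method: str = "sliding_percentile"
    # detection
    k_sd: float = 3.0
    min_isi_ms: float = 20.0
    # waveforms
    window_ms: float = 300.0
    # scoring
    match_tolerance_ms: float = 6.0
    out_dir: str | None = None

    def resolve_inputs(self) -> str:
        chosen = [
            k
            for k, v in (
                ("preset", self.preset),
                ("sim_config", self.sim_config),
                ("movie_paths", self.movie_paths),
            )
            if v
        ]
        if len(chosen) != 1:
            raise ValueError(
                f"exactly one of preset/sim_config/movie_paths must be set, got {chosen}"
            )
        return chosen[0]


@dataclass
class NeuronResult:
    """Everything the pipeline derived for one recovered neuron."""

    neuron_id: int
    movie_index: int
    trace: Trace
    spiketrain: SpikeTrain
    waveforms: APWaveformSet
    annotation: EventAnnotation
    stats: FiringStats
    matched_truth: int | None = None  # index into the movie's ground truth
    spike_score: DetectionScore | None = None


@dataclass
class PipelineResult:
    neurons: list[NeuronResult]
    roisets: list[ROISet]
    ground_truths: list[GroundTruth]
    manifest: dict

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for nr in self.neurons:
            rows.append(
                {
                    "neuron_id": nr.neuron_id,
                    "movie_index": nr.movie_index,
                    "firing_rate_hz": nr.stats.firing_rate,
                    "bursting_rate_per_min": nr.stats.bursting_rate,
                    "n_spikes": nr.stats.n_spikes,
                    "n_bursts": nr.stats.n_bursts,
                    "mean_isi_s": float(np.mean(nr.stats.isi_list))
                    if nr.stats.isi_list.size
                    else np.nan,
                    "mean_fwhm_ms": float(np.nanmean(nr.waveforms.fwhm_ms[nr.waveforms.valid()]))
                    if nr.waveforms.valid().any()
                    else np.nan,
                    "matched_truth": nr.matched_truth,
                    "spike_f1": nr.spike_score.f1 if nr.spike_score else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def spike_frame(self) -> pd.DataFrame:
        rows = []
        for nr in self.neurons:
            for t, sc in zip(nr.spiketrain.spike_times, nr.spiketrain.neo_scores):
                rows.append({"neuron_id": nr.neuron_id, "spike_time_s": t, "neo_score": sc})
        return pd.DataFrame(rows, columns=["neuron_id", "spike_time_s", "neo_score"])

    def waveform_frame(self) -> pd.DataFrame:
        rows = []
        for nr in self.neurons:
            wf = nr.waveforms
            for j in range(wf.n_spikes):
                rows.append(
                    {
                        "neuron_id": nr.neuron_id,
                        "spike_time_s": wf.spike_times[j],
                        "fwhm_ms": wf.fwhm_ms[j],
                        "amplitude_pct": wf.amplitude[j],
                        "rise_ms": wf.rise_ms[j],
                        "decay_ms": wf.decay_ms[j],
                        "flag": wf.flags[j],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["neuron_id", "spike_time_s", "fwhm_ms", "amplitude_pct",
                     "rise_ms", "decay_ms", "flag"],
        )

    def event_frame(self) -> pd.DataFrame:
        rows = []
        for nr in self.neurons:
            for e in nr.annotation.events:
                rows.append(
                    {
                        "neuron_id": nr.neuron_id,
                        "event_type": e.type,
                        "n_spikes": e.n_spikes,
                        "start_s": e.start,
                        "end_s": e.end,
                        "on_plateau": e.on_plateau,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["neuron_id", "event_type", "n_spikes", "start_s", "end_s", "on_plateau"],
        )

    def cohort_summary(self) -> dict:
        df = self.stats_frame()
        valid_fwhm = df["mean_fwhm_ms"].dropna()
        per_spike_fwhm = np.concatenate(
            [
                nr.waveforms.fwhm_ms[nr.waveforms.valid()]
                for nr in self.neurons
                if nr.waveforms.valid().any()
            ]
        ) if self.neurons else np.empty(0)
        out = {
            "n_neurons": self.n_neurons,
            "mean_firing_rate_hz": float(df["firing_rate_hz"].mean()) if len(df) else np.nan,
            "sd_firing_rate_hz": float(df["firing_rate_hz"].std(ddof=1)) if len(df) > 1 else np.nan,
            "mean_bursting_rate_per_min": float(df["bursting_rate_per_min"].mean())
            if len(df)
            else np.nan,
            "mean_fwhm_ms_per_neuron": float(valid_fwhm.mean()) if len(valid_fwhm) else np.nan,
            "mean_fwhm_ms_per_spike": float(per_spike_fwhm.mean())
            if per_spike_fwhm.size
            else np.nan,
            "n_spikes_total": int(df["n_spikes"].sum()) if len(df) else 0,
        }
        if any(nr.spike_score for nr in self.neurons):
            tp = sum(nr.spike_score.true_positives for nr in self.neurons if nr.spike_score)
            fp = sum(nr.spike_score.false_positives for nr in self.neurons if nr.spike_score)
            fn = sum(nr.spike_score.false_negatives for nr in self.neurons if nr.spike_score)
            # truth neurons with no matched ROI contribute false negatives
            matched_truth = {
                (nr.movie_index, nr.matched_truth)
                for nr in self.neurons
                if nr.matched_truth is not None
            }
            for m, gt in enumerate(self.ground_truths):
                for j in range(gt.n_neurons):
                    if (m, j) not in matched_truth:
                        fn += gt.spike_times[j].size
            precision = tp / (tp + fp) if (tp + fp) else 0.0
            recall = tp / (tp + fn) if (tp + fn) else 0.0
            out["spike_precision"] = precision
            out["spike_recall"] = recall
            out["spike_f1"] = (
                2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
            )
        return out

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.stats_frame().to_csv(out_dir / "stats.csv", index=False)
        self.spike_frame().to_csv(out_dir / "spikes.csv", index=False)
        self.waveform_frame().to_csv(out_dir / "waveforms.csv", index=False)
        self.event_frame().to_csv(out_dir / "events.csv", index=False)
        summary = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                   for k, v in self.cohort_summary().items()}
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return out_dir


def _analyze_movie(
    movie: Movie,
    cfg: PipelineConfig,
    movie_index: int,
    expected: int,
    gt: GroundTruth | None,
    id_offset: int,
) -> tuple[list[NeuronResult], ROISet]:
    from .movie import spatiotemporal_filter

    t0 = time.time()
    spatial = spatiotemporal_filter(movie, cfg.spatial_sigma_px, 1)
    roiset = segment_movie(
        spatial,
        expected_neurons=expected,
        components_per_neuron=cfg.components_per_neuron,
        max_components=cfg.max_components,
        mu=cfg.mu,
        seed=cfg.seed + movie_index,
        min_quality=cfg.min_quality,
        mask_threshold=cfg.mask_threshold,
    )
    log.info(
        "movie %d: %d ROIs from %d expected neurons (%.1f s)",
        movie_index, roiset.n_rois, expected, time.time() - t0,
    )
    traces = extract_traces(spatial, roiset, baseline_method=cfg.baseline_method)
    matches = {}
    if gt is not None:
        matches = {i: (j, jac) for i, j, jac in match_rois(roiset.masks, gt.masks)}
    results = []
    for i, tr in enumerate(traces):
        # temporal smoothing on the extracted trace (commutes with the
        # mask mean); waveforms are measured on the unsmoothed trace so
        # the moving average does not broaden the APs
        det_trace = Trace(
            values=smooth_trace(tr.values, cfg.temporal_window_frames),
            frame_rate=tr.frame_rate,
            neuron_id=tr.neuron_id,
        )
        st = detect_spikes(det_trace, k_sd=cfg.k_sd, min_isi_ms=cfg.min_isi_ms)
        wf = extract_waveforms(tr, st, window_ms=cfg.window_ms)
        plateaus = detect_plateaus(tr, spike_times=st.spike_times)
        bursts = detect_bursts(st.spike_times)
        ann = classify_events(st.spike_times, bursts, plateaus, neuron_id=id_offset + i)
        stats = compute_firing_stats(ann, st.spike_times, tr.duration)
        nr = NeuronResult(
            neuron_id=id_offset + i,
            movie_index=movie_index,
            trace=tr,
            spiketrain=st,
            waveforms=wf,
            annotation=ann,
            stats=stats,
        )
        if gt is not None and i in matches:
            j, _ = matches[i]
            nr.matched_truth = j
            nr.spike_score = score_detection(
                st.spike_times, gt.spike_times[j], tolerance_ms=cfg.match_tolerance_ms
            )
        results.append(nr)
    return results, roiset


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and return a result bundle.

    Stages: simulate/load → denoise → PCA/ICA segmentation → trace
    extraction → NEO spike detection → waveform metrics → plateau/burst
    classification → firing statistics (→ ground-truth scoring for
    simulated input).  Writes CSV/JSON outputs when ``out_dir`` is set.
    """
    mode = config.resolve_inputs()
    t_start = time.time()
    movies: list[Movie] = []
    gts: list[GroundTruth | None] = []
    if mode == "preset":
        sim = preset(config.preset, scale=config.scale, seed=config.seed)
        for movie, gt in simulate_cohort(sim):
            movies.append(movie)
            gts.append(gt)
    elif mode == "sim_config":
        for movie, gt in simulate_cohort(config.sim_config):
            movies.append(movie)
            gts.append(gt)
    else:
        for p in config.movie_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input movie not found: {p}")
        if config.expected_neurons is None:
            raise ValueError("expected_neurons is required for recorded movies")
        for p in config.movie_paths:
            movies.append(read_movie(p))
            gts.append(None)
    neurons: list[NeuronResult] = []
    roisets: list[ROISet] = []
    for m, (movie, gt) in enumerate(zip(movies, gts)):
        expected = gt.n_neurons if gt is not None else config.expected_neurons
        try:
            res, roiset = _analyze_movie(movie, config, m, expected, gt, len(neurons))
        except Exception as err:
            raise RuntimeError(f"pipeline failed at movie {m}: {err}") from err
        neurons.extend(res)
        roisets.append(roiset)
    def _jsonable(v):
        if isinstance(v, dict):
            return {k: _jsonable(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_jsonable(x) for x in v]
        if isinstance(v, float) and not np.isfinite(v):
            return None
        return v

    manifest = {
        "voltpipe_version": __version__,
        "numpy_version": np.__version__,
        "config": _jsonable(asdict(config)),
        "n_movies": len(movies),
        "n_neurons_recovered": len(neurons),
        "n_spikes_total": int(sum(nr.spiketrain.n_spikes for nr in neurons)),
        "n_bursts_total": int(sum(nr.stats.n_bursts for nr in neurons)),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    result = PipelineResult(
        neurons=neurons,
        roisets=roisets,
        ground_truths=[g for g in gts if g is not None],
        manifest=manifest,
    )
    if config.out_dir:
        result.save(config.out_dir)
    return result
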