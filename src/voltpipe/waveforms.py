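"""Per-spike AP waveform extraction and shape quantification.

Segments of the ΔF/F₀ trace in a fixed window (default 300 ms) centred on
each detected AP peak are aligned by integer shift; AP duration is the
full width at half-maximal amplitude (FWHM) with half-max crossings found
by linear interpolation between samples, giving sub-frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movie import Trace
from .spikes import SpikeTrain

__all__ = [
    "APWaveformSet",
    "extract_waveforms",
    "compute_fwhm",
    "waveform_params",
]

FLAG_OK = ""
FLAG_OVERLAP = "overlap"  # another detected spike inside this window
FLAG_TRUNCATED = "truncated"  # no half-max crossing on one side
FLAG_INVALID = "invalid"  # degenerate segment (no peak above baseline)


@dataclass
class APWaveformSet:
    """Aligned per-spike segments and their shape metrics."""

    segments: np.ndarray  # (n_spikes, L)
    aligned_peak_index: int
    frame_rate: float
    spike_times: np.ndarray  # seconds, spikes actually included
    fwhm_ms: np.ndarray
    amplitude: np.ndarray  # % ΔF/F₀, peak − local baseline
    rise_ms: np.ndarray  # 10→90% before the peak
    decay_ms: np.ndarray  # 90→10% after the peak
    flags: list[str] = field(default_factory=list)
    n_edge_excluded: int = 0
    neuron_id: int = 0

    @property
    def n_spikes(self) -> int:
        return self.segments.shape[0]

    @property
    def mean_waveform(self) -> np.ndarray:
        if self.n_spikes == 0:
            return np.empty(0)
        return self.segments.mean(axis=0)

    def valid(self) -> np.ndarray:
        """Spikes whose FWHM is usable in summaries."""
        return np.array(
            [f in (FLAG_OK, FLAG_OVERLAP) for f in self.flags], dtype=bool
        ) & np.isfinite(self.fwhm_ms)


def extract_waveforms(
    trace: Trace, spiketrain: SpikeTrain, window_ms: float = 300.0
) -> APWaveformSet:
    """Cut fixed-length windows around each detected spike.

    Segment length is ``round(window_ms·frame_rate/1000) + 1`` samples,
    centred on the trace-sample peak.  Spikes closer than half a window to
    either trace edge are excluded and counted.  Alignment re-centres each
    segment on the local trace maximum within ±2 frames of the detection
    (integer shift only).  Windows containing another detected spike are
    flagged ``overlap``.
    """
    fs = trace.frame_rate
    L = int(round(window_ms * fs / 1000.0)) + 1
    half = (L - 1) // 2
    s = trace.values
    if s.size < L:
        raise ValueError("trace shorter than one waveform window")
    segs, times, flags = [], [], []
    excluded = 0
    all_idx = spiketrain.spike_indices
    for i in all_idx:
        lo, hi = max(i - 2, 0), min(i + 3, s.size)
        c = lo + int(np.argmax(s[lo:hi]))  # integer re-alignment on the trace peak
        if c - half < 0 or c + half >= s.size:
            excluded += 1
            continue
        seg = s[c - half : c + half + 1].copy()
        others = all_idx[(all_idx != i) & (np.abs(all_idx - c) <= half)]
        segs.append(seg)
        times.append(c / fs)
        flags.append(FLAG_OVERLAP if others.size else FLAG_OK)
    n = len(segs)
    segments = np.asarray(segs).reshape(n, L) if n else np.empty((0, L))
    out = APWaveformSet(
        segments=segments,
        aligned_peak_index=half,
        frame_rate=fs,
        spike_times=np.asarray(times),
        fwhm_ms=np.full(n, np.nan),
        amplitude=np.full(n, np.nan),
        rise_ms=np.full(n, np.nan),
        decay_ms=np.full(n, np.nan),
        flags=flags,
        n_edge_excluded=excluded,
        neuron_id=trace.neuron_id,
    )
    for j in range(n):
        fwhm, flag = compute_fwhm(segments[j], fs, peak_index=half, return_flag=True)
        out.fwhm_ms[j] = fwhm
        amp, rise, decay, pflag = waveform_params(
            segments[j], fs, peak_index=half, return_flag=True
        )
        out.amplitude[j] = amp
        out.rise_ms[j] = rise
        out.decay_ms[j] = decay
        if flag or pflag:
            out.flags[j] = flag or pflag
    return out


def _segment_baseline(segment: np.ndarray, frame_rate: float,
                      baseline_ms: float = 50.0) -> float:
    nb = max(int(round(baseline_ms * frame_rate / 1000.0)), 1)
    nb = min(nb, segment.size // 3)
    return float(np.median(np.concatenate([segment[:nb], segment[-nb:]])))


def _cross_left(seg, peak_idx, level):
    """Interpolated time (in samples, relative to 0) where the segment
    last rises through ``level`` before the peak."""
    for i in range(peak_idx, 0, -1):
        if seg[i - 1] < level <= seg[i]:
            frac = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
            return (i - 1) + frac
    return None


def _cross_right(seg, peak_idx, level):
    for i in range(peak_idx, seg.size - 1):
        if seg[i] >= level > seg[i + 1]:
            frac = (seg[i] - level) / (seg[i] - seg[i + 1])
            return i + frac
    return None


def _find_peak(seg: np.ndarray, peak_index: int | None, search_radius: int) -> int:
    """Peak sample: global argmax, or argmax near a known peak position.

    Constraining the search matters for windows that contain a second
    spike (doublets/bursts): the metric must describe the AP the window
    was cut around, not its larger neighbour.
    """
    if peak_index is None:
        return int(np.argmax(seg))
    lo = max(peak_index - search_radius, 0)
    hi = min(peak_index + search_radius + 1, seg.size)
    return lo + int(np.argmax(seg[lo:hi]))


def compute_fwhm(
    segment: np.ndarray,
    frame_rate: float,
    baseline_ms: float = 50.0,
    peak_index: int | None = None,
    search_radius: int = 2,
    return_flag: bool = False,
):
    """Full width at half-maximal amplitude of one AP segment, in ms.

    Baseline is the median of the first and last ``baseline_ms`` of the
    segment; half-max = baseline + (peak − baseline)/2; crossings are
    linearly interpolated, searching outward from the peak.  Returns NaN
    (with flag ``truncated`` or ``invalid``) if a crossing is missing or
    the segment has no peak above baseline.  ``peak_index`` (if given)
    anchors the peak search to the aligned AP.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 5:
        raise ValueError("segment too short")
    base = _segment_baseline(seg, frame_rate, baseline_ms)
    peak_idx = _find_peak(seg, peak_index, search_radius)
    peak = seg[peak_idx]
    if peak <= base:
        return (np.nan, FLAG_INVALID) if return_flag else np.nan
    half = base + (peak - base) / 2.0
    left = _cross_left(seg, peak_idx, half)
    right = _cross_right(seg, peak_idx, half)
    if left is None or right is None:
        return (np.nan, FLAG_TRUNCATED) if return_flag else np.nan
    fwhm = (right - left) * 1000.0 / frame_rate
    return (fwhm, FLAG_OK) if return_flag else fwhm


def waveform_params(
    segment: np.ndarray,
    frame_rate: float,
    baseline_ms: float = 50.0,
    peak_index: int | None = None,
    search_radius: int = 2,
    return_flag: bool = False,
):
    """Amplitude, 10–90% rise time and 90–10% decay time of one segment.

    Amplitude is peak − baseline (percent ΔF/F₀); rise/decay crossings are
    linearly interpolated on the flanks adjacent to the peak.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 5:
        raise ValueError("segment too short")
    base = _segment_baseline(seg, frame_rate, baseline_ms)
    peak_idx = _find_peak(seg, peak_index, search_radius)
    amp = seg[peak_idx] - base
    if amp <= 0:
        out = (np.nan, np.nan, np.nan)
        return (*out, FLAG_INVALID) if return_flag else out
    lvl10 = base + 0.1 * amp
    lvl90 = base + 0.9 * amp
    t10l = _cross_left(seg, peak_idx, lvl10)
    t90l = _cross_left(seg, peak_idx, lvl90)
    t90r = _cross_right(seg, peak_idx, lvl90)
    t10r = _cross_right(seg, peak_idx, lvl10)
    ms = 1000.0 / frame_rate
    rise = (t90l - t10l) * ms if (t10l is not None and t90l is not None) else np.nan
    decay = (t10r - t90r) * ms if (t90r is not None and t10r is not None) else np.nan
    flag = FLAG_OK if np.isfinite(rise) and np.isfinite(decay) else FLAG_TRUNCATED
    return (amp, rise, decay, flag) if return_flag else (amp, rise, decay)
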