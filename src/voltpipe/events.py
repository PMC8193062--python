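"""Plateau detection, spike-event taxonomy, and firing statistics.

Events are a partition of a neuron's spike train: a *burst* is any
sequence of four or more APs whose mean inter-spike interval (ISI) is
below 250 ms; remaining spikes are grouped by the same 250 ms gap into
*singlets*, *doublets* and *triplets*.  Each event is tagged with whether
it rides on a slow plateau depolarization, detected as a sustained
elevation of the low-pass-filtered ΔF/F₀ trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig

from .movie import Trace

__all__ = [
    "Event",
    "EventAnnotation",
    "FiringStats",
    "detect_plateaus",
    "detect_bursts",
    "classify_events",
    "compute_firing_stats",
    "BURST_MAX_MEAN_ISI_MS",
    "BURST_MIN_SPIKES",
]

BURST_MAX_MEAN_ISI_MS = 250.0
BURST_MIN_SPIKES = 4


@dataclass
class Event:
    type: str  # singlet | doublet | triplet | burst
    spike_times: np.ndarray  # seconds
    on_plateau: bool = False

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def start(self) -> float:
        return float(self.spike_times[0])

    @property
    def end(self) -> float:
        return float(self.spike_times[-1])


@dataclass
class EventAnnotation:
    """Classified events and plateau intervals for one neuron."""

    events: list[Event] = field(default_factory=list)
    plateau_intervals: list[tuple[float, float]] = field(default_factory=list)
    neuron_id: int = 0

    @property
    def bursts(self) -> list[Event]:
        return [e for e in self.events if e.type == "burst"]

    def n_spikes(self) -> int:
        return sum(e.n_spikes for e in self.events)


@dataclass
class FiringStats:
    """Descriptive firing statistics for one neuron."""

    firing_rate: float  # Hz, spikes / recording duration
    bursting_rate: float  # bursts per minute
    isi_list: np.ndarray  # s, successive spike intervals
    ibi_list: np.ndarray  # s, burst onset-to-onset intervals
    burst_durations: np.ndarray  # s, first-to-last spike of each burst
    n_spikes: int
    n_bursts: int
    recording_duration: float
    neuron_id: int = 0


# ---------------------------------------------------------------------------
# Plateaus
# ---------------------------------------------------------------------------


def detect_plateaus(
    trace: Trace,
    lowpass_cutoff_hz: float = 5.0,
    k_sd_plateau: float = 3.0,
    min_duration_ms: float = 200.0,
    median_window_ms: float = 80.0,
    spike_times: np.ndarray | None = None,
    excise_pre_ms: float = 20.0,
    excise_post_ms: float = 80.0,
    min_amplitude_pct: float = 0.5,
) -> list[tuple[float, float]]:
    """Find sustained slow depolarizations.

    When detected ``spike_times`` are supplied, each AP (including its
    slow decay tail) is excised and bridged by linear interpolation, so
    only genuinely sustained depolarization remains; a rolling median
    (window ``median_window_ms``) then suppresses any leftover fast
    transients, followed by a zero-phase low-pass below the AP band.  A
    plateau is a maximal interval where the slow signal exceeds
    ``k_sd_plateau`` times a robust (MAD-based) estimate of its noise
    floor — and an absolute floor of ``min_amplitude_pct`` percent
    ΔF/F₀, so that statistically significant but biologically negligible
    drifts in very clean traces do not qualify — for at least
    ``min_duration_ms``.  An empty list is a valid result.
    """
    from scipy.ndimage import median_filter

    s = np.asarray(trace.values, dtype=float)
    fs = trace.frame_rate
    if lowpass_cutoff_hz >= fs / 2:
        raise ValueError("low-pass cutoff must be below Nyquist")
    if s.size < 20:
        return []
    if spike_times is not None and len(spike_times):
        s = s.copy()
        excised = np.zeros(s.size, dtype=bool)
        pre = int(round(excise_pre_ms / 1000.0 * fs))
        post = int(round(excise_post_ms / 1000.0 * fs))
        for t0 in np.asarray(spike_times, dtype=float):
            c = int(round(t0 * fs))
            excised[max(c - pre, 0) : min(c + post + 1, s.size)] = True
        if excised.all():
            return []
        idx = np.arange(s.size)
        s[excised] = np.interp(idx[excised], idx[~excised], s[~excised])
    med_win = int(round(median_window_ms / 1000.0 * fs)) | 1
    slow = median_filter(s, size=min(med_win, s.size | 1), mode="nearest")
    sos = ssig.butter(2, lowpass_cutoff_hz, btype="low", fs=fs, output="sos")
    slow = ssig.sosfiltfilt(sos, slow)
    med = np.median(slow)
    mad = np.median(np.abs(slow - med))
    floor = 1.4826 * mad
    if floor == 0:
        floor = slow.std() or np.finfo(float).eps
    level = max(k_sd_plateau * floor, min_amplitude_pct)
    above = slow > med + level
    min_len = int(round(min_duration_ms / 1000.0 * fs))
    intervals: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                intervals.append((i / fs, (j + 1) / fs))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# Bursts
# ---------------------------------------------------------------------------


def _mean_isi_ms(times: np.ndarray, i: int, j: int) -> float:
    return (times[j] - times[i]) / (j - i) * 1000.0


def detect_bursts(
    spike_times: np.ndarray,
    max_mean_isi_ms: float = BURST_MAX_MEAN_ISI_MS,
    min_spikes: int = BURST_MIN_SPIKES,
) -> list[tuple[int, int]]:
    """Find bursts: ≥ 4 APs with mean ISI below 250 ms.

    Left-to-right greedy scan: a burst starts wherever ``min_spikes``
    consecutive spikes satisfy the mean-ISI bound, and is extended one
    spike at a time while the running mean ISI stays below the bound; the
    scan resumes after the emitted run.  Returns ``(first, last)`` spike
    index pairs (inclusive); bursts never overlap.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    bursts: list[tuple[int, int]] = []
    n = t.size
    i = 0
    while i <= n - min_spikes:
        j = i + min_spikes - 1
        if _mean_isi_ms(t, i, j) < max_mean_isi_ms:
            while j + 1 < n and _mean_isi_ms(t, i, j + 1) < max_mean_isi_ms:
                j += 1
            bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts


# ---------------------------------------------------------------------------
# Event taxonomy
# ---------------------------------------------------------------------------

_SMALL_EVENT_TYPE = {1: "singlet", 2: "doublet", 3: "triplet"}


def _on_plateau(spike_times: np.ndarray, plateaus) -> bool:
    med = float(np.median(spike_times))
    return any(a <= med <= b for a, b in plateaus)


def classify_events(
    spike_times: np.ndarray,
    bursts: list[tuple[int, int]] | None = None,
    plateaus: list[tuple[float, float]] | None = None,
    gap_ms: float = BURST_MAX_MEAN_ISI_MS,
    neuron_id: int = 0,
) -> EventAnnotation:
    """Partition a spike train into singlet/doublet/triplet/burst events.

    Burst spikes come from :func:`detect_bursts`; remaining spikes are
    grouped by gap clustering (successive free spikes closer than
    ``gap_ms``, provided no burst lies between them).  Every spike belongs
    to exactly one event.  An event is ``on_plateau`` if its median spike
    time falls inside a plateau interval.
    """
    t = np.asarray(spike_times, dtype=float)
    if bursts is None:
        bursts = detect_bursts(t)
    plateaus = plateaus or []
    in_burst = np.zeros(t.size, dtype=bool)
    events: list[Event] = []
    for i, j in bursts:
        if in_burst[i : j + 1].any():
            raise RuntimeError("inconsistent burst input: spike assigned twice")
        in_burst[i : j + 1] = True
        events.append(Event("burst", t[i : j + 1].copy()))
    free = np.flatnonzero(~in_burst)
    gap = gap_ms / 1000.0
    k = 0
    while k < free.size:
        group = [free[k]]
        while (
            k + 1 < free.size
            and free[k + 1] == group[-1] + 1  # no burst spike intervenes
            and t[free[k + 1]] - t[group[-1]] < gap
        ):
            k += 1
            group.append(free[k])
        if len(group) > 3:
            # ≥4 consecutive free spikes all within the gap would qualify as
            # a burst, so detect_bursts output was inconsistent with t
            raise RuntimeError("inconsistent inputs: free spike cluster of size ≥ 4")
        events.append(Event(_SMALL_EVENT_TYPE[len(group)], t[list(group)].copy()))
        k += 1
    events.sort(key=lambda e: e.start)
    for e in events:
        e.on_plateau = _on_plateau(e.spike_times, plateaus)
    ann = EventAnnotation(events=events, plateau_intervals=list(plateaus),
                          neuron_id=neuron_id)
    assert ann.n_spikes() == t.size
    return ann


def compute_firing_stats(
    annotation: EventAnnotation,
    spike_times: np.ndarray,
    duration: float,
    neuron_id: int | None = None,
) -> FiringStats:
    """Firing rate, bursting rate, ISI/IBI lists and burst durations.

    Firing rate is spike count over recording duration (Hz); bursting
    rate is bursts per minute; IBI is measured burst onset to onset.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(spike_times, dtype=float)
    bursts = annotation.bursts
    onsets = np.array([b.start for b in bursts])
    return FiringStats(
        firing_rate=t.size / duration,
        bursting_rate=len(bursts) / duration * 60.0,
        isi_list=np.diff(t) if t.size > 1 else np.empty(0),
        ibi_list=np.diff(onsets) if onsets.size > 1 else np.empty(0),
        burst_durations=np.array([b.end - b.start for b in bursts]),
        n_spikes=int(t.size),
        n_bursts=len(bursts),
        recording_duration=float(duration),
        neuron_id=annotation.neuron_id if neuron_id is None else neuron_id,
    )
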