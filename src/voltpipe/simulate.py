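"""Synthetic voltage-imaging movies with ground truth.

Emulates recordings of cultured neurons loaded with a fast voltage dye
that brightens on depolarization, imaged by an sCMOS camera at 300–500 Hz
with ~2 ms exposure for ~3 minute epochs.  Each neuron is a compact soma
footprint whose pixel intensity follows

    F(x, t) = background + bleach(t) · baseline · Σ_n w_n(x) · (1 + s_n(t)/100)

where s_n(t) is the neuron's percent ΔF/F₀ built from an AP kernel
convolved with a spike train plus slow plateau depolarizations, and
optional Poisson shot noise is applied per pixel before 16-bit clipping.

Named presets parameterize cohorts from reported statistics of three
human iPSC-derived lines (WT4, WT156, WT83) and of primary rat
hippocampal cultures; cohorts larger than one field of view are split
into several movies of at most ``neurons_per_fov`` neurons each.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import tifffile

from .movie import Movie

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_footprints",
    "simulate_spike_train",
    "render_ap_kernel",
    "ap_kernel_value",
    "render_dff",
    "render_movie",
    "simulate_cohort",
    "preset",
    "PRESET_NAMES",
]

_UINT16_MAX = np.iinfo(np.uint16).max


@dataclass
class SimConfig:
    """All knobs of the movie generator.

    ``firing_rate`` and ``ap_fwhm`` may be scalars (shared by every
    neuron) or ``(mean, sd)`` pairs, in which case per-neuron values are
    drawn from a lognormal with exactly those moments (FWHM draws are
    floored at 2 ms by resampling).
    """

    n_neurons: int = 4
    fov_shape: tuple[int, int] = (150, 200)  # (H, W) pixels
    frame_rate: float = 500.0  # Hz
    duration: float = 180.0  # s
    exposure_ms: float = 2.2
    firing_rate: float | tuple[float, float] = 1.0  # Hz
    firing_pattern: str = "poisson"  # poisson | bursting | synchronized-bursting
    ap_fwhm: float | tuple[float, float] = 12.0  # ms
    ap_amplitude: float = 10.0  # % ΔF/F₀ per AP
    ap_shape: str = "lognormal"  # lognormal | gaussian
    refractory_ms: float = 5.0
    burst_fraction: float = 0.75  # fraction of spikes emitted inside bursts
    spikes_per_burst: tuple[int, int] = (4, 8)
    intra_burst_isi_ms: tuple[float, float] = (30.0, 150.0)
    sync_participation: float = 0.8  # per-neuron burst participation probability
    plateau_rate: float = 0.5  # events/min
    plateau_amplitude: float = 2.5  # % ΔF/F₀ (~¼ of an AP, as for a ~25 mV plateau)
    plateau_duration: float = 1.0  # s
    plateau_edge_ms: float = 50.0  # rise/fall time constant of plateau edges
    baseline_counts: float = 1500.0
    background_counts: float = 100.0
    shot_noise: bool = True
    bleach_tau: float = math.inf  # s; inf disables photobleaching
    overlap_fraction: float = 0.0
    soma_radius_px: tuple[float, float] = (4.0, 7.5)  # → 8–15 px diameters
    neurons_per_fov: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (100.0 <= self.frame_rate <= 1000.0):
            raise ValueError("frame_rate must lie in [100, 1000] Hz")
        rate = self.firing_rate[0] if isinstance(self.firing_rate, tuple) else self.firing_rate
        if rate < 0:
            raise ValueError("firing_rate must be nonnegative")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        fwhm = self.ap_fwhm[0] if isinstance(self.ap_fwhm, tuple) else self.ap_fwhm
        if fwhm < 2000.0 / self.frame_rate:
            warnings.warn(
                f"ap_fwhm {fwhm:.2f} ms is below two frame periods at "
                f"{self.frame_rate:.0f} Hz; APs will be undersampled"
            )

    def scaled(self, scale: float) -> "SimConfig":
        """Scale the field of view down while preserving trace SNR.

        Soma radii scale with the FOV (floored at 2 px).  Baseline counts
        scale by 1/scale² so the photon budget *per neuron* — and hence
        the shot-noise level of extracted traces — matches the unscaled
        instrument: a desk-scale movie is a smaller camera, not a dimmer
        preparation.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        if scale > 1:
            raise ValueError("scale factor is meant to shrink the FOV (scale ≤ 1)")
        h, w = self.fov_shape
        radii = tuple(max(r * scale, 2.0) for r in self.soma_radius_px)
        return replace(
            self,
            fov_shape=(max(int(round(h * scale)), 8), max(int(round(w * scale)), 8)),
            soma_radius_px=radii,
            baseline_counts=self.baseline_counts / scale**2,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bleach_tau"] = None if math.isinf(self.bleach_tau) else self.bleach_tau
        return d


@dataclass
class GroundTruth:
    """The simulator's truth record: the oracle for recovery testing."""

    footprints: np.ndarray  # (N, H, W) float, peak 1
    masks: np.ndarray  # (N, H, W) bool
    centers: np.ndarray  # (N, 2) row/col
    radii: np.ndarray  # (N,)
    spike_times: list[np.ndarray] = field(default_factory=list)
    plateau_intervals: list[list[tuple[float, float]]] = field(default_factory=list)
    kernel_params: list[tuple[float, float]] = field(default_factory=list)  # (fwhm ms, amp %)
    firing_rates: np.ndarray | None = None
    dff_traces: list[np.ndarray] = field(default_factory=list)
    config: SimConfig | None = None

    @property
    def n_neurons(self) -> int:
        return self.footprints.shape[0]

    def validate(self) -> None:
        if np.any(self.footprints < 0):
            raise ValueError("footprints must be nonnegative")
        for i in range(self.n_neurons):
            if not self.masks[i].any():
                raise ValueError(f"neuron {i} has an empty mask")
        for st in self.spike_times:
            if st.size > 1 and not np.all(np.diff(st) > 0):
                raise ValueError("spike times must be strictly increasing")

    def save(self, out_dir: str | Path, stem: str = "ground_truth") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(
            out_dir / f"{stem}_footprints.tif",
            (self.footprints * 10000).astype(np.uint16),
            photometric="minisblack",
        )
        payload = {
            "spike_times": [st.tolist() for st in self.spike_times],
            "plateau_intervals": [
                [[float(a), float(b)] for a, b in iv] for iv in self.plateau_intervals
            ],
            "kernel_params": [[float(f), float(a)] for f, a in self.kernel_params],
            "firing_rates": None
            if self.firing_rates is None
            else self.firing_rates.tolist(),
            "centers": self.centers.tolist(),
            "radii": self.radii.tolist(),
            "config": None if self.config is None else self.config.to_dict(),
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Per-neuron random streams: fixed spawn keys off one master seed, so
# adding a neuron never perturbs the draws of existing ones.
# ---------------------------------------------------------------------------


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Footprints
# ---------------------------------------------------------------------------


def _soma_profile(fov_shape, center, radius):
    """Super-Gaussian soma profile: 1 at the centre, 0.5 at ``radius``."""
    h, w = fov_shape
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-math.log(2.0) * (d2 / radius**2) ** 2).astype(np.float32)


def make_footprints(
    n_neurons: int,
    fov_shape: tuple[int, int],
    overlap_fraction: float = 0.0,
    seed: int = 0,
    soma_radius_px: tuple[float, float] = (4.0, 7.5),
    max_tries: int = 2000,
) -> GroundTruth:
    """Place soma-like footprints in the field of view.

    Footprints are smooth compact super-Gaussian blobs; the binary mask is
    the 0.5-level set (a disc of the drawn radius).  A target fraction of
    neuron pairs is made to share at least one pixel by placing those
    neurons adjacent to an earlier one; the rest are kept disjoint.
    """
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    h, w = fov_shape
    rng = _rng(seed, 0)
    radii = rng.uniform(*soma_radius_px, size=n_neurons)
    margin = radii.max() + 1
    if h - 2 * margin < 1 or w - 2 * margin < 1:
        raise ValueError(
            f"FOV {fov_shape} too small for somas of radius ≤ {radii.max():.1f} px"
        )
    target_pairs = int(round(overlap_fraction * n_neurons * (n_neurons - 1) / 2))
    centers: list[np.ndarray] = []
    overlapping_pairs = 0
    for k in range(n_neurons):
        placed = False
        want_overlap = k > 0 and overlapping_pairs < target_pairs
        for _ in range(max_tries):
            if want_overlap:
                j = int(rng.integers(len(centers)))
                ang = rng.uniform(0, 2 * math.pi)
                dist = 0.8 * (radii[k] + radii[j]) / 2 + rng.uniform(0, radii[j] / 2)
                cand = centers[j] + dist * np.array([math.sin(ang), math.cos(ang)])
                if not (margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin):
                    continue
            else:
                cand = np.array(
                    [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
                )
                # disjoint placement: keep discs separated by > 1 px
                ok = all(
                    np.hypot(*(cand - c)) > radii[k] + radii[j] + 1.5
                    for j, c in enumerate(centers)
                )
                if not ok:
                    continue
            centers.append(cand)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place neuron {k} after {max_tries} tries: "
                f"{n_neurons} somas of radius ~{radii.mean():.1f} px are too dense "
                f"for a {h}×{w} px FOV"
            )
        if want_overlap:
            overlapping_pairs += 1
    centers_arr = np.array(centers)
    footprints = np.stack(
        [_soma_profile(fov_shape, c, r) for c, r in zip(centers_arr, radii)]
    )
    masks = footprints >= 0.5
    gt = GroundTruth(
        footprints=footprints, masks=masks, centers=centers_arr, radii=radii
    )
    gt.validate()
    return gt


def count_overlapping_pairs(masks: np.ndarray) -> int:
    n = masks.shape[0]
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if np.any(masks[i] & masks[j])
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _apply_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0 or refractory_s <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.array(kept)


def simulate_spike_train(
    firing_rate: float,
    pattern: str = "poisson",
    duration: float = 180.0,
    refractory_ms: float = 5.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    burst_onset_rate: float | None = None,
    burst_fraction: float = 0.75,
    spikes_per_burst: tuple[int, int] = (4, 8),
    intra_burst_isi_ms: tuple[float, float] = (30.0, 150.0),
    burst_onsets: np.ndarray | None = None,
    participation: float = 1.0,
) -> np.ndarray:
    """Generate strictly increasing spike times in ``[0, duration)``.

    ``poisson``: homogeneous Poisson thinned by an absolute refractory
    period (output rate ≈ λ/(1 + λτ_r)).  ``bursting``: Poisson burst
    onsets each emitting 4–8 spikes at short intra-burst ISIs, plus a
    residual train of isolated Poisson spikes; onset rate defaults to
    ``burst_fraction·rate/E[spikes per burst]`` so the overall rate
    matches ``firing_rate``.  ``synchronized-bursting``: as bursting, but
    onsets may be supplied (shared across a network) and each burst is
    joined with probability ``participation``.
    """
    if firing_rate < 0:
        raise ValueError("firing_rate must be nonnegative")
    if refractory_ms < 0:
        raise ValueError("refractory_ms must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    refr = refractory_ms / 1000.0
    if pattern == "poisson":
        times = _poisson_times(firing_rate, duration, rng)
    elif pattern in ("bursting", "synchronized-bursting"):
        lo, hi = spikes_per_burst
        mean_per_burst = (lo + hi) / 2.0
        if burst_onsets is None:
            if burst_onset_rate is None:
                burst_onset_rate = burst_fraction * firing_rate / mean_per_burst
            burst_onsets = _poisson_times(burst_onset_rate, duration, rng)
        iso_rate = max(firing_rate - participation * burst_onset_rate_of(
            burst_onsets, duration) * mean_per_burst, 0.0) if burst_onsets.size else firing_rate
        spikes = []
        for onset in burst_onsets:
            if participation < 1.0 and rng.uniform() > participation:
                continue
            n_spk = int(rng.integers(lo, hi + 1))
            isis = rng.uniform(*intra_burst_isi_ms, size=n_spk - 1) / 1000.0
            spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
        spikes.append(_poisson_times(iso_rate, duration, rng))
        times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        times = times[(times >= 0) & (times < duration)]
    else:
        raise ValueError(f"unknown firing pattern {pattern!r}")
    return _apply_refractory(times, refr)


def burst_onset_rate_of(onsets: np.ndarray, duration: float) -> float:
    return onsets.size / duration if duration > 0 else 0.0


# ---------------------------------------------------------------------------
# AP kernel
# ---------------------------------------------------------------------------

_RISE_FRACTION = 0.25  # rise (half-max → peak) as a fraction of FWHM


def _lognormal_shape_params(fwhm_ms: float, rise_fraction: float = _RISE_FRACTION):
    """Closed-form lognormal pulse parameters for a target FWHM and rise.

    For a pulse exp(−(ln(t/t_peak))²/(2s²)) the half-max times are
    t_peak·e^{∓a} with a = s√(2 ln 2); the rise fraction is x/(1+x) with
    x = e^{−a}, so x = ρ/(1−ρ), and t_peak = FWHM·x/(1−x²).
    """
    x = rise_fraction / (1.0 - rise_fraction)
    a = -math.log(x)
    s = a / math.sqrt(2.0 * math.log(2.0))
    t_peak = fwhm_ms * x / (1.0 - x * x)
    return t_peak, s


def ap_kernel_value(
    t_ms: np.ndarray,
    ap_fwhm_ms: float,
    ap_amplitude: float = 10.0,
    shape: str = "lognormal",
) -> np.ndarray:
    """Continuous-time AP pulse, peak ``ap_amplitude`` at ``t_ms = 0``.

    ``lognormal`` (default) is asymmetric with rise time 0.25·FWHM;
    ``gaussian`` is symmetric (closed-form FWHM = 2√(2 ln 2)·σ) and exists
    for analytic tests.
    """
    t = np.asarray(t_ms, dtype=float)
    if ap_fwhm_ms <= 0:
        raise ValueError("ap_fwhm_ms must be positive")
    if shape == "gaussian":
        sigma = ap_fwhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return ap_amplitude * np.exp(-(t**2) / (2.0 * sigma**2))
    if shape == "lognormal":
        t_peak, s = _lognormal_shape_params(ap_fwhm_ms)
        out = np.zeros_like(t)
        pos = t > -t_peak
        out[pos] = ap_amplitude * np.exp(
            -np.log((t[pos] + t_peak) / t_peak) ** 2 / (2.0 * s**2)
        )
        return out
    raise ValueError(f"unknown kernel shape {shape!r}")


def render_ap_kernel(
    ap_fwhm_ms: float,
    ap_amplitude: float = 10.0,
    frame_rate: float = 500.0,
    shape: str = "lognormal",
    tail_cut: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the AP kernel on the camera's frame grid.

    Returns ``(t_ms, samples)`` with the peak exactly on a grid point.
    The grid spans the support where the pulse exceeds ``tail_cut`` of
    its peak.  Warns if the FWHM is below one frame period.
    """
    if ap_fwhm_ms <= 0:
        raise ValueError("ap_fwhm_ms must be positive")
    dt_ms = 1000.0 / frame_rate
    if ap_fwhm_ms < dt_ms:
        warnings.warn(
            f"AP FWHM {ap_fwhm_ms:.2f} ms below one frame period ({dt_ms:.2f} ms)"
        )
    if shape == "gaussian":
        sigma = ap_fwhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        half_span = sigma * math.sqrt(-2.0 * math.log(tail_cut))
        pre = post = half_span
    else:
        t_peak, s = _lognormal_shape_params(ap_fwhm_ms)
        reach = s * math.sqrt(-2.0 * math.log(tail_cut))
        pre = t_peak * (1.0 - math.exp(-reach))
        post = t_peak * (math.exp(reach) - 1.0)
    n_pre = int(math.ceil(pre / dt_ms))
    n_post = int(math.ceil(post / dt_ms))
    t_ms = np.arange(-n_pre, n_post + 1) * dt_ms
    return t_ms, ap_kernel_value(t_ms, ap_fwhm_ms, ap_amplitude, shape)


# ---------------------------------------------------------------------------
# ΔF/F₀ assembly and movie rendering
# ---------------------------------------------------------------------------


def _plateau_waveform(t_s, intervals, amplitude, edge_ms):
    """Sum of soft-edged boxcars (erf edges with time constant edge_ms)."""
    from scipy.special import erf

    out = np.zeros_like(t_s)
    tau = edge_ms / 1000.0
    for a, b in intervals:
        out += 0.25 * amplitude * (1.0 + erf((t_s - a) / tau)) * (1.0 + erf((b - t_s) / tau))
    return out


def _draw_plateaus(rate_per_min, duration, mean_dur, rng):
    onsets = _poisson_times(rate_per_min / 60.0, duration, rng)
    intervals = []
    t_free = 0.0
    for onset in onsets:
        if onset < t_free:
            continue  # drop overlapping events
        dur = mean_dur * rng.uniform(0.7, 1.3)
        end = min(onset + dur, duration)
        intervals.append((float(onset), float(end)))
        t_free = end + 0.2
    return intervals


def _draw_lognormal(mean: float, sd: float, size: int, rng, floor: float = 0.0):
    """Lognormal draws with exactly the requested mean and SD (moment match)."""
    if sd <= 0:
        return np.full(size, mean)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    out = rng.lognormal(mu, math.sqrt(s2), size=size)
    while floor > 0 and np.any(out < floor):
        bad = out < floor
        out[bad] = rng.lognormal(mu, math.sqrt(s2), size=int(bad.sum()))
    return out


def _per_neuron_params(config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_neurons
    if isinstance(config.firing_rate, tuple):
        rates = _draw_lognormal(*config.firing_rate, n, rng)
    else:
        rates = np.full(n, float(config.firing_rate))
    if isinstance(config.ap_fwhm, tuple):
        fwhms = _draw_lognormal(*config.ap_fwhm, n, rng, floor=2.0)
    else:
        fwhms = np.full(n, float(config.ap_fwhm))
    return rates, fwhms


def render_dff(gt: GroundTruth, config: SimConfig) -> GroundTruth:
    """Fill ground truth with spike trains, plateaus and ΔF/F₀ traces.

    Spike times are continuous (not grid-aligned); each AP contributes the
    continuous kernel evaluated at the frame times, so the rendered trace
    is the exact sampled ΔF/F₀.
    """
    n = gt.n_neurons
    fs = config.frame_rate
    t_s = np.arange(int(round(config.duration * fs))) / fs
    param_rng = _rng(config.seed, 1)
    rates, fwhms = _per_neuron_params(config, param_rng)
    shared_onsets = None
    if config.firing_pattern == "synchronized-bursting":
        lo, hi = config.spikes_per_burst
        onset_rate = config.burst_fraction * float(np.mean(rates)) / ((lo + hi) / 2.0)
        shared_onsets = _poisson_times(onset_rate, config.duration, _rng(config.seed, 2))
    gt.spike_times, gt.plateau_intervals = [], []
    gt.kernel_params, gt.dff_traces = [], []
    gt.firing_rates = rates
    for i in range(n):
        rng_i = _rng(config.seed, 10, i)
        st = simulate_spike_train(
            float(rates[i]),
            config.firing_pattern,
            config.duration,
            config.refractory_ms,
            rng=rng_i,
            burst_fraction=config.burst_fraction,
            spikes_per_burst=config.spikes_per_burst,
            intra_burst_isi_ms=config.intra_burst_isi_ms,
            burst_onsets=shared_onsets,
            participation=config.sync_participation
            if config.firing_pattern == "synchronized-bursting"
            else 1.0,
        )
        plateaus = _draw_plateaus(
            config.plateau_rate, config.duration, config.plateau_duration, rng_i
        )
        dff = np.zeros_like(t_s)
        if st.size:
            # evaluate the kernel only on a local window around each spike
            t_peak_ms = fwhms[i] * 3.0  # generous support on either side
            half = int(math.ceil((t_peak_ms * 8) / 1000.0 * fs)) + 1
            for s0 in st:
                c = int(round(s0 * fs))
                lo_i, hi_i = max(c - half, 0), min(c + half + 1, t_s.size)
                dff[lo_i:hi_i] += ap_kernel_value(
                    (t_s[lo_i:hi_i] - s0) * 1000.0,
                    float(fwhms[i]),
                    config.ap_amplitude,
                    config.ap_shape,
                )
        if plateaus:
            dff += _plateau_waveform(
                t_s, plateaus, config.plateau_amplitude, config.plateau_edge_ms
            )
        gt.spike_times.append(st)
        gt.plateau_intervals.append(plateaus)
        gt.kernel_params.append((float(fwhms[i]), float(config.ap_amplitude)))
        gt.dff_traces.append(dff)
    gt.config = config
    gt.validate()
    return gt


def render_movie(
    gt: GroundTruth, config: SimConfig, chunk_frames: int = 10000
) -> Movie:
    """Render a 16-bit camera movie from ground truth.

    Per-pixel expected counts follow the rendering equation in the module
    docstring; Poisson shot noise (if enabled) is applied chunk-wise and
    the result clipped to the 16-bit range.  Deterministic given the
    config seed.
    """
    if not gt.dff_traces:
        render_dff(gt, config)
    n = gt.n_neurons
    h, w = gt.footprints.shape[1:]
    t = np.arange(int(round(config.duration * config.frame_rate))) / config.frame_rate
    T = t.size
    bleach = (
        np.ones(T) if math.isinf(config.bleach_tau) else np.exp(-t / config.bleach_tau)
    )
    W = gt.footprints.reshape(n, h * w).astype(np.float32)
    gain = np.empty((n, T), dtype=np.float32)  # (N, T)
    for i, d in enumerate(gt.dff_traces):
        gain[i] = 1.0 + np.asarray(d, dtype=np.float32) / 100.0
    peak_gain = gain.max(initial=1.0)
    max_weight = W.sum(axis=0).max()
    peak_counts = config.background_counts + config.baseline_counts * max_weight * peak_gain
    if peak_counts > _UINT16_MAX:
        raise ValueError(
            f"expected counts ({peak_counts:.0f}) overflow 16-bit; "
            "lower baseline_counts or ap_amplitude"
        )
    noise_rng = _rng(config.seed, 3)
    frames = np.empty((T, h, w), dtype=np.uint16)
    # Poisson tails cannot reach the 16-bit ceiling when the expected peak
    # sits ≥ 8σ below it, so clipping can usually be skipped
    needs_clip = peak_counts + 8.0 * math.sqrt(max(peak_counts, 1.0)) >= _UINT16_MAX
    for lo in range(0, T, chunk_frames):
        hi = min(lo + chunk_frames, T)
        expected = gain[:, lo:hi].T @ W  # (chunk, P)
        expected *= np.float32(config.baseline_counts)
        expected *= bleach[lo:hi, None].astype(np.float32)
        expected += np.float32(config.background_counts)
        if config.shot_noise:
            # Gaussian approximation to Poisson shot noise (skew 1/√λ is
            # negligible above ~30 counts); exact Poisson for dim pixels
            chunk = noise_rng.standard_normal(expected.shape, dtype=np.float32)
            chunk *= np.sqrt(expected)
            chunk += expected
            dim = expected < 30.0
            if dim.any():
                chunk[dim] = noise_rng.poisson(expected[dim].astype(np.float64))
            np.maximum(chunk, 0.0, out=chunk)
            np.rint(chunk, out=chunk)
        else:
            chunk = np.rint(expected)
        if needs_clip:
            chunk = np.clip(chunk, 0, _UINT16_MAX)
        frames[lo:hi] = chunk.astype(np.uint16).reshape(hi - lo, h, w)
    return Movie(
        frames=frames,
        frame_rate=config.frame_rate,
        exposure_ms=config.exposure_ms,
        origin="simulated",
    )


def simulate_fov(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Simulate one field of view: footprints, ΔF/F₀, and the movie."""
    gt = make_footprints(
        config.n_neurons,
        config.fov_shape,
        config.overlap_fraction,
        seed=config.seed,
        soma_radius_px=config.soma_radius_px,
    )
    render_dff(gt, config)
    movie = render_movie(gt, config)
    return movie, gt


def simulate_cohort(config: SimConfig) -> list[tuple[Movie, GroundTruth]]:
    """Simulate a cohort, splitting it into movies of ≤ ``neurons_per_fov``.

    Each FOV gets its own seed stream derived from the master seed.
    """
    out = []
    remaining = config.n_neurons
    fov_idx = 0
    while remaining > 0:
        n_here = min(remaining, config.neurons_per_fov)
        sub_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(100 + fov_idx,)).generate_state(1)[0]
            % (2**31)
        )
        sub = replace(config, n_neurons=n_here, seed=sub_seed)
        out.append(simulate_fov(sub))
        remaining -= n_here
        fov_idx += 1
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("WT4", "WT156", "WT83", "primary")


def preset(name: str, scale: float = 1.0, seed: int = 0) -> SimConfig:
    """Named cohort configurations parameterized from reported statistics.

    - ``WT4``: 24 neurons, firing rate 1.03 ± 0.50 Hz, AP FWHM 14.8 ms.
    - ``WT83``: 41 neurons, 0.23 ± 0.16 Hz, FWHM 12.2 ms.
    - ``WT156``: 36 neurons, bursting pattern, FWHM 12.3 ms (rate not
      reported for this line; 0.6 ± 0.3 Hz chosen between the other two).
    - ``primary``: 27 neurons, synchronized network bursting, per-neuron
      FWHM drawn with mean 10.1 ms and SD 7.14 ms (floored at 2 ms).

    All presets run 180 s at 500 Hz over a 200×150 px field of view;
    ``scale`` shrinks the FOV (and soma radii) for desk-scale runs.
    """
    base = SimConfig(
        fov_shape=(150, 200),
        frame_rate=500.0,
        duration=180.0,
        seed=seed,
    )
    if name == "WT4":
        cfg = replace(base, n_neurons=24, firing_rate=(1.03, 0.50), ap_fwhm=14.8)
    elif name == "WT83":
        cfg = replace(base, n_neurons=41, firing_rate=(0.23, 0.16), ap_fwhm=12.2)
    elif name == "WT156":
        cfg = replace(
            base,
            n_neurons=36,
            firing_rate=(0.6, 0.3),
            ap_fwhm=12.3,
            firing_pattern="bursting",
        )
    elif name == "primary":
        cfg = replace(
            base,
            n_neurons=27,
            firing_rate=(1.0, 0.5),
            ap_fwhm=(10.1, 7.14),
            firing_pattern="synchronized-bursting",
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if scale != 1.0:
        cfg = cfg.scaled(scale)
    return cfg
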