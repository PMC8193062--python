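"""Movie and trace containers, TIFF I/O, denoising, and ΔF/F₀ conversion.

A recording is a T×H×W stack of nonnegative camera counts acquired at a
known frame rate (hundreds of Hz for voltage imaging).  The quantity
analysed downstream is the percent fluorescence change relative to
baseline, ΔF/F₀ = 100·(F − F₀)/F₀, which for a voltage dye that brightens
on depolarization makes action potentials fast positive transients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage, optimize

__all__ = [
    "Movie",
    "Trace",
    "read_movie",
    "write_movie",
    "spatiotemporal_filter",
    "smooth_trace",
    "compute_dff",
    "detrend_bleach",
    "save_traces_csv",
    "load_traces_csv",
    "save_traces_hdf5",
    "load_traces_hdf5",
]


@dataclass
class Movie:
    """A grayscale frame stack with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Nonnegative camera counts (integer or float after filtering).
    frame_rate : float
        Acquisition rate in Hz.
    exposure_ms : float
        Camera exposure per frame, milliseconds.
    origin : {"recorded", "simulated"}
    """

    frames: np.ndarray
    frame_rate: float
    exposure_ms: float = 2.2
    origin: str = "recorded"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 3:
            raise ValueError("movie must have at least 3 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < 0:
            raise ValueError("frames contain negative counts")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fov_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame centres at k/frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class Trace:
    """One neuron's ΔF/F₀ time series in percent units."""

    values: np.ndarray
    frame_rate: float
    neuron_id: int = 0
    baseline_f0: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate

    def smoothed(self, window_frames: int) -> "Trace":
        return replace(self, values=smooth_trace(self.values, window_frames))


# ---------------------------------------------------------------------------
# TIFF I/O (metadata lives in a JSON sidecar next to the stack)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as a multi-page grayscale TIFF plus a JSON sidecar."""
    path = Path(path)
    frames = movie.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "frame_rate": movie.frame_rate,
        "exposure_ms": movie.exposure_ms,
        "origin": movie.origin,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path, frame_rate: float | None = None) -> Movie:
    """Read a multi-page grayscale TIFF stack.

    Acquisition metadata is taken from the JSON sidecar written by
    :func:`write_movie`; if absent, ``frame_rate`` must be given.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale T×H×W stack, got shape {frames.shape}"
        )
    if frames.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError(f"{path}: expected 8/16-bit grayscale, got dtype {frames.dtype}")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fr = meta.get("frame_rate", frame_rate)
    if fr is None:
        raise ValueError(f"{path}: no metadata sidecar; pass frame_rate explicitly")
    return Movie(
        frames=frames,
        frame_rate=fr,
        exposure_ms=meta.get("exposure_ms", 2.2),
        origin=meta.get("origin", "recorded"),
    )


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------


def spatiotemporal_filter(
    movie: Movie, spatial_sigma_px: float = 1.0, temporal_window_frames: int = 3
) -> Movie:
    """Smooth a movie in space (Gaussian) and time (centred moving average).

    Frame count, frame rate and FOV are preserved.  ``spatial_sigma_px=0``
    with ``temporal_window_frames=1`` is the identity.  Temporal edges use
    reflection padding.
    """
    if temporal_window_frames < 1 or temporal_window_frames % 2 == 0:
        raise ValueError("temporal window must be odd and ≥ 1")
    if temporal_window_frames > movie.n_frames:
        raise ValueError("temporal window longer than movie")
    if spatial_sigma_px < 0:
        raise ValueError("spatial sigma must be nonnegative")
    out = np.asarray(movie.frames, dtype=np.float32)
    if spatial_sigma_px > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(0, spatial_sigma_px, spatial_sigma_px), mode="nearest"
        )
    elif out is movie.frames:
        out = out.copy()
    if temporal_window_frames > 1:
        out = ndimage.uniform_filter1d(
            out, size=temporal_window_frames, axis=0, mode="reflect"
        )
    return replace(movie, frames=out)


def smooth_trace(values: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average of a 1-D trace with reflection padding."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window must be odd and ≥ 1")
    values = np.asarray(values, dtype=float)
    if window_frames > values.size:
        raise ValueError("window longer than trace")
    if window_frames == 1:
        return values.copy()
    return ndimage.uniform_filter1d(values, size=window_frames, mode="reflect")


# ---------------------------------------------------------------------------
# ΔF/F₀
# ---------------------------------------------------------------------------


def _sliding_percentile_baseline(
    raw: np.ndarray, frame_rate: float, percentile: float, window_s: float
) -> np.ndarray:
    """Sliding-window percentile baseline, evaluated on a coarse grid.

    The percentile is computed in full windows centred on a ~1 s grid
    (clamped to lie inside the trace) and linearly interpolated between
    grid points; this keeps the estimator O(T) while tracking drift far
    slower than any AP.
    """
    n = raw.size
    win = int(round(window_s * frame_rate))
    win = min(max(win, 3), n)
    stride = max(int(round(frame_rate)), 1)  # ~1 s between anchor points
    centers = np.arange(0, n, stride)
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    anchors = np.empty(centers.size)
    half = win // 2
    for i, c in enumerate(centers):
        lo = min(max(c - half, 0), n - win)
        anchors[i] = np.percentile(raw[lo : lo + win], percentile)
    return np.interp(np.arange(n), centers, anchors)


def compute_dff(
    raw_trace: np.ndarray,
    frame_rate: float,
    baseline_method: str = "sliding_percentile",
    percentile: float = 20.0,
    window_s: float = 10.0,
    neuron_id: int = 0,
) -> Trace:
    """Convert a raw fluorescence trace to percent ΔF/F₀.

    Baseline F₀ options:

    - ``sliding_percentile`` (default): 20th percentile in a sliding 10 s
      window, so sparse positive spikes do not inflate the baseline;
    - ``global_percentile``: one percentile over the whole trace;
    - ``global_mean``: mean of the trace (for short synthetic segments).
    """
    raw = np.asarray(raw_trace, dtype=float)
    if raw.ndim != 1 or raw.size < 3:
        raise ValueError("raw trace must be 1-D with ≥ 3 samples")
    if not np.any(raw > 0):
        raise ValueError("raw trace has no positive fluorescence")
    if baseline_method == "sliding_percentile":
        f0 = _sliding_percentile_baseline(raw, frame_rate, percentile, window_s)
    elif baseline_method == "global_percentile":
        f0 = np.full(raw.size, np.percentile(raw, percentile))
    elif baseline_method == "global_mean":
        f0 = np.full(raw.size, raw.mean())
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 is non-positive; cannot form ΔF/F₀")
    values = 100.0 * (raw - f0) / f0
    return Trace(values=values, frame_rate=frame_rate, neuron_id=neuron_id, baseline_f0=f0)


def detrend_bleach(raw_trace: np.ndarray, frame_rate: float) -> np.ndarray:
    """Divide out a fitted monoexponential-plus-offset photobleaching trend.

    Disabled by default in the pipeline: under the imaging regime emulated
    here photobleaching is negligible, so this is a robustness option for
    recordings that do show a slow decay.  If the fit does not converge the
    trace is passed through with a warning.
    """
    raw = np.asarray(raw_trace, dtype=float)
    if raw.size < 100:
        raise ValueError("need ≥ 100 samples to fit a bleaching trend")
    if np.all(raw == 0):
        raise ValueError("all-zero trace is degenerate")
    t = np.arange(raw.size) / frame_rate

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    span = raw.max() - raw.min()
    p0 = (max(span, 1e-9), max(t[-1], 1.0), raw.min())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model, t, raw, p0=p0, maxfev=5000,
                bounds=([0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            )
    except (RuntimeError, ValueError):
        warnings.warn("bleach fit did not converge; returning trace unchanged")
        return raw.copy()
    trend = model(t, *popt)
    if np.any(trend <= 0):
        warnings.warn("bleach trend non-positive; returning trace unchanged")
        return raw.copy()
    return raw * (trend[0] / trend)


# ---------------------------------------------------------------------------
# Trace set persistence (CSV for interchange, HDF5 for bundles)
# ---------------------------------------------------------------------------


def save_traces_csv(traces: list[Trace], path: str | Path) -> Path:
    import pandas as pd

    rows = [
        {"time_s": t, "neuron_id": tr.neuron_id, "dff_percent": v}
        for tr in traces
        for t, v in zip(tr.times, tr.values)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["time_s", "neuron_id", "dff_percent"]).to_csv(
        path, index=False
    )
    return path


def load_traces_csv(path: str | Path, frame_rate: float) -> list[Trace]:
    import pandas as pd

    df = pd.read_csv(path)
    traces = []
    for nid, grp in df.groupby("neuron_id"):
        grp = grp.sort_values("time_s")
        traces.append(
            Trace(values=grp["dff_percent"].to_numpy(), frame_rate=frame_rate,
                  neuron_id=int(nid))
        )
    return traces


def save_traces_hdf5(traces: list[Trace], path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        for tr in traces:
            g = f.create_group(f"neuron_{tr.neuron_id:04d}")
            g.create_dataset("dff_percent", data=tr.values)
            g.attrs["frame_rate"] = tr.frame_rate
            g.attrs["neuron_id"] = tr.neuron_id
    return path


def load_traces_hdf5(path: str | Path) -> list[Trace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            traces.append(
                Trace(
                    values=g["dff_percent"][()],
                    frame_rate=float(g.attrs["frame_rate"]),
                    neuron_id=int(g.attrs["neuron_id"]),
                )
            )
    return traces
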