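"""Single-neuron ROI extraction by PCA followed by spatio-temporal ICA.

The movie (after denoising) is treated as a T×P matrix of pixel time
courses.  PCA retains a small signal subspace; ICA then rotates it so that
each component isolates one neuron, exploiting the fact that spiking
fluorescence traces are sparse and right-skewed while noise is symmetric.
The ICA operates on a concatenation of the spatial and temporal PCA
factors weighted by ``mu`` (mu=1 → purely temporal independence, mu=0 →
purely spatial).  Spatial filters are thresholded into binary masks and
weighted-mean traces extracted per neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from skimage import measure
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .movie import Movie, Trace, compute_dff

__all__ = [
    "PCAFactors",
    "ROISet",
    "pca_reduce",
    "ica_unmix",
    "filters_to_masks",
    "dedupe_rois",
    "extract_traces",
    "segment_movie",
    "save_roiset",
    "load_roiset",
]


@dataclass
class PCAFactors:
    """Truncated PCA of a movie: spatial components, temporal scores."""

    spatial: np.ndarray  # (k, H, W)
    temporal: np.ndarray  # (T, k), mean-free scores
    variance_ratio: np.ndarray  # (k,)
    mean_image: np.ndarray  # (H, W) per-pixel temporal mean

    @property
    def n_components(self) -> int:
        return self.spatial.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Inverse transform back to a T×H×W array."""
        k, h, w = self.spatial.shape
        flat = self.temporal @ self.spatial.reshape(k, h * w)
        return flat.reshape(-1, h, w) + self.mean_image


@dataclass
class ROISet:
    """Candidate single-neuron ROIs with quality scores.

    ``quality`` is the temporal skewness of each independent component:
    spiking traces are strongly right-skewed, noise components are not.
    """

    spatial_filters: np.ndarray  # (n, H, W)
    masks: np.ndarray  # (n, H, W) bool
    quality: np.ndarray  # (n,) temporal skewness
    spatial_skew: np.ndarray  # (n,)
    temporal_ics: np.ndarray | None = None  # (T, n)
    converged: bool = True

    @property
    def n_rois(self) -> int:
        return self.spatial_filters.shape[0]

    def subset(self, idx) -> "ROISet":
        idx = np.asarray(idx, dtype=int)
        return ROISet(
            spatial_filters=self.spatial_filters[idx],
            masks=self.masks[idx],
            quality=self.quality[idx],
            spatial_skew=self.spatial_skew[idx],
            temporal_ics=None if self.temporal_ics is None else self.temporal_ics[:, idx],
            converged=self.converged,
        )


def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a flattened binary mask as [start, length] pairs."""
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flat.view(np.int8), [0]])))
    return [[int(a), int(b - a)] for a, b in zip(edges[::2], edges[1::2])]


def _rle_decode(runs, shape) -> np.ndarray:
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        mask[start : start + length] = True
    return mask.reshape(shape)


def save_roiset(roiset: ROISet, out_dir, stem: str = "rois"):
    """Persist a ROISet: spatial filters as TIFF, the rest as JSON."""
    import json
    from pathlib import Path

    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out_dir / f"{stem}_filters.tif",
        roiset.spatial_filters.astype(np.float32),
        photometric="minisblack",
    )
    h, w = roiset.masks.shape[1:] if roiset.n_rois else (0, 0)
    payload = {
        "shape": [int(h), int(w)],
        "masks_rle": [_rle_encode(m) for m in roiset.masks],
        "quality": roiset.quality.tolist(),
        "spatial_skew": roiset.spatial_skew.tolist(),
        "converged": roiset.converged,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(payload))
    return out_dir


def load_roiset(out_dir, stem: str = "rois") -> ROISet:
    import json
    from pathlib import Path

    import tifffile

    out_dir = Path(out_dir)
    filters = tifffile.imread(out_dir / f"{stem}_filters.tif")
    if filters.ndim == 2:
        filters = filters[None]
    payload = json.loads((out_dir / f"{stem}.json").read_text())
    shape = tuple(payload["shape"])
    masks = (
        np.stack([_rle_decode(r, shape) for r in payload["masks_rle"]])
        if payload["masks_rle"]
        else np.zeros((0, *shape), dtype=bool)
    )
    return ROISet(
        spatial_filters=filters,
        masks=masks,
        quality=np.asarray(payload["quality"]),
        spatial_skew=np.asarray(payload["spatial_skew"]),
        converged=payload["converged"],
    )


def pca_reduce(movie: Movie, n_components: int, seed: int = 0) -> PCAFactors:
    """Reduce a movie to its leading principal components.

    Pixels are mean-subtracted internally; components are ordered by
    decreasing variance explained.  Uses a randomized solver for large
    movies and the exact solver when all components are requested.
    """
    T = movie.n_frames
    h, w = movie.fov_shape
    max_rank = min(T, h * w)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds min(T, H·W) = {max_rank}")
    X = np.asarray(movie.frames, dtype=np.float32).reshape(T, h * w)
    solver = "full" if n_components >= max_rank or max_rank <= 200 else "randomized"
    pca = PCA(
        n_components=n_components,
        svd_solver=solver,
        random_state=seed,
        iterated_power=4,
    )
    temporal = pca.fit_transform(X)
    return PCAFactors(
        spatial=pca.components_.reshape(n_components, h, w),
        temporal=temporal,
        variance_ratio=pca.explained_variance_ratio_,
        mean_image=pca.mean_.reshape(h, w),
    )


def ica_unmix(
    factors: PCAFactors,
    n_ics: int,
    mu: float = 0.5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    mask_threshold: float = 0.5,
) -> ROISet:
    """Rotate PCA factors into independent components (one per neuron).

    The ICA input stacks the variance-normalized temporal scores (weight
    ``mu``) on the unit-norm spatial components (weight ``1 − mu``), so
    statistical independence is judged jointly in space and time.  Each IC
    is sign-flipped so its temporal skewness is ≥ 0 (spikes are positive
    deflections) and ICs are sorted by spatial-filter skewness.  If the
    fixed-point iteration does not converge the best iterate is returned
    with ``converged=False``.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    k = factors.n_components
    if n_ics > k:
        raise ValueError("n_ics cannot exceed the number of principal components")
    h, w = factors.spatial.shape[1:]
    # rotate only among the top-variance PCs: the concatenated factors are
    # isotropic, so reduction must happen here, not inside FastICA
    V = factors.temporal[:, :n_ics]
    V = V / (V.std(axis=0, keepdims=True) + 1e-12)
    U = factors.spatial[:n_ics].reshape(n_ics, h * w).T
    U = U / (np.linalg.norm(U, axis=0, keepdims=True) + 1e-12)
    Z = np.vstack([mu * V, (1.0 - mu) * U * np.sqrt(V.shape[0])])
    ica = FastICA(
        n_components=n_ics,
        whiten="unit-variance",
        fun="cube",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(Z)
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
            warnings.warn("ICA did not converge; returning best iterate")
    T = V.shape[0]
    temporal_ics = sources[:T]
    spatial_ics = sources[T:]
    t_skew = sstats.skew(temporal_ics, axis=0)
    flip = np.where(t_skew < 0, -1.0, 1.0)
    temporal_ics = temporal_ics * flip
    spatial_ics = spatial_ics * flip
    t_skew = np.abs(t_skew)  # skewness after the sign flip
    s_skew = sstats.skew(spatial_ics, axis=0)
    order = np.argsort(s_skew)[::-1]
    filters = spatial_ics.T.reshape(n_ics, h, w)[order]
    roiset = ROISet(
        spatial_filters=filters,
        masks=np.zeros((n_ics, h, w), dtype=bool),
        quality=t_skew[order],
        spatial_skew=s_skew[order],
        temporal_ics=temporal_ics[:, order],
        converged=converged,
    )
    return filters_to_masks(roiset, mask_threshold)


def filters_to_masks(roiset: ROISet, threshold_fraction: float = 0.5) -> ROISet:
    """Binarize spatial filters at a fraction of their maximum.

    The mask is the largest connected component of
    ``filter ≥ threshold_fraction·max(filter)``; ROIs whose mask comes out
    empty are dropped with a warning.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    keep = []
    masks = np.zeros_like(roiset.masks)
    for i, filt in enumerate(roiset.spatial_filters):
        peak = filt.max()
        if peak <= 0:
            warnings.warn(f"ROI {i}: non-positive filter; dropped")
            continue
        binary = filt >= threshold_fraction * peak
        labels = measure.label(binary, connectivity=2)
        if labels.max() == 0:
            warnings.warn(f"ROI {i}: empty mask; dropped")
            continue
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        masks[i] = labels == largest
        keep.append(i)
    out = roiset.subset(keep)
    out.masks = masks[keep]
    return out


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def dedupe_rois(
    roiset: ROISet, min_quality: float = 0.2, max_jaccard: float = 0.5
) -> ROISet:
    """Drop low-quality and duplicate ROIs.

    ROIs with temporal skewness below ``min_quality`` are discarded (noise
    components); among ROIs whose masks overlap with Jaccard above
    ``max_jaccard`` only the higher-quality one is kept.
    """
    idx = [i for i in range(roiset.n_rois) if roiset.quality[i] >= min_quality]
    idx.sort(key=lambda i: -roiset.quality[i])
    kept: list[int] = []
    for i in idx:
        if all(_jaccard(roiset.masks[i], roiset.masks[j]) <= max_jaccard for j in kept):
            kept.append(i)
    kept.sort()
    return roiset.subset(kept)


def extract_traces(
    movie: Movie,
    roiset: ROISet,
    weighted: bool = True,
    baseline_method: str = "sliding_percentile",
    **dff_kwargs,
) -> list[Trace]:
    """Extract per-neuron ΔF/F₀ traces.

    The raw trace is the spatial-filter-weighted mean of the movie over
    the mask pixels (uniform mean if ``weighted=False``), converted to
    percent ΔF/F₀ with :func:`~voltpipe.movie.compute_dff`.
    """
    h, w = movie.fov_shape
    flat = np.asarray(movie.frames).reshape(movie.n_frames, h * w)
    traces = []
    for i in range(roiset.n_rois):
        mask = roiset.masks[i].ravel()
        if not mask.any():
            raise ValueError(f"ROI {i} has an empty mask")
        if roiset.masks[i].shape != (h, w):
            raise ValueError(f"ROI {i} mask shape does not match the FOV")
        if weighted:
            wts = np.clip(roiset.spatial_filters[i].ravel()[mask], 0, None)
            if wts.sum() <= 0:
                wts = np.ones(mask.sum())
        else:
            wts = np.ones(mask.sum())
        wts = wts / wts.sum()
        raw = flat[:, mask] @ wts
        traces.append(
            compute_dff(
                raw, movie.frame_rate, baseline_method=baseline_method,
                neuron_id=i, **dff_kwargs,
            )
        )
    return traces


def segment_movie(
    movie: Movie,
    expected_neurons: int,
    components_per_neuron: int = 3,
    max_components: int = 60,
    mu: float = 0.5,
    seed: int = 0,
    min_quality: float = 0.2,
    mask_threshold: float = 0.5,
) -> ROISet:
    """PCA → signal-subspace selection → ICA → masks → quality filtering.

    The PCA retains ``components_per_neuron × expected_neurons``
    components; the ICA then rotates only the *signal* subspace, taken as
    the components whose explained variance exceeds twice the noise floor
    (the median eigenvalue of the retained spectrum).  Rotating noise
    components along with signal splits neurons across multiple ICs, so
    this selection is what makes the ROI count track the neuron count.
    """
    k = min(
        max(components_per_neuron * expected_neurons, expected_neurons + 2),
        max_components,
        min(movie.n_frames, movie.fov_shape[0] * movie.fov_shape[1]),
    )
    factors = pca_reduce(movie, k, seed=seed)
    noise_floor = np.median(factors.variance_ratio)
    n_sig = int(np.sum(factors.variance_ratio > 2.0 * noise_floor))
    n_sig = int(np.clip(n_sig, 1, k))
    roiset = ica_unmix(
        factors, n_ics=n_sig, mu=mu, seed=seed, mask_threshold=mask_threshold
    )
    return dedupe_rois(roiset, min_quality=min_quality)
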