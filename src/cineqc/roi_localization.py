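"""Ventricle localisation from temporal dynamics and fixed-size ROI cropping.

Each slice sequence covers one heartbeat, so the magnitude of the
first-harmonic temporal Fourier coefficient per pixel ("activity image")
highlights the beating ventricle.  Circular Hough candidates on the activity
image are combined by score-weighted Gaussian kernel voting into a likelihood
surface whose argmax is the ROI centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel
from skimage.transform import hough_circle

from .phantom import CineSequence

__all__ = [
    "ActivityImage", "CircleCandidate", "RoiResult",
    "temporal_activity", "hough_candidates", "vote_centre", "crop_roi",
    "normalise_intensity", "localise",
]


class LocalizationError(RuntimeError):
    pass


@dataclass
class ActivityImage:
    values: np.ndarray                  # non-negative, same H x W as the source
    beat_frequency_index: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activity image must be 2D")
        if np.any(self.values < 0):
            raise ValueError("activity values must be >= 0")


@dataclass(order=True)
class CircleCandidate:
    centre: tuple[int, int] = field(compare=False)
    radius: int = field(compare=False)
    score: float = field(compare=False)


@dataclass
class RoiResult:
    centre: tuple[int, int]
    likelihood_surface: np.ndarray
    crop_size: int = 80


def temporal_activity(seq: CineSequence, beat_bin: int = 1) -> ActivityImage:
    """Per-pixel magnitude of the temporal Fourier coefficient at ``beat_bin``.

    ``beat_bin=1`` (the first harmonic, DC excluded) is the heartbeat
    frequency for single-beat sequences.  A temporally constant sequence has
    no dynamics: a warning is emitted and an all-zero activity returned.
    """
    if seq.n_frames < 2:
        raise ValueError("temporal activity needs at least 2 frames")
    if not (1 <= beat_bin < seq.n_frames):
        raise ValueError(f"beat_bin must lie in [1, n_frames); got {beat_bin}")
    spectrum = np.fft.fft(seq.frames, axis=2)
    act = np.abs(spectrum[:, :, beat_bin])
    if np.allclose(seq.frames.std(axis=2), 0.0):
        warnings.warn("sequence is constant in time; activity image is all zero")
        act = np.zeros_like(act)
    return ActivityImage(values=act, beat_frequency_index=beat_bin)


def _edge_map(activity: np.ndarray, method: str, percentile: float,
              canny_sigma: float) -> np.ndarray:
    # Canny's non-maximum suppression gives one-pixel edges; thick edge bands
    # from plain thresholding let small spurious circles saturate the
    # normalised Hough accumulator and bias the kernel vote.
    if method == "canny":
        return canny(activity / activity.max(), sigma=canny_sigma)
    if method == "percentile":
        grad = sobel(activity)
        return grad > np.percentile(grad, percentile)
    raise ValueError(f"unknown edge method {method!r}")


def hough_candidates(activity: ActivityImage, radii: np.ndarray | range,
                     n_candidates: int = 10,
                     edge_method: str = "canny",
                     edge_percentile: float = 90.0,
                     canny_sigma: float = 1.0) -> list[CircleCandidate]:
    """Best Hough circle per radius, top ``n_candidates`` overall.

    The edge map comes from Canny by default (``edge_method="percentile"``
    selects plain gradient-magnitude thresholding at ``edge_percentile``).
    Ties in accumulator score are broken by smaller radius, then row-major
    centre order, so results are deterministic.
    """
    vals = activity.values
    if not np.any(vals > 0):
        raise LocalizationError("activity image is all zero; cannot localise")
    radii = np.asarray(list(radii), dtype=int)
    edges = _edge_map(vals, edge_method, edge_percentile, canny_sigma)
    accum = hough_circle(edges, radii)        # (n_radii, H, W)

    cands: list[CircleCandidate] = []
    for ri, radius in enumerate(radii):
        flat = int(np.argmax(accum[ri]))
        r, c = np.unravel_index(flat, accum[ri].shape)
        cands.append(CircleCandidate(centre=(int(r), int(c)), radius=int(radius),
                                     score=float(accum[ri, r, c])))
    cands.sort(key=lambda cc: (-cc.score, cc.radius, cc.centre[0], cc.centre[1]))
    return cands[:n_candidates]


def vote_centre(candidate_sets, kernel_sigma: float = 5.0,
                image_shape: tuple[int, int] | None = None,
                crop_size: int = 80) -> RoiResult:
    """Score-weighted Gaussian kernel voting over circle centres.

    ``candidate_sets`` is one list of candidates or a list of per-slice
    lists.  Each centre contributes an isotropic Gaussian scaled by its
    Hough score; the likelihood-surface argmax is the ROI centre.
    """
    if candidate_sets and isinstance(candidate_sets[0], CircleCandidate):
        candidate_sets = [candidate_sets]
    all_cands = [c for s in candidate_sets for c in s]
    if not all_cands:
        raise LocalizationError("no circle candidates to vote on")

    if image_shape is None:
        h = max(c.centre[0] for c in all_cands) + 1
        w = max(c.centre[1] for c in all_cands) + 1
        image_shape = (h, w)
    rows = np.arange(image_shape[0])[:, None]
    cols = np.arange(image_shape[1])[None, :]
    surface = np.zeros(image_shape)
    for c in all_cands:
        d2 = (rows - c.centre[0]) ** 2 + (cols - c.centre[1]) ** 2
        surface += c.score * np.exp(-d2 / (2.0 * kernel_sigma ** 2))
    r, c = np.unravel_index(int(np.argmax(surface)), surface.shape)
    return RoiResult(centre=(int(r), int(c)), likelihood_surface=surface,
                     crop_size=crop_size)


def crop_roi(seq: CineSequence, roi: RoiResult) -> CineSequence:
    """Fixed-size crop centred on the ROI, clamped inside the image.

    Windows are half-open ``[r0, r0+crop)`` in 0-based indices.
    """
    size = roi.crop_size
    h, w, _ = seq.shape
    if size > h or size > w:
        raise ValueError(f"crop_size {size} exceeds image dimensions {(h, w)}")
    r0 = int(np.clip(roi.centre[0] - size // 2, 0, h - size))
    c0 = int(np.clip(roi.centre[1] - size // 2, 0, w - size))
    out = seq.frames[r0:r0 + size, c0:c0 + size, :]
    return seq.with_frames(out, extra_provenance=f"crop(origin=({r0},{c0}), size={size})")


def normalise_intensity(seq: CineSequence) -> CineSequence:
    """Rescale to zero mean, unit standard deviation over the whole sequence."""
    mu = seq.frames.mean()
    sd = seq.frames.std()
    if sd == 0:
        raise ValueError("cannot normalise a constant-intensity sequence")
    return seq.with_frames((seq.frames - mu) / sd, extra_provenance="normalise(z-score)")


def localise(seq: CineSequence, radii: np.ndarray | range = range(5, 41),
             kernel_sigma: float = 5.0, crop_size: int = 80,
             edge_method: str = "canny", edge_percentile: float = 90.0,
             canny_sigma: float = 1.0) -> RoiResult:
    """Full single-slice localisation: activity -> Hough -> kernel voting."""
    act = temporal_activity(seq)
    cands = hough_candidates(act, radii, edge_method=edge_method,
                             edge_percentile=edge_percentile,
                             canny_sigma=canny_sigma)
    return vote_centre(cands, kernel_sigma=kernel_sigma,
                       image_shape=act.values.shape, crop_size=crop_size)


def extract_roi(seq: CineSequence, crop_size: int = 80, **kwargs) -> CineSequence:
    """Localise, crop and z-score normalise in one step."""
    roi = localise(seq, crop_size=crop_size, **kwargs)
    return normalise_intensity(crop_roi(seq, roi))
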