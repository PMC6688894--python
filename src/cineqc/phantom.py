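"""Synthetic beating-ventricle cine phantoms.

A phantom is a 2D+time magnitude sequence containing a bright annulus (the
"myocardium") around a mid-grey disk (the "blood pool") on a dark background,
mimicking short-axis bSSFP contrast.  The annulus contracts and dilates
sinusoidally, so the ground-truth centre, radius trajectory and beat frequency
are known exactly — every downstream stage (k-space corruption, ROI
localisation, classification) can be validated against this geometry without
access to real acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomConfig", "CineSequence", "generate_phantom", "generate_labelled_set"]

#: Allowed quality labels (binary mode uses good/artefact; 3-class mode the rest).
LABELS = ("good", "artefact", "mistriggering", "breathing")


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass
class CineSequence:
    """One 2D+time magnitude slice sequence.

    ``frames`` is ``(height, width, n_frames)``; intensities are finite and,
    for raw (un-normalised) sequences, non-negative.  ``provenance`` is a
    free-text record of every operation applied so far.
    """

    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.8, 1.8)
    label: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (height, width, n_frames); got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None; got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    def with_frames(self, frames: np.ndarray, *, label: str | None = None,
                    extra_provenance: str | None = None) -> "CineSequence":
        """Copy of this sequence with new pixel data and updated bookkeeping."""
        prov = list(self.provenance)
        if extra_provenance:
            prov.append(extra_provenance)
        return CineSequence(
            frames=frames,
            pixel_spacing_mm=self.pixel_spacing_mm,
            label=self.label if label is None else label,
            provenance=prov,
        )


@dataclass
class PhantomConfig:
    """Geometry and noise parameters of a synthetic cine phantom.

    ``ventricle_radius_range`` is the (min, max) inner (blood-pool) radius of
    the beating annulus in pixels; the bright ring extends
    ``myocardium_thickness`` pixels beyond it.  ``beat_cycles`` full
    contraction/dilation cycles span the sequence, so with the default of 1
    the temporal first harmonic is the beat frequency.
    """

    image_size: int = 128
    n_frames: int = 50
    centre: tuple[float, float] | None = None
    ventricle_radius_range: tuple[float, float] = (12.0, 20.0)
    myocardium_thickness: float = 6.0
    beat_cycles: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    pixel_spacing_mm: tuple[float, float] = (1.8, 1.8)
    # bSSFP-like contrast levels; exact values immaterial, only their ordering.
    background_intensity: float = 0.1
    blood_pool_intensity: float = 0.5
    myocardium_intensity: float = 0.9

    def __post_init__(self) -> None:
        if self.centre is None:
            self.centre = (self.image_size / 2.0, self.image_size / 2.0)
        rmin, rmax = self.ventricle_radius_range
        if not (0 < rmin < rmax < self.image_size / 2):
            raise ConfigurationError(
                "ventricle_radius_range must satisfy 0 < min < max < image_size/2; "
                f"got {self.ventricle_radius_range} with image_size={self.image_size}"
            )
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2; got {self.n_frames}")
        margin = rmax + self.myocardium_thickness
        r, c = self.centre
        if not (margin <= r <= self.image_size - margin
                and margin <= c <= self.image_size - margin):
            raise ConfigurationError(
                f"centre {self.centre} must lie at least radius_max + thickness "
                f"(= {margin}) from every border of a {self.image_size}px image"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0; got {self.noise_sigma}")
        if self.beat_cycles < 1:
            raise ConfigurationError(f"beat_cycles must be >= 1; got {self.beat_cycles}")

    def valid_centre_bounds(self) -> tuple[float, float]:
        """(low, high) bound for each centre coordinate given the geometry."""
        margin = self.ventricle_radius_range[1] + self.myocardium_thickness
        return margin, self.image_size - margin


def _annulus_frame(dist: np.ndarray, r_inner: float, thickness: float,
                   bg: float, pool: float, myo: float) -> np.ndarray:
    # 1px linear ramps at both boundaries: antialiased edges keep the Hough
    # transform and temporal Fourier analysis free of gridding artefacts.
    ramp_in = np.clip(r_inner - dist + 0.5, 0.0, 1.0)
    ramp_out = np.clip(r_inner + thickness - dist + 0.5, 0.0, 1.0)
    return bg + (myo - bg) * ramp_out - (myo - pool) * ramp_in


def generate_phantom(config: PhantomConfig) -> CineSequence:
    """Generate one beating-annulus cine sequence.

    The inner radius follows ``r(t) = rmin + (rmax-rmin) * (1 - cos(2*pi*
    beat_cycles * t/(n_frames-1)))/2`` so that a whole number of cycles closes
    periodically: with no noise, the first and last frames are identical.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    dist = np.hypot(rows - config.centre[0], cols - config.centre[1])

    rmin, rmax = config.ventricle_radius_range
    t = np.arange(config.n_frames)
    phase = 2.0 * np.pi * config.beat_cycles * t / (config.n_frames - 1)
    radii = rmin + (rmax - rmin) * (1.0 - np.cos(phase)) / 2.0

    frames = np.empty((n, n, config.n_frames))
    for i in range(config.n_frames):
        frames[:, :, i] = _annulus_frame(
            dist, radii[i], config.myocardium_thickness,
            config.background_intensity, config.blood_pool_intensity,
            config.myocardium_intensity,
        )
    if config.noise_sigma > 0:
        frames = np.clip(frames + rng.normal(0.0, config.noise_sigma, frames.shape), 0.0, None)

    return CineSequence(
        frames=frames,
        pixel_spacing_mm=config.pixel_spacing_mm,
        label="good",
        provenance=[
            f"phantom(centre={tuple(config.centre)}, radius_range={config.ventricle_radius_range}, "
            f"thickness={config.myocardium_thickness}, beat_cycles={config.beat_cycles}, "
            f"noise_sigma={config.noise_sigma}, seed={config.seed})"
        ],
    )


def generate_labelled_set(
    n_good: int,
    n_artefact_per_type: int,
    corruption_specs: dict | None = None,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> list[CineSequence]:
    """Generate a labelled phantom dataset with randomised geometry.

    ``corruption_specs`` maps an artefact label (``"mistriggering"`` or
    ``"breathing"``) to a corruption spec from :mod:`cineqc.kspace_artefacts`;
    each artefact member is a fresh phantom corrupted with a per-sample
    reseeded copy of that spec.  Centres are jittered uniformly within the
    valid-centre region and radii within the configured range, so ROI
    localisation is not trivially solvable.
    """
    from . import kspace_artefacts as ka

    if n_good < 0 or n_artefact_per_type < 0:
        raise ValueError("counts must be >= 0")
    corruption_specs = corruption_specs or {}
    total = n_good + n_artefact_per_type * len(corruption_specs)
    if total == 0:
        raise ValueError("requested dataset is empty (zero total size)")
    if n_artefact_per_type > 0 and not corruption_specs:
        raise ValueError("n_artefact_per_type > 0 but no corruption_specs given")

    base = base_config if base_config is not None else PhantomConfig()
    rng = np.random.default_rng(seed)

    def random_phantom() -> CineSequence:
        lo, hi = base.valid_centre_bounds()
        centre = tuple(rng.uniform(lo, hi, size=2))
        rmin, rmax = base.ventricle_radius_range
        jitter = rng.uniform(0.85, 1.0)
        cfg = replace(base, centre=centre,
                      ventricle_radius_range=(rmin * jitter, rmax * jitter),
                      seed=int(rng.integers(0, 2**31)))
        return generate_phantom(cfg)

    out: list[CineSequence] = []
    for _ in range(n_good):
        out.append(random_phantom())
    for label, spec in corruption_specs.items():
        for _ in range(n_artefact_per_type):
            clean = random_phantom()
            sample_spec = replace(spec, seed=int(rng.integers(0, 2**31)))
            if label == "mistriggering":
                out.append(ka.corrupt_mistriggering(clean, sample_spec))
            elif label == "breathing":
                out.append(ka.corrupt_breathing(clean, sample_spec))
            else:
                raise ValueError(f"unknown artefact label {label!r}")
    return out
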