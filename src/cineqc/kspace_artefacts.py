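"""Frequency-domain corruption of cine sequences.

Cartesian cine CMR fills k-space line by line over several heartbeats.  Two
acquisition failures are simulated here at graded severity:

* **mistriggering** — ECG-trigger errors fill every z-th phase-encode line of
  a frame's k-space with the corresponding line of a *different* cardiac
  phase (frame offset ``j``).  Smaller ``z`` corrupts more lines and is more
  severe.
* **breathing** — respiratory translation of the heart between line
  acquisitions: each k-space line is taken from the frame translated along
  the phase-encode (row) axis by a sinusoidal displacement, applied via the
  Fourier shift theorem.  Larger amplitude is more severe.

Only magnitude images are available as input, so corruption operates on the
Fourier transform of the magnitude image and reconstructs the magnitude of
the (now complex) inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import CineSequence

__all__ = [
    "MistriggerSpec", "BreathingSpec", "SeveritySchedule",
    "to_kspace", "from_kspace",
    "corrupt_mistriggering", "corrupt_breathing", "severity_schedule",
]


@dataclass
class MistriggerSpec:
    """Parameters of a mistriggering corruption.

    Every ``z``-th phase-encode line (a deterministic stride with seeded
    random phase ``r``) of frame ``i`` is replaced with the same line of
    frame ``(i + j) mod n_frames``.  ``offset_mode="random"`` draws ``j``
    per frame uniformly from {1, ..., n_frames-1}; ``"fixed"`` uses ``j``.
    ``phase`` pins the line phase ``r`` (otherwise seeded random in [0, z)).
    ``selection_mode="random_subset"`` replaces a random subset of
    ``n_rows // z`` lines instead of a strided comb.
    """

    z: int
    offset_mode: str = "random"
    j: int = 1
    seed: int = 0
    phase: int | None = None
    selection_mode: str = "stride"

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"z must be >= 1; got {self.z}")
        if self.offset_mode not in ("fixed", "random"):
            raise ValueError(f"offset_mode must be 'fixed' or 'random'; got {self.offset_mode!r}")
        if self.selection_mode not in ("stride", "random_subset"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.phase is not None and not (0 <= self.phase < self.z):
            raise ValueError(f"phase must lie in [0, z); got {self.phase} with z={self.z}")


@dataclass
class BreathingSpec:
    """Parameters of a breathing corruption.

    The per-line displacement is ``d(l) = offset_px + amplitude_px *
    sin(2*pi*cycles*s/n_pe_samples + phi)`` sampled at ``n_pe_samples``
    points and linearly resampled onto the frame's phase-encode lines.
    ``phi`` is seeded uniform on [0, 2*pi) unless ``phase`` pins it.
    """

    amplitude_px: float
    cycles: float = 4.0
    n_pe_samples: int = 256
    seed: int = 0
    phase: float | None = None
    offset_px: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_px < 0:
            raise ValueError(f"amplitude_px must be >= 0; got {self.amplitude_px}")
        if self.cycles <= 0:
            raise ValueError(f"cycles must be > 0; got {self.cycles}")
        if self.n_pe_samples < 2:
            raise ValueError(f"n_pe_samples must be >= 2; got {self.n_pe_samples}")


@dataclass
class SeveritySchedule:
    """Ordered corruption severities, index 0 = level 1 = most severe.

    ``params`` holds one dict per level (``{"z": ...}`` for mistriggering,
    ``{"amplitude_px": ...}`` for breathing).
    """

    artefact_type: str
    params: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.artefact_type not in ("mistriggering", "breathing"):
            raise ValueError(f"unknown artefact_type {self.artefact_type!r}")
        if not self.params:
            raise ValueError("schedule must have at least one level")

    @property
    def b(self) -> int:
        return len(self.params)

    def make_spec(self, level: int, seed: int = 0, **overrides):
        """Concrete corruption spec for 1-based severity ``level``."""
        if not (1 <= level <= self.b):
            raise ValueError(f"level must lie in [1, {self.b}]; got {level}")
        p = dict(self.params[level - 1])
        p.update(overrides)
        if self.artefact_type == "mistriggering":
            return MistriggerSpec(seed=seed, **p)
        return BreathingSpec(seed=seed, **p)


def to_kspace(frame: np.ndarray) -> np.ndarray:
    """Centred 2D DFT of a frame (unnormalised; DC at the array centre)."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame; got shape {frame.shape}")
    return np.fft.fftshift(np.fft.fft2(frame))


def from_kspace(k: np.ndarray) -> np.ndarray:
    """Magnitude of the inverse centred 2D DFT.

    Corruption generally destroys conjugate symmetry, so the inverse is
    complex; as only magnitude images exist in this pipeline, the magnitude
    is returned.
    """
    k = np.asarray(k)
    if k.ndim != 2:
        raise ValueError(f"expected a 2D k-space grid; got shape {k.shape}")
    return np.abs(np.fft.ifft2(np.fft.ifftshift(k)))


def _replaced_rows(n_rows: int, spec: MistriggerSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.z > n_rows:
        raise ValueError(f"z={spec.z} exceeds the number of phase-encode lines ({n_rows})")
    if spec.selection_mode == "random_subset":
        count = n_rows // spec.z
        return rng.choice(n_rows, size=count, replace=False)
    r = spec.phase if spec.phase is not None else int(rng.integers(0, spec.z))
    return np.arange(r, n_rows, spec.z)


def corrupt_mistriggering(seq: CineSequence, spec: MistriggerSpec) -> CineSequence:
    """Replace 1-in-z k-space lines of each frame with lines from another phase."""
    n_frames = seq.n_frames
    if n_frames < 2:
        raise ValueError("mistriggering corruption needs at least 2 frames")
    if spec.offset_mode == "fixed" and not (1 <= spec.j <= n_frames - 1):
        raise ValueError(f"fixed offset j={spec.j} must lie in [1, n_frames-1]")

    rng = np.random.default_rng(spec.seed)
    rows = _replaced_rows(seq.frames.shape[0], spec, rng)

    # k-space of the *original* frames is the source for every replacement.
    ksp = np.stack([to_kspace(seq.frames[:, :, i]) for i in range(n_frames)], axis=2)

    offsets = []
    out = np.empty_like(seq.frames)
    for i in range(n_frames):
        j = spec.j if spec.offset_mode == "fixed" else int(rng.integers(1, n_frames))
        offsets.append(j)
        k = ksp[:, :, i].copy()
        k[rows, :] = ksp[rows, :, (i + j) % n_frames]
        out[:, :, i] = from_kspace(k)

    return seq.with_frames(
        out, label="mistriggering",
        extra_provenance=(
            f"mistriggering(z={spec.z}, offsets={offsets}, rows_phase={int(rows[0]) if len(rows) else None}, "
            f"selection={spec.selection_mode}, seed={spec.seed})"
        ),
    )


def breathing_displacement(spec: BreathingSpec, n_pe: int,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-line displacement (pixels) resampled onto ``n_pe`` phase-encode lines."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    phi = spec.phase if spec.phase is not None else float(rng.uniform(0.0, 2.0 * np.pi))
    s = np.arange(spec.n_pe_samples)
    curve = spec.offset_px + spec.amplitude_px * np.sin(
        2.0 * np.pi * spec.cycles * s / spec.n_pe_samples + phi)
    target = np.linspace(0.0, spec.n_pe_samples - 1, n_pe)
    return np.interp(target, s, curve)


def corrupt_breathing(seq: CineSequence, spec: BreathingSpec) -> CineSequence:
    """Fill each k-space line from a sinusoidally translated copy of the frame.

    Translation along the phase-encode (row) axis by ``d`` multiplies k-space
    row with centred frequency ``f`` by ``exp(-2i*pi*f*d/N)`` (Fourier shift
    theorem), which handles subpixel shifts exactly.
    """
    n_pe = seq.frames.shape[0]
    rng = np.random.default_rng(spec.seed)
    d = breathing_displacement(spec, n_pe, rng)
    freqs = np.arange(n_pe) - n_pe // 2  # centred k-space: row l <-> frequency l - N//2
    shift_factor = np.exp(-2j * np.pi * freqs * d / n_pe)[:, None]

    out = np.empty_like(seq.frames)
    for i in range(seq.n_frames):
        k = to_kspace(seq.frames[:, :, i]) * shift_factor
        out[:, :, i] = from_kspace(k)

    return seq.with_frames(
        out, label="breathing",
        extra_provenance=(
            f"breathing(amplitude_px={spec.amplitude_px}, cycles={spec.cycles}, "
            f"n_pe_samples={spec.n_pe_samples}, offset_px={spec.offset_px}, seed={spec.seed})"
        ),
    )


def severity_schedule(artefact_type: str, b: int, *,
                      z_min: int = 2,
                      amplitude_max_px: float = 8.0,
                      amplitude_min_px: float = 0.8) -> SeveritySchedule:
    """Graded severity levels, level 1 most severe (easiest to classify).

    Mistriggering: z = z_min, z_min+1, ... (more lines replaced at level 1).
    Breathing: amplitudes log-spaced from ``amplitude_max_px`` down to
    ``amplitude_min_px``.
    """
    if b < 1:
        raise ValueError(f"b must be >= 1; got {b}")
    if artefact_type == "mistriggering":
        params = [{"z": z_min + i} for i in range(b)]
    elif artefact_type == "breathing":
        if b == 1:
            amps = [amplitude_max_px]
        else:
            amps = np.geomspace(amplitude_max_px, amplitude_min_px, b).tolist()
        params = [{"amplitude_px": float(a)} for a in amps]
    else:
        raise ValueError(f"unknown artefact_type {artefact_type!r}")
    return SeveritySchedule(artefact_type=artefact_type, params=params)


def corrupt_at_level(seq: CineSequence, schedule: SeveritySchedule,
                     level: int, seed: int = 0) -> CineSequence:
    """Apply the corruption of 1-based severity ``level`` from a schedule."""
    spec = schedule.make_spec(level, seed=seed)
    if schedule.artefact_type == "mistriggering":
        return corrupt_mistriggering(seq, spec)
    return corrupt_breathing(seq, spec)
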