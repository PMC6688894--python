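import numpy as np
import pytest

from cineqc import PhantomConfig, generate_phantom
from cineqc.phantom import CineSequence


@pytest.fixture(scope="session")
def small_config():
    """64px noise-free phantom, 12 frames — fast enough for per-test generation."""
    return PhantomConfig(image_size=64, n_frames=12,
                         ventricle_radius_range=(8.0, 14.0),
                         myocardium_thickness=4.0, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


def make_sequence(frames: np.ndarray, label: str | None = None) -> CineSequence:
    return CineSequence(frames=np.asarray(frames, dtype=float), label=label)


@pytest.fixture(scope="session")
def separable_batch():
    """Clean vs heavily mistriggered phantom crops: a trivially separable
    binary problem small enough to train a tiny model in seconds."""
    from cineqc import MistriggerSpec, corrupt_mistriggering, normalise_intensity

    rng = np.random.default_rng(11)

    def crop16(seq):
        h, w, _ = seq.shape
        r0, c0 = (h - 16) // 2, (w - 16) // 2
        return normalise_intensity(
            seq.with_frames(seq.frames[r0:r0 + 16, c0:c0 + 16, :]))

    out = []
    for i in range(24):
        cfg = PhantomConfig(image_size=32, n_frames=6,
                            ventricle_radius_range=(5.0, 8.0),
                            myocardium_thickness=2.0, noise_sigma=0.01,
                            seed=int(rng.integers(0, 2**31)))
        ph = generate_phantom(cfg)
        if i % 2:
            ph = corrupt_mistriggering(ph, MistriggerSpec(z=2, seed=int(rng.integers(0, 2**31))))
        out.append(crop16(ph))
    return out
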