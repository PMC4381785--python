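import numpy as np
import pytest

from dendropatch import ratio as rt
from dendropatch import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_patch_scene(
    enrichments=(1.8,),
    arcs=None,
    background_level=0.0,
    noise_sigma=0.0,
    radius_um=1.0,
    seed=0,
    **kwargs,
):
    """Single-frame scene with static patches along the default shaft."""
    if arcs is None:
        arcs = np.linspace(8.0, 40.0, len(enrichments))
    n_frames = kwargs.get("n_frames", 1)
    events = [
        sim.PatchEvent(float(a), 0, n_frames, float(e), radius_um)
        for a, e in zip(arcs, enrichments)
    ]
    cfg = sim.SceneConfig(
        patch_events=events,
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )
    return cfg, *sim.generate_scene(cfg)


def channel(stack, name, frame=0):
    return rt.ChannelImage(stack.channels[name][frame], stack.pixel_size, name)
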