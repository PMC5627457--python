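import numpy as np
import pytest

from sociotrack import arena, synthetic


@pytest.fixture(scope="session")
def config():
    return arena.default_config()


@pytest.fixture(scope="session")
def render_params():
    return synthetic.RenderParams()


@pytest.fixture(scope="session")
def sp_video(config, render_params):
    """A 60-s scripted social-preference session rendered to frames, with
    its per-frame ground-truth log.  Session-scoped: rendering dominates
    suite runtime."""
    params = synthetic.BehaviorParams(session_length_s=60.0,
                                      phase_boundary_s=24.0, seed=11)
    script = synthetic.simulate_behavior(params)
    frames, truth = synthetic.render_video(script, config, render_params)
    return script, frames, truth


def random_label_series(rng, n_frames=None, fps=30.0):
    """A random frame-label sequence with realistic run structure."""
    from sociotrack.events import LabelSeries
    if n_frames is None:
        n_frames = int(rng.integers(1, 900))
    labels = np.zeros(n_frames, dtype=np.int8)
    i = 0
    while i < n_frames:
        state = int(rng.choice([0, 0, 1, 2]))
        run = int(rng.integers(1, 40))
        labels[i:i + run] = state
        i += run
    return LabelSeries(labels, fps, corrected=False)
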