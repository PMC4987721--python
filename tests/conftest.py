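import warnings

import numpy as np
import pandas as pd
import pytest

from fadynamics import synthetic

# deprecation chatter from scikit-image internals is not ours to fix here
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def fa_image_set():
    """One rendered FA field of view (8 cells, default config, seed 1)."""
    return synthetic.generate_fa_image(synthetic.FaImageConfig(seed=1))


@pytest.fixture(scope="session")
def small_pillar_movie():
    """Short pillar movie with OU deflections under a central cell."""
    cfg = synthetic.PillarSimConfig(
        n_pillars=150, n_frames=30, ou_sd_um=0.3, ou_tau_min=30.0,
        detection_noise_um=0.03, miss_rate=0.0, seed=5,
    )
    return synthetic.generate_pillar_movie(cfg)


@pytest.fixture(scope="session")
def screen_layout():
    genes = [f"G{i:02d}" for i in range(20)]
    layout = pd.DataFrame({
        "well": [f"A{i:02d}" for i in range(21)],
        "gene": ["CTRL"] + genes,
        "is_control": [True] + [False] * 20,
    })
    categories = (
        ["increase"] * 6 + ["decrease"] * 4 + ["assembly_blocked"] * 4
        + ["disassembly_blocked"] * 3 + ["none"] * 3
    )
    effect_of = {
        "increase": (1.5, 2.4, 1.65),
        "decrease": (0.7, 1.12, 0.77),
        "assembly_blocked": (1.0, 1.0, 1.0),
        "disassembly_blocked": (1.0, 1.6, 1.6),
        "none": (1.0, 1.6, 1.1),
    }
    effects = {g: effect_of[c] for g, c in zip(genes, categories)}
    return layout, effects, dict(zip(genes, categories))


def brute_force_signed_d(test, ref):
    """Exhaustive ECDF comparison at every sample point (independent oracle).

    When the maximal |F_ref - F_test| is attained at several points the
    sign is taken at the smallest such point, matching the package's
    first-argmax convention.
    """
    test = np.asarray(test, float)
    ref = np.asarray(ref, float)
    best = 0.0
    for t in np.sort(np.concatenate([test, ref])):
        d = np.mean(ref <= t) - np.mean(test <= t)
        if abs(d) > abs(best) + 1e-12:
            best = d
    return best
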