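"""Shared fixtures: axes, class specs, and small simulated scenes.

Scene sizes here are deliberately small (tens of fitted pixels, short
axes) so the whole suite stays within a desk-scale CPU budget; the
statistically heavy checks live in tests/test_acceptance.py.
"""

import numpy as np
import pytest

from carsflim import carsfit, synth


@pytest.fixture(scope="session")
def axis240():
    return synth.make_axis()


@pytest.fixture(scope="session")
def axis120():
    return synth.make_axis(n_points=120)


@pytest.fixture(scope="session")
def lnp_spec():
    return synth.class_spec("lnp")


@pytest.fixture(scope="session")
def control_spec():
    return synth.class_spec("control")


@pytest.fixture(scope="session")
def clean_cube(lnp_spec, axis120):
    """Zero-noise LNP scene: ground truth holds to machine precision."""
    scene = synth.SceneSpec(image_shape=(48, 48), n_cells=2, droplet_density=2.0,
                            noise_sd=0.0, seed=7)
    return synth.simulate_hypercube(lnp_spec, scene, axis120)


@pytest.fixture(scope="session")
def noisy_pair(lnp_spec, control_spec, axis120):
    """A control and an LNP scene at 20 dB SNR sharing one axis."""
    out = {}
    for name, spec, seed in [("control", control_spec, 11), ("lnp", lnp_spec, 12)]:
        noise_sd = synth.noise_sd_for_snr(spec, axis120, 20.0)
        scene = synth.SceneSpec(image_shape=(48, 48), n_cells=2, droplet_density=2.0,
                                noise_sd=noise_sd, seed=seed)
        out[name] = synth.simulate_hypercube(spec, scene, axis120)
    return out


@pytest.fixture(scope="session")
def flim_scene():
    spec = synth.FlimSceneSpec(n_cells=3, coloc_rho=0.3, rho_drift_per_hour=0.1,
                               hours=(0, 3, 6), seed=5)
    return synth.simulate_flim_scene(spec, (96, 96))


def make_feature_image(rng, shape=(20, 20), n_pixels=50, shift=None):
    """A synthetic FeatureImage with random plausible 29-vectors.

    ``shift`` maps feature name -> additive offset, used to plant
    class-separating signal in chosen columns.
    """
    import pandas as pd

    rows, cols = shape
    idx = rng.choice(rows * cols, size=n_pixels, replace=False)
    r, c = np.divmod(idx, cols)
    data = {"row": r, "col": c}
    base_mu = [2775, 2825, 2875, 2925, 2975, 3025, 3075]
    for k in range(7):
        data[f"amplitude{k + 1}"] = rng.uniform(0.1, 1.0, n_pixels)
        data[f"mu{k + 1}"] = base_mu[k] + rng.normal(0, 3, n_pixels)
        data[f"sigma{k + 1}"] = rng.uniform(15, 25, n_pixels)
    table = pd.DataFrame(data)
    for k in range(7):
        table[f"AOC{k + 1}"] = (
            table[f"amplitude{k + 1}"] * table[f"sigma{k + 1}"] * np.sqrt(2 * np.pi)
        )
    table["AOCT"] = sum(table[f"AOC{k + 1}"] for k in range(7))
    if shift:
        for name, delta in shift.items():
            table[name] = table[name] + delta
    table["residual_rms"] = rng.uniform(0, 0.02, n_pixels)
    table = table[["row", "col", *carsfit.FEATURE_NAMES, "residual_rms"]]
    return carsfit.FeatureImage(table=table, shape=shape)
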