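"""Shared fixtures: synthetic panels, scenes and a trained pixel classifier.

Scene fixtures are session-scoped because rendering a full 256 x 320 x 216
acquisition pair is the most expensive step in the suite.
"""

import pytest

from nutspec import cube, pipeline, simulate
from nutspec.varieties import WALNUT_PROFILES


@pytest.fixture(scope="session")
def panel_small():
    """5 varieties x 10 kernels with default chemistry spread."""
    return simulate.generate_reference_panel(WALNUT_PROFILES, 10, seed=1)


@pytest.fixture(scope="session")
def noisy_scene(panel_small):
    """One 10-kernel tray pair rendered at default noise."""
    return simulate.generate_scene(panel_small.iloc[:10], None, simulate.NoiseConfig(), seed=7)


@pytest.fixture(scope="session")
def silent_scene(panel_small):
    """The same tray with every stochastic term off (same layout seed)."""
    noise = simulate.NoiseConfig().silent()
    return simulate.generate_scene(panel_small.iloc[:10], None, noise, seed=7)


@pytest.fixture(scope="session")
def trained_lda(noisy_scene):
    absorb = cube.absorbance_from_raw(noisy_scene.a.raw, noisy_scene.a.frames)
    return pipeline.train_segmentation_lda(absorb, noisy_scene.a.truth.mask, 1500, seed=0)


@pytest.fixture(scope="session")
def spectra_run():
    """A full 165-kernel spectra-level simulation (panel, measured, spectra)."""
    cfg = pipeline.RunConfig(seed=3, imaging=False)
    panel, measured = pipeline.simulate_panel(cfg)
    spectra = simulate.generate_spectra(panel, None, cfg.noise, cfg.seed)
    return cfg, panel, measured, spectra
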