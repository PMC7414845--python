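"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from paleocanid import microct as mc
from paleocanid import synthetic as syn


@pytest.fixture(scope="session")
def tooth_phantom():
    """Unworn default tooth phantom: (gray, labels, truth)."""
    return syn.gen_tooth_phantom(syn.ToothPhantomConfig(seed=1))


@pytest.fixture(scope="session")
def tooth_plane(tooth_phantom):
    """Cervix plane fitted on the phantom's own ring."""
    _, labels, _ = tooth_phantom
    pts = mc.extract_cervix_points(labels)
    occl = labels.coords_mm(labels.mask("enamel")).mean(axis=0)
    return mc.fit_cervix_plane(pts, toward=occl)


@pytest.fixture(scope="session")
def tooth_slice(tooth_phantom, tooth_plane):
    _, labels, _ = tooth_phantom
    return mc.extract_crown_slice(labels, tooth_plane)


@pytest.fixture(scope="session")
def outline_population():
    """Default two-group sample (21 + 23) with ground truth."""
    return syn.gen_outline_population(syn.OutlinePopConfig(seed=5))


@pytest.fixture(scope="session")
def small_read_set():
    cfg = syn.ReadSimConfig(n_reads=2000, ref_length=5000, seed=7)
    return syn.gen_ancient_reads(cfg)


@pytest.fixture(scope="session")
def synthetic_curve():
    return syn.gen_calibration_curve(syn.CurveSimConfig(seed=6))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
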