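"""Shared fixtures. UMAP fits are expensive, so fitted maps are session-scoped."""

import numpy as np
import pytest

from scopemapper import fixtures as fx
from scopemapper.fingerprints import compute_fingerprints
from scopemapper.mapping import EmbedParams, fit_map
from scopemapper.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def reference_set():
    """Default 15-family reference fixture (300 molecules, family-tagged)."""
    return fx.generate_reference(seed=42)


@pytest.fixture(scope="session")
def reference_fps(reference_set):
    return compute_fingerprints(reference_set)


@pytest.fixture(scope="session")
def small_reference():
    """5 well-separated families x 20 molecules — fast to embed."""
    fams = [f for f in fx.default_reference_families(count=20)
            if f.name in ("alkyl", "pyranose", "sulfonamide", "terpenoid", "thiophene")]
    return fx.generate_reference(fams, seed=7)


@pytest.fixture(scope="session")
def small_fps(small_reference):
    return compute_fingerprints(small_reference)


@pytest.fixture(scope="session")
def small_map(small_fps):
    return fit_map(small_fps, EmbedParams(n_neighbors=10, seed=7))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    return run_pipeline(RunConfig(outdir=str(outdir)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
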