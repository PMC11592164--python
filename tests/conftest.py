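import numpy as np
import pytest

import lesionmtl as lm

TINY_WIDTHS = (4, 8, 8, 8, 16, 16)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small in-memory synthetic dataset (64x64) shared across tests."""
    cfg = lm.SynthConfig(n_benign=12, n_melanoma=6, seed=42)
    return lm.generate_samples(cfg)


@pytest.fixture(scope="session")
def disk_dataset(tmp_path_factory):
    """Tiny synthetic dataset written to disk with its manifest."""
    out = tmp_path_factory.mktemp("synthdata")
    cfg = lm.SynthConfig(n_benign=8, n_melanoma=4, seed=7)
    records = lm.generate_dataset(cfg, out)
    return out, records


def tiny_model(variant="mtl3", seed=0, **overrides):
    overrides.setdefault("widths", TINY_WIDTHS)
    if variant == "mtl3":
        overrides.setdefault("cbam_reduction", 4)
    cfg = lm.NetworkConfig.from_variant(variant, **overrides)
    return lm.MultiTaskUNet(cfg, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
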