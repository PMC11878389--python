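import numpy as np
import pytest
from hypothesis import settings

import keratotype as kt
from keratotype import synth

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def color_scale():
    return kt.ColorScale()


@pytest.fixture(scope="session")
def small_bank(tmp_path_factory):
    """A 3-images-per-class bank with a 2-per-class train split."""
    bank = tmp_path_factory.mktemp("bank")
    rows = synth.generate_bank(
        {lab: 3 for lab in kt.CLASS_ORDER}, seed=11, out_dir=bank, train_per_class=2,
        grid_n=128,
    )
    return bank, rows


@pytest.fixture(scope="session")
def small_tensors(small_bank):
    from keratotype import pipeline

    bank, rows = small_bank
    return pipeline.dataset_from_bank(bank, rows)


@pytest.fixture(scope="session")
def symmetric_topogram():
    p = kt.sample_params(kt.ClassLabel.SYMMETRIC, rng_seed=2)
    pm = kt.make_power_map(p)
    return kt.render_topogram(pm)


def assert_valid_probs(p):
    assert np.all(np.isfinite(p))
    np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
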