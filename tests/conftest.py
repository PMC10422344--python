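import dataclasses

import numpy as np
import pytest

from ganaug.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort32(tmp_path_factory):
    """Small preprocessed-free phantom cohort shared across tests."""
    d = tmp_path_factory.mktemp("cohort32")
    spec = PhantomSpec(image_size=32, tumor_radius=3.5, noise_sigma=6.0,
                       tumor_class="glioma")
    manifest = generate_cohort({"glioma": 12, "meningioma": 12, "pituitary": 12},
                               spec, str(d), seed=11)
    return manifest


@pytest.fixture()
def train_records(cohort32):
    return [dataclasses.replace(r, split="train") for r in cohort32.records]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
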