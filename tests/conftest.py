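import numpy as np
import pytest

from histostress import (
    DatasetSpec,
    RGBPatch,
    TemplateBank,
    ToyClassifier,
    generate_patch,
    generate_patches,
    generate_scheme_bank,
    generate_template_bank,
    load_scheme_bank,
)


@pytest.fixture(scope="session")
def template_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("templates")
    generate_template_bank(seed=11, out_dir=path)
    return path


@pytest.fixture(scope="session")
def template_bank(template_dir):
    return TemplateBank(template_dir)


@pytest.fixture(scope="session")
def scheme_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("schemes")
    generate_scheme_bank(seed=13, out_dir=path)
    return path


@pytest.fixture(scope="session")
def scheme_profiles(scheme_dir):
    return {p.scheme_id: p for p in load_scheme_bank(scheme_dir)}


@pytest.fixture(scope="session")
def toy_classifier():
    return ToyClassifier.trained(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """60 labeled patches at the 5:5:2 class ratio (25/25/10)."""
    return generate_patches(DatasetSpec(25, 25, 10, seed=7))


@pytest.fixture(scope="session")
def gland_patch():
    return generate_patch("GLAND", 5).patch


@pytest.fixture(scope="session")
def tumor_patch():
    return generate_patch("TUMOR", 5).patch


@pytest.fixture
def textured_patch():
    """A 300x300 noise patch with energy at all frequencies (fixed seed)."""
    rng = np.random.default_rng(123)
    return RGBPatch(rng.integers(0, 256, size=(300, 300, 3), dtype=np.uint8), id="noise")
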