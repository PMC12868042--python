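import numpy as np
import pytest

from phantomforge.phantoms import (
    DegradationSpec,
    PhantomSpec,
    default_tissue_table,
    degrade,
    make_labels,
    render_ct,
    render_mri,
)


@pytest.fixture(scope="session")
def tissues():
    return default_tissue_table()


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(6, 96, 96), seed=3)


@pytest.fixture(scope="session")
def labels(small_spec):
    return make_labels(small_spec)


@pytest.fixture(scope="session")
def phantom_ct(labels, tissues):
    return render_ct(labels, tissues)


@pytest.fixture(scope="session")
def phantom_mri(labels, tissues):
    return render_mri(labels, tissues)


@pytest.fixture(scope="session")
def patientlike_ct(phantom_ct):
    spec = DegradationSpec(noise_sigma=25.0, noise_corr=1.0, bias_amplitude=0.05)
    return degrade(phantom_ct, spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
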