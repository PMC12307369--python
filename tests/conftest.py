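import dataclasses

import numpy as np
import pytest

import glymphkit as gk


@pytest.fixture(scope="session")
def spec_noiseless():
    return gk.PhantomSpec(snr=None)


@pytest.fixture(scope="session")
def spec_snr30():
    return gk.PhantomSpec(snr=30.0)


@pytest.fixture(scope="session")
def groups():
    return gk.default_groups()


@pytest.fixture(scope="session")
def ad_group(groups):
    return groups[0]


@pytest.fixture(scope="session")
def atlas(spec_noiseless):
    return gk.make_template_atlas(spec_noiseless)


@pytest.fixture(scope="session")
def noiseless_bundle(spec_noiseless, ad_group):
    """One deterministic noiseless subject with DWI."""
    grp = dataclasses.replace(ad_group, alps_between_sd=0.0)
    return gk.synth_subject(spec_noiseless, grp, 7)


@pytest.fixture(scope="session")
def unit_grid():
    """64^3 grid at 1 mm isotropic spacing, origin at the corner."""
    return gk.Volume(np.zeros((64, 64, 64), np.uint8), np.eye(4))
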