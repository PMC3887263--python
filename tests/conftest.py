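"""Shared fixtures: species registry, bounds, reference spectra."""

import pytest

import hostguest as hg
from hostguest import reference as ref


@pytest.fixture(scope="session")
def host():
    return ref.HOST


@pytest.fixture(scope="session")
def guest():
    return ref.GUEST


@pytest.fixture(scope="session")
def registry(host, guest):
    return [host, guest]


@pytest.fixture(scope="session")
def default_config():
    return hg.RunConfig()


@pytest.fixture(scope="session")
def positive_spectrum():
    return hg.Spectrum(
        "positive", tuple(hg.Peak(mz, i) for mz, i, _ in ref.POSITIVE_PEAKS)
    )


@pytest.fixture(scope="session")
def negative_spectrum():
    return hg.Spectrum(
        "negative", tuple(hg.Peak(mz, i) for mz, i, _ in ref.NEGATIVE_PEAKS)
    )


def make_ion(registry, label):
    return hg.parse_ion_label(label, registry)
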