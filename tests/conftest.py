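import pytest

from methylsense import synthetic_data as sd


@pytest.fixture(scope="session")
def wbox():
    return sd.wbox_pwm()


@pytest.fixture(scope="session")
def fixture_unmethylated():
    return sd.build_geometry_fixture(methylated=False)


@pytest.fixture(scope="session")
def fixture_methylated():
    return sd.build_geometry_fixture(methylated=True)


@pytest.fixture(scope="session")
def planted_bundle():
    """500-region peakset with the default planted W-box effects."""
    return sd.generate_methylome_peakset(500, seed=1)
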