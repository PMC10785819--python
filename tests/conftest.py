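import pytest

from crisscut import BuildConfig, build_scission_model


@pytest.fixture(scope="session")
def toy_spec():
    """Smallest nontrivial ribbon: one cross bond, one cut-y type, one copy.

    Small enough for exact state-space enumeration.
    """
    return build_scission_model(
        BuildConfig(
            core_slat_length=2,
            extension_length=1,
            include_cut_x=False,
            cut_excess=1,
        )
    )


@pytest.fixture(scope="session")
def small_spec():
    """L=4 ribbon with both cut families — fast to simulate."""
    return build_scission_model(BuildConfig(core_slat_length=4, extension_length=3))


@pytest.fixture(scope="session")
def default_spec():
    """The headline configuration: core slat length 10, extension length 5."""
    return build_scission_model(BuildConfig(core_slat_length=10, extension_length=5))
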