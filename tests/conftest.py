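import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def suspects():
    from pcbscreen.chem_core import enumerate_suspects

    return enumerate_suspects(classes_only=True)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study (2 groups x 3 samples) for fast tests."""
    from pcbscreen.synthetic_data import StudyConfig, generate_study

    cfg = StudyConfig(
        groups=(("M", "WT"), ("F", "KO")),
        n_per_group=3,
        n_decoys=40,
    )
    return cfg, generate_study(cfg, seed=11)
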