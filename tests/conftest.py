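"""Shared fixtures: expensive study results computed once per session."""
import pytest

from pcmfrap import protocols

# Declared once, before any outcome was inspected; used by every study-level
# test so results are reproducible run to run.
STUDY_SEED = 20140917


@pytest.fixture(scope="session")
def classification_batch():
    return protocols.classification_study(STUDY_SEED, n_per_class=20)


@pytest.fixture(scope="session")
def even_recovery_result():
    return protocols.even_recovery_study(STUDY_SEED + 1)


@pytest.fixture(scope="session")
def spreading_result():
    return protocols.spreading_study(STUDY_SEED + 2)


@pytest.fixture(scope="session")
def roi_kinetics_result():
    return protocols.roi_kinetics_study(STUDY_SEED + 3)


@pytest.fixture(scope="session")
def double_bleach_result():
    return protocols.double_bleach_study(STUDY_SEED + 4)
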