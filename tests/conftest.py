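import random

import pytest

from riboseek.examples import XPT_APTAMER
from riboseek.folding import NussinovEngine, ViennaEngine, fold_mfe


@pytest.fixture(scope="session")
def builtin_engine():
    return NussinovEngine()


@pytest.fixture(scope="session")
def vienna_engine():
    return ViennaEngine()


@pytest.fixture(scope="session", params=["builtin", "vienna"])
def any_engine(request, builtin_engine, vienna_engine):
    return builtin_engine if request.param == "builtin" else vienna_engine


@pytest.fixture(scope="session")
def xpt():
    return XPT_APTAMER


@pytest.fixture(scope="session")
def xpt_ref(vienna_engine, xpt):
    """The thermodynamic MFE structure of the xpt aptamer (three-stem
    multibranch), used as the reference throughout pipeline tests."""
    structure, _ = fold_mfe(xpt, vienna_engine)
    return structure


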