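import dataclasses

import pytest

from cavcmi.channel_model import GatingParams, VoltageProtocol


@pytest.fixture(scope="session")
def default_params() -> GatingParams:
    return GatingParams()


@pytest.fixture(scope="session")
def cmi_params(default_params) -> GatingParams:
    """The inducible-CMI scenario weight that reduces the peak to 35%."""
    return dataclasses.replace(default_params, w=0.8125)


@pytest.fixture(scope="session")
def single_step() -> VoltageProtocol:
    return VoltageProtocol.default_single()


@pytest.fixture(scope="session")
def family_protocol() -> VoltageProtocol:
    return VoltageProtocol.default_family()
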