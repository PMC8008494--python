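import pytest

from brca2hdr.calibration import ControlSet
from brca2hdr.hdr_quant import FunctionCall, load_table1
from brca2hdr.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=20210219)


@pytest.fixture()
def perfect_calls():
    """Calls that separate a control set perfectly, keyed off truth labels."""

    def _make(controls: ControlSet):
        return {
            v.variant_id: (
                FunctionCall.NON_FUNCTIONAL
                if v.truth.value == "pathogenic"
                else FunctionCall.FUNCTIONAL
            )
            for v in controls.variants
        }

    return _make
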