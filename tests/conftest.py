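import numpy as np
import pytest

from smskinetics import RateConstants, build_sms_network

#: the published stepwise constants of the SMS cycle
BASELINE = (0.1, 0.2, 1.0, 1.43)
#: symmetric starting composition, % mol/mol per lipid
START_25 = (25.0, 25.0, 25.0, 25.0)


@pytest.fixture
def baseline_rc() -> RateConstants:
    return RateConstants(*BASELINE)


@pytest.fixture
def baseline_net(baseline_rc):
    return build_sms_network(baseline_rc, START_25, enzyme_total=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
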