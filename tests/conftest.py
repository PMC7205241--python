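import pytest

import psmcea as m

# published log-logistic parameters (time in months): (arm, endpoint) -> (theta, kappa)
TABLE1 = {
    ("ram", "pfs"): (-3.157, 2.058),
    ("pla", "pfs"): (-2.268, 2.042),
    ("ram", "os"): (-4.671, 2.089),
    ("pla", "os"): (-3.337, 1.681),
}


@pytest.fixture(scope="session")
def cfg():
    return m.ModelConfig()


@pytest.fixture(scope="session")
def bundle():
    """Baseline model at the mainland-scenario ramucirumab price."""
    return m.default_bundle(ram_price_per_cycle=244.0)


@pytest.fixture(scope="session")
def base_case(bundle):
    """Both arms evaluated once at the mainland WTP (reused across tests)."""
    return m.run_comparison(bundle, 26022.0)


def params(arm, endpoint):
    theta, kappa = TABLE1[(arm, endpoint)]
    return m.LogLogisticParams(theta=theta, kappa=kappa, label=f"{arm}-{endpoint}")
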