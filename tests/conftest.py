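import pytest

import hiersd as hs


@pytest.fixture(scope="session")
def atp():
    """Canonical ATP module: k_s=k_d=C=k_a=1, ADP_ss=0.5, k_b=0.25 (k_0=0.25)."""
    return hs.make_atp_module()


@pytest.fixture(scope="session")
def atp_integral():
    """Ideal-integral ATP module: zero-order enzyme degradation (k_b=0, k_0=0.5)."""
    return hs.make_atp_module(k_b=0.0)


@pytest.fixture(scope="session")
def end_product():
    """End-product operon pathway with leaky integration (k_ED=0.2)."""
    return hs.make_end_product_operon(k_ED=0.2)


@pytest.fixture(scope="session")
def end_product_integral():
    """End-product operon pathway with ideal integral control (k_ED=0)."""
    return hs.make_end_product_operon(k_ED=0.0)


@pytest.fixture(scope="session")
def initial_product():
    return hs.make_initial_product_module()


@pytest.fixture(scope="session")
def leucine():
    return hs.make_leucine_skeleton()


@pytest.fixture(scope="session")
def atp_ss(atp):
    return hs.find_steady_state(atp)


@pytest.fixture(scope="session")
def end_product_ss(end_product):
    return hs.find_steady_state(end_product)
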