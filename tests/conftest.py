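import pytest

from marrowsim import Params


@pytest.fixture
def make_params():
    """Factory for Params with small, fast defaults."""

    def _make(**kw):
        base = dict(
            psi=2, theta=2, phi=2, delta=5, m=2, eta=1,
            width=7, height=7, topology="bounded",
        )
        base.update(kw)
        return Params(**base)

    return _make


@pytest.fixture
def small_params(make_params):
    return make_params()
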