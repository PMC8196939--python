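import pytest

from sispulse import get_preset


@pytest.fixture(scope="session")
def fig1():
    return get_preset("fig1")


@pytest.fixture(scope="session")
def fig2a():
    return get_preset("fig2a")


@pytest.fixture(scope="session")
def fig2b():
    return get_preset("fig2b")


@pytest.fixture(scope="session")
def rng_params():
    """Seeded random valid parameter sets for property tests."""
    import numpy as np

    from sispulse import ModelParams

    def draw(n, **overrides):
        # fresh generator per call so draws do not depend on test order
        rng = np.random.default_rng([20240917, n])
        out = []
        while len(out) < n:
            A = rng.uniform(1, 12)
            d = rng.uniform(0.1, 1.5)
            kw = dict(
                A=A,
                d=d,
                beta=rng.uniform(0.05, 2.0),
                v=rng.uniform(0.1, 5.0),
                theta=rng.uniform(0.0, 1.0),
                c=rng.uniform(0.1, 4.0),
                b=rng.uniform(0.2, 3.0),
                q=rng.uniform(0.05, 0.9),
                S_T=rng.uniform(0.3, 0.9) * A / d,
            )
            kw.update(overrides)
            out.append(ModelParams(**kw))
        return out

    return draw
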