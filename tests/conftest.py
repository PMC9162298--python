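import numpy as np
import pytest

from emotransfer import (
    GeneratorConfig,
    SourceEmotionSpec,
    TargetEmotionSpec,
    TransferModelSpec,
    builtin_fixture,
    generate_series,
)


@pytest.fixture(scope="session")
def table2_base():
    """Simulation-study parameters; (a, b) unset."""
    return builtin_fixture("table2")


@pytest.fixture(scope="session")
def table6_spec():
    """Empirical regression-parameter fixture (fully parameterized)."""
    return builtin_fixture("table6")


@pytest.fixture(scope="session")
def known_spec():
    """A fully-known two-source spec with moderate rates, safe for the
    unit-step recursion and with well-separated composites."""
    return TransferModelSpec(
        sources=(
            SourceEmotionSpec("negative", x0=80.0, r=0.7, K=800.0, a=0.5, b=0.9),
            SourceEmotionSpec("neutral", x0=40.0, r=0.9, K=400.0, a=0.3, b=0.4),
        ),
        target=TargetEmotionSpec("positive", y0=20.0, r=0.8, K=300.0),
    )


@pytest.fixture(scope="session")
def recursion_series(known_spec):
    """Noise-free unit-step recursion data, the estimator's exact model class."""
    return generate_series(GeneratorConfig(spec=known_spec, mode="difference", horizon=15))


def random_spec(rng: np.random.Generator, n_sources: int = 2) -> TransferModelSpec:
    """A random valid spec for property tests."""
    sources = tuple(
        SourceEmotionSpec(
            label=f"s{i}",
            x0=float(rng.uniform(5, 50)),
            r=float(rng.uniform(0.2, 1.5)),
            K=float(rng.uniform(100, 1000)),
            a=float(rng.uniform(0.05, 0.95)),
            b=float(rng.uniform(0.05, 0.95)),
        )
        for i in range(n_sources)
    )
    target = TargetEmotionSpec(
        label="t",
        y0=float(rng.uniform(5, 50)),
        r=float(rng.uniform(0.2, 1.5)),
        K=float(rng.uniform(100, 1000)),
    )
    return TransferModelSpec(sources=sources, target=target)
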