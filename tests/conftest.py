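import numpy as np
import pytest

from sniper_nmr import GolemSpec, SpinSystem, design_golem


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def plain_system():
    """Coupled pair without relaxation."""
    return SpinSystem(J_NH=92.0)


@pytest.fixture
def relaxing_system():
    """Amide-like rates for a disordered-protein residue."""
    return SpinSystem(J_NH=92.0, R1_H=1.2, R2_H=8.0, R1_N=1.5, R2_N=6.0,
                      sigma_HN=-0.03)


@pytest.fixture(scope="session")
def golem_default():
    """The default ultra-selective pulse design (expensive; shared)."""
    spec = GolemSpec(seed=1)
    with np.errstate(all="ignore"):
        shape, diagnostics = design_golem(spec)
    return spec, shape, diagnostics


def random_system(rng, relax=True):
    kw = dict(
        offset_H=float(rng.uniform(-200, 200)),
        offset_N=float(rng.uniform(-100, 100)),
        J_NH=float(rng.uniform(85, 100)),
    )
    if relax:
        r1h, r1n = rng.uniform(0.5, 2.5, 2)
        kw.update(R1_H=float(r1h), R2_H=float(rng.uniform(r1h / 2, 12)),
                  R1_N=float(r1n), R2_N=float(rng.uniform(r1n / 2, 12)),
                  sigma_HN=float(rng.uniform(-0.3, 0.3) *
                                 np.sqrt(r1h * r1n)))
    return SpinSystem(**kw)
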