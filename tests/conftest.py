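import numpy as np
import pytest

from permeakit.synth import (
    BiasSpec,
    LangevinConfig,
    PotentialSpec,
    simulate_overdamped,
)
from permeakit.wham import UmbrellaWindow


@pytest.fixture(scope="session")
def ca_like_spec() -> PotentialSpec:
    """Landscape shaped like the divalent-cation PMF: a deep coordination
    well on the luminal side followed by the selectivity-filter barrier."""
    return PotentialSpec(terms=((-4.1, -2.0, 1.0), (2.8, 1.0, 1.0)))


@pytest.fixture(scope="session")
def mutant_like_spec() -> PotentialSpec:
    """The charge-neutralized variant: coordination well removed, barrier
    raised above 10 kcal/mol."""
    return PotentialSpec(terms=((10.5, 1.0, 1.0),))


def sample_umbrella_windows(
    spec: PotentialSpec,
    centers,
    force_constant: float = 10.0,
    n_steps: int = 225_000,
    discard: int = 20_000,
    stride: int = 10,
    seed0: int = 100,
    n_blocks: int = 7,
):
    """Simulate one biased window per center and package the (thinned)
    samples with a block length that divides them into n_blocks."""
    windows = []
    for i, c in enumerate(centers):
        # low friction decorrelates the window quickly, so the 7 error
        # blocks are statistically independent
        cfg = LangevinConfig(
            friction=0.1, timestep=1e-4, n_steps=n_steps, seed=seed0 + i,
            initial_position=float(c),
        )
        traj = simulate_overdamped(spec, [BiasSpec("harmonic", float(c),
                                                   force_constant)], cfg)
        samples = traj[discard::stride]
        n_keep = (samples.size // n_blocks) * n_blocks
        windows.append(UmbrellaWindow(
            center=float(c), force_constant=force_constant,
            samples=samples[:n_keep], block_length=n_keep // n_blocks,
        ))
    return windows


@pytest.fixture(scope="session")
def ca_like_windows(ca_like_spec):
    """20 umbrella windows, 0.5 Å apart, across the well-plus-barrier
    landscape; shared across tests to avoid resampling."""
    centers = np.arange(-4.75, 5.0, 0.5)
    return sample_umbrella_windows(ca_like_spec, centers)
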