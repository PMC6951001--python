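import numpy as np
import pytest

from t1quant import (
    ImhCoreSpec,
    MvoCoreSpec,
    NoiseSpec,
    PhantomSpec,
    generate_phantom,
)
from t1quant.core import AngularSector


@pytest.fixture
def noiseless_phantom():
    """Plain oedema phantom, no cores, no noise."""
    return generate_phantom(PhantomSpec(noise_sd=NoiseSpec.none()))


@pytest.fixture
def noiseless_full_phantom():
    """Noiseless phantom with no-reflow and haemorrhage cores."""
    return generate_phantom(
        PhantomSpec(noise_sd=NoiseSpec.none(), mvo_core=MvoCoreSpec(), imh_core=ImhCoreSpec())
    )


def random_phantom_spec(seed: int, grid: int = 64) -> PhantomSpec:
    """A randomised small phantom spec for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    endo = float(rng.uniform(8.0, 12.0))
    epi = endo + float(rng.uniform(7.0, 10.0))
    center_angle = float(rng.uniform(0.0, 360.0))
    width = float(rng.uniform(70.0, 160.0))
    mvo = MvoCoreSpec() if rng.random() < 0.5 else None
    imh = ImhCoreSpec() if rng.random() < 0.5 else None
    return PhantomSpec(
        grid_size=(grid, grid),
        endo_radius=endo,
        epi_radius=epi,
        aar_sector=AngularSector(center_angle, width),
        mvo_core=mvo,
        imh_core=imh,
        seed=seed,
    )
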