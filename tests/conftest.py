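import numpy as np
import pytest

from lungquant.phantom import PhantomConfig, generate_phantom

# small, fast grid for most segmentation tests; coarse 3 mm voxels keep the
# volumes realistic (~750 mL lungs) while staying cheap
SMALL_GRID = dict(shape=(48, 64, 64), spacing=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def phantom_clean():
    """No contusion, no pneumothorax."""
    return generate_phantom(PhantomConfig(**SMALL_GRID, seed=11))


@pytest.fixture(scope="session")
def phantom_25_10():
    """25% contusion with consolidation cores, 10% pneumothorax."""
    return generate_phantom(
        PhantomConfig(
            **SMALL_GRID,
            target_contusion_fraction=25.0,
            pneumothorax_fraction=10.0,
            contusion_texture="ggo+consolidation",
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def phantom_40():
    """40% contusion with consolidation, no pneumothorax."""
    return generate_phantom(
        PhantomConfig(
            **SMALL_GRID,
            target_contusion_fraction=40.0,
            contusion_texture="ggo+consolidation",
            seed=3,
        )
    )


def dice(a, b) -> float:
    a = a.voxels if hasattr(a, "voxels") else np.asarray(a)
    b = b.voxels if hasattr(b, "voxels") else np.asarray(b)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
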