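import numpy as np
import pytest

from nicheshift.envspace import GridSpec, NicheGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid_spec(r=10, lo=0.0, hi=1.0):
    return GridSpec(xmin=lo, xmax=hi, ymin=lo, ymax=hi, resolution=r)


def grid_from_surface(z, spec=None, mask=None, bg_density=None,
                      percentiles=(75, 100)):
    """Hand-built NicheGrid around an explicit density surface (for oracle and
    limit-case tests)."""
    z = np.asarray(z, dtype=float)
    if spec is None:
        spec = make_grid_spec(r=z.shape[0])
    if mask is None:
        mask = np.ones_like(z, dtype=bool)
    total = z.sum()
    zn = z / total if total > 0 else z
    return NicheGrid(
        spec=spec, z=zn, z_corrected=zn,
        bg_density=bg_density if bg_density is not None else np.ones_like(z),
        masks={int(p): mask.copy() for p in percentiles},
        n_occurrences=100,
    )


@pytest.fixture
def grid_factory():
    return grid_from_surface
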