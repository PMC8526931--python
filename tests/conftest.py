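import numpy as np
import pytest

from tissueatlas import PhantomSpec, ProportionMap, assemble_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """A small phantom spec that keeps test runtimes low."""
    return PhantomSpec(
        grid_shape=(36, 36, 36),
        wm_semi_axes=(6.0, 5.5, 5.0),
        gm_semi_axes=(11.0, 10.5, 10.0),
        csf_semi_axes=(16.0, 15.5, 15.0),
        seed=7,
    )


def make_maps(values_4d, tissue="GM", affine=None):
    """Wrap a (subjects, nx, ny, nz) array into ProportionMaps."""
    affine = np.eye(4) if affine is None else affine
    return [
        ProportionMap(f"sub-{i:03d}", tissue, v, affine)
        for i, v in enumerate(values_4d)
    ]


@pytest.fixture
def tiny_stack():
    """3 subjects on a 4x4x4 grid, values in [0, 1]."""
    rng = np.random.default_rng(11)
    data = rng.random((3, 4, 4, 4))
    return assemble_stack(make_maps(data))
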