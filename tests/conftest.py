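import numpy as np
import pytest

from staincycle import SyntheticSlideSpec, render_slide_pair


@pytest.fixture(scope="session")
def std_pair():
    """A mid-size mixed tumour/normal slide pair with ground truth."""
    spec = SyntheticSlideSpec(width=256, height=256, n_cells=120,
                              tissue_fraction=0.75, tumor_region_fraction=0.5,
                              positive_fraction=0.4, seed=3)
    return render_slide_pair(spec)


@pytest.fixture(scope="session")
def mil_slides():
    """Ten small slides (alternating tumour/normal) for fast MIL tests."""
    out = []
    for i in range(10):
        spec = SyntheticSlideSpec(width=160, height=160, n_cells=40,
                                  tissue_fraction=0.85,
                                  tumor_region_fraction=0.5 if i % 2 == 0 else 0.0,
                                  positive_fraction=0.8, seed=700 + i)
        out.append(render_slide_pair(spec, slide_id=f"mil{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
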