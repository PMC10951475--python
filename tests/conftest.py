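import numpy as np
import pytest

from fastpaint.localization_io import make_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n, fov_w=16, fov_h=16, n_frames=1000, with_precision=False):
    """A uniform random localization table for round-trip/oracle tests."""
    kwargs = {}
    if with_precision:
        kwargs["lpx"] = rng.uniform(0.01, 0.2, n)
        kwargs["lpy"] = rng.uniform(0.01, 0.2, n)
    return make_table(
        frame=rng.integers(0, n_frames, n),
        x=rng.uniform(0, fov_w, n).astype(np.float32) % fov_w,
        y=rng.uniform(0, fov_h, n).astype(np.float32) % fov_h,
        photons=rng.exponential(1000.0, n),
        fov_width=fov_w,
        fov_height=fov_h,
        n_frames_total=n_frames,
        **kwargs,
    )
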