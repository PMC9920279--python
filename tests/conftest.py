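import numpy as np
import pytest

from odcss.clustering import ODCState
from odcss.config import KernelConfig, RunConfig
from odcss.stream import StreamSample


@pytest.fixture
def fixed_kernel():
    """Kernel with optimization off, for closed-form comparisons."""
    return KernelConfig(optimize=False, length_scale_init=1.0,
                       signal_variance_init=1.0, noise_variance_init=1e-4)


@pytest.fixture
def state_1d():
    """1-D clustering state with R=1, M=2 and no clusters yet."""
    cfg = RunConfig(R=1.0, M=2, seed=0)
    return ODCState(config=cfg)


def make_samples(xs, ys=None, t0=0):
    """Build StreamSamples from a list of feature vectors (or scalars)."""
    samples = []
    for i, x in enumerate(xs):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = None if ys is None else ys[i]
        samples.append(StreamSample(t=t0 + i, x=x, y=y))
    return samples


@pytest.fixture
def linear_labeled_db():
    """Five standardized 1-D labeled points on the line y = 2x, with a gap at x=3."""
    xs = [0.0, 1.0, 2.0, 4.0, 5.0]
    return make_samples(xs, ys=[2 * x for x in xs])
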