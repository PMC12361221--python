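import os

# tiny matrices: BLAS threading only adds overhead and nondeterminism
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")

import numpy as np
import pytest

from bisenext.config import NetworkConfig, PointParams
from bisenext.synth import SceneSpec, generate_scene, smoke_spec_kwargs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Width/8 network at 64x64 input: every module present, CPU-friendly."""
    return NetworkConfig(input_size=64, width_mult=0.125, eama_groups=2,
                         point_params=PointParams(j=3, n=128, beta=0.75, m=2))


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    from bisenext.backbone import BiSeNeXt

    return BiSeNeXt(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_scenes():
    """Eight deterministic 64x64 scenes covering all three classes."""
    return [generate_scene(SceneSpec(seed=i, **smoke_spec_kwargs(64)))
            for i in range(8)]


def numeric_grad(fn, arrs, seed_grad, eps=1e-5):
    """Central-difference gradients of sum(fn(*arrs) * seed_grad)."""
    grads = []
    for target in arrs:
        g = np.zeros_like(target)
        it = np.nditer(target, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = target[i]
            target[i] = orig + eps
            lp = float((fn(*arrs) * seed_grad).sum())
            target[i] = orig - eps
            lm = float((fn(*arrs) * seed_grad).sum())
            target[i] = orig
            g[i] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads
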