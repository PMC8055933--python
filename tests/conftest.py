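import logging

import numpy as np
import pytest

from attnrank.network import ArchitectureSpec, GatedAttentionNet
from attnrank.synthetic import CohortConfig, generate_cohort

# quota warnings from saturated rings are expected on tiny synthetic volumes
logging.getLogger("attnrank.patches").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_arch():
    """Small architecture for fast exact tests (27-voxel patches)."""
    return ArchitectureSpec(n_contrasts=2, patch_size=3, n_filters=3,
                            hidden_dim=4, attn_dim=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort shared by patch / correlation / io tests."""
    config = CohortConfig(n_subjects=6, volume_shape=(24, 24, 24), n_contrasts=4,
                          informative_set=(0, 2), n_lesions_range=(1, 2),
                          lesion_radius_range=(2, 3), seed=11)
    return config, generate_cohort(config)


def finite_diff_grads(net, x, y, n_per_param=4, eps=1e-6, seed=1):
    """Central finite differences of the BCE loss wrt sampled parameters."""
    def loss_only():
        p = np.clip(net.forward(x, training=True)["prob"], 1e-12, 1 - 1e-12)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    rng = np.random.default_rng(seed)
    out = {}
    for k, p in net.parameters().items():
        flat = p.ravel()
        idx = rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False)
        vals = []
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_only()
            flat[i] = orig - eps
            lm = loss_only()
            flat[i] = orig
            vals.append((i, (lp - lm) / (2 * eps)))
        out[k] = vals
    return out
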