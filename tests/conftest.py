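import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def warm_kernels():
    """Compile the numba kernels once so individual tests time only their work."""
    from lambclust._kernels import block_log_marginal, crp_scan, pred_logpdf_stats, restricted_scan_kernel

    d = 2
    eta = np.zeros((3, d))
    rng = np.random.default_rng(0)
    pred_logpdf_stats(np.zeros(d), np.zeros(1), np.zeros((1, d)), np.zeros((1, d, d)), 1.0, 5.0, 1.0)
    block_log_marginal(eta, 1.0, 5.0, 1.0)
    labels = np.zeros(3, dtype=np.int64)
    ids = np.full(4, -1, dtype=np.int64)
    ids[0] = 0
    counts = np.zeros(4)
    counts[0] = 3.0
    sums = np.zeros((4, d))
    sums[0] = eta.sum(0)
    outers = np.zeros((4, d, d))
    crp_scan(eta, labels, ids, counts, sums, outers, 1, 1.0, 1.0, 5.0, 1.0, rng)
    restricted_scan_kernel(
        eta, np.zeros(0, dtype=np.int64), np.zeros(3, dtype=np.int64),
        np.array([1.0, 2.0]), np.zeros((2, d)), np.zeros((2, d, d)),
        1.0, 5.0, 1.0, rng, False, np.zeros(3, dtype=np.int64),
    )
    return True
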