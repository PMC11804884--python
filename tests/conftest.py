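import numpy as np
import pytest

from mbiselect import PanelData, SourcePartition, detect_layout


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_three_source_panel(
    rng,
    n_k=(6, 8, 8),
    block_size=2,
    m=3,
    beta=None,
    noise=0.3,
):
    """Small three-source panel with the canonical missing layout:
    pattern 1 complete, pattern 2 missing source 3, pattern 3 missing
    source 2.  Covariates are cross-correlated so imputation has signal.
    """
    n = sum(n_k)
    p = 3 * block_size
    shared = rng.standard_normal((n, m, 1))
    x = 0.6 * shared + 0.8 * rng.standard_normal((n, m, p))
    if beta is None:
        beta = np.zeros(p)
        beta[0] = 1.0
        beta[block_size] = -0.5
    y = x @ beta + noise * rng.standard_normal((n, m))
    xm = x.copy()
    src = [range(s * block_size, (s + 1) * block_size) for s in range(3)]
    start = n_k[0]
    xm[start : start + n_k[1], :, src[2]] = np.nan
    xm[start + n_k[1] :, :, src[1]] = np.nan
    panel = PanelData(y=y, x=xm, subject_id=np.arange(1, n + 1))
    partition = SourcePartition(src)
    return panel, partition, x, np.asarray(beta, float)


@pytest.fixture
def canonical3(rng):
    panel, partition, x_full, beta = make_three_source_panel(rng)
    layout = detect_layout(panel, partition)
    return {
        "panel": panel,
        "partition": partition,
        "layout": layout,
        "x_full": x_full,
        "beta": beta,
    }


@pytest.fixture
def complete_panel(rng):
    """Fully observed single-source-free panel (K=1) for oracle checks."""
    n, m, p = 20, 3, 4
    x = rng.standard_normal((n, m, p))
    beta = np.array([1.0, -0.5, 0.0, 2.0])
    y = x @ beta + rng.standard_normal((n, m))
    panel = PanelData(y=y, x=x, subject_id=np.arange(n))
    partition = SourcePartition([range(p)])
    detect_layout(panel, partition)
    return panel, partition, beta
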