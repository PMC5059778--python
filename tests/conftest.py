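import numpy as np
import pytest

from nksocial.landscape import NKLandscape


@pytest.fixture(scope="session")
def rugged_landscape():
    """A mid-size rugged landscape shared by read-only tests."""
    return NKLandscape.generate(10, 5, seed=11)


def manual_landscape(tables, partners=None, **kw):
    """Build a landscape from explicit contribution tables (list of rows)."""
    tables = np.asarray(tables, dtype=float)
    N = tables.shape[0]
    K = int(np.log2(tables.shape[1])) - 1
    if partners is None:
        partners = [[(i + j + 1) % N for j in range(K)] for i in range(N)]
    return NKLandscape(
        N=N,
        K=K,
        interaction_map=np.array(partners, dtype=np.int64).reshape(N, K),
        contribution_tables=tables,
        **kw,
    )
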