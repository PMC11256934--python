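import numpy as np
import scipy.sparse as sp

from pathimpute import ExpressionDataset


def random_dataset(rng, n=20, m=30, density=0.4, coords=True) -> ExpressionDataset:
    """Small random sparse dataset helper shared by several test modules."""
    mat = sp.random(
        n, m, density=density,
        random_state=np.random.RandomState(rng.integers(2**31)),
        data_rvs=lambda k: rng.integers(1, 9, k).astype(float),
    )
    return ExpressionDataset(
        values=sp.csr_matrix(mat),
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        coords=rng.uniform(0, 10, (n, 2)) if coords else None,
    )
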