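"""Small shared builders for the test suite."""

import numpy as np
import pandas as pd

from methylstream import Batch, ChunkSpec, MethylStore

_counter = {"n": 0}


def tiny_store(tmp_path, m, u, chunk_spec=None):
    """Store holding one explicit (P x S) M/U pair."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    P, S = m.shape
    man = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(P)],
            "design_type": ["II"] * P,
            "channel": ["Both"] * P,
            "chromosome": ["chr1"] * P,
            "position": np.arange(1, P + 1) * 100,
            "is_control": [False] * P,
        }
    )
    _counter["n"] += 1
    store = MethylStore.create(
        tmp_path / f"tiny{_counter['n']}.h5", man, chunk_spec or ChunkSpec()
    )
    store.append_samples(
        Batch(
            sample_ids=[f"s{j}" for j in range(S)],
            probe_ids=man["probe_id"].tolist(),
            methylated=m,
            unmethylated=u,
        )
    )
    return store


def store_with_betas(tmp_path, betas, chunk_spec=None, name=None):
    """Store whose betas assay holds an explicit matrix (M/U synthetic)."""
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    t = 5000.0
    m = betas * t
    u = np.maximum((1 - betas) * t - 100.0, 0.0)
    store = tiny_store(tmp_path, m, u, chunk_spec)
    from methylstream import compute_betas

    compute_betas(store)
    return store


def dense_quantile_normalize(X):
    """Independent dense oracle for classic quantile normalization.

    Reference = elementwise mean of the sorted columns; each value maps
    to the reference at its rank; tied values get the mean of the
    reference entries at the tied positions.  Written as plain loops so
    it shares no code with the streaming implementation.
    """
    X = np.asarray(X, dtype=float)
    P, S = X.shape
    ref = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(S):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(P)
        assigned[order] = ref
        for v in np.unique(col):
            mask = col == v
            assigned[mask] = assigned[mask].mean()
        out[:, j] = assigned
    return out
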