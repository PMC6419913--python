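"""Shared helper for the example scripts."""

import methylstream as ms


def store_from_dataset(path, ds, chunk_spec=None):
    store = ms.create_store(path, ds.manifest, chunk_spec or ms.ChunkSpec())
    store.append_samples(ds.as_batch())
    ms.compute_betas(store)
    return store
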