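import numpy as np
import pytest

from methylstream import ChunkSpec, MethylStore, compute_betas, simulate_dataset


def build_store(path, ds, chunk_spec=None, betas=True, n_batches=1):
    """Create a store from a simulated dataset, appending in n_batches."""
    from methylstream.ingest import parse_manifest  # noqa: F401  (manifest df already typed)

    store = MethylStore.create(str(path), ds.manifest, chunk_spec or ChunkSpec())
    ids = ds.sample_ids
    bounds = np.array_split(np.arange(len(ids)), n_batches)
    for part in bounds:
        if len(part):
            store.append_samples(ds.as_batch([ids[i] for i in part]))
    if betas:
        compute_betas(store)
    return store


@pytest.fixture
def store_factory(tmp_path):
    stores = []

    def _make(ds, name="store.h5", chunk_spec=None, betas=True, n_batches=1):
        st = build_store(tmp_path / name, ds, chunk_spec, betas, n_batches)
        stores.append(st)
        return st

    yield _make
    for st in stores:
        try:
            st.close()
        except Exception:
            pass


@pytest.fixture(scope="session")
def small_ds():
    """Read-only small cohort: 400 probes x 24 samples, mild noise."""
    return simulate_dataset(P=400, S=24, seed=11)


@pytest.fixture(scope="session")
def clean_ds():
    """Noise-free cohort for exact round-trip checks (do not mutate)."""
    return simulate_dataset(
        P=400, S=24, seed=7, beta_noise_sd=0.0, intensity_noise_sd=0.0,
        conversion_noise_sd=0.0,
    )
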