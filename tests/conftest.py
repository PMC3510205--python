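import pytest

from nucstate.synthetic_data import (
    SimConfig,
    build_genome,
    simulate_library_arrays,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    ds = build_genome(SimConfig(seed=1))
    libs = {lib: simulate_library_arrays(ds, lib) for lib in ("nucRNA", "RNAPII", "input")}
    conservation, tf_peaks = simulate_tracks(ds)
    return {
        "dataset": ds,
        "libs": libs,
        "tracks": {lib: libs[lib].coverage() for lib in libs},
        "conservation": conservation,
        "tf_peaks": tf_peaks,
    }


@pytest.fixture(scope="session")
def small_genome():
    """A tiny gene-only genome for fast structural tests."""
    cfg = SimConfig(
        seed=5, n_chroms=1, chrom_length=300_000,
        n_genes={"BT": 2, "loBT": 6}, n_enhancers=0,
        n_lncrna=0, n_lncrna_decoys=0, input_artifact=False,
        n_stall={},
    )
    ds = build_genome(cfg)
    return ds
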