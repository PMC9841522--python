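import numpy as np
import pytest

from vstriage import (
    CompoundRecord,
    DeckSpec,
    default_pharmacophore_model,
    gen_funnel_inputs,
    kmedoids,
    tanimoto_distance_matrix,
    fingerprint,
)


@pytest.fixture(scope="session")
def funnel():
    """One coherent synthetic screen mirroring the study funnel."""
    return gen_funnel_inputs(DeckSpec(seed=11))


@pytest.fixture(scope="session")
def funnel_clustering(funnel):
    """PAM clustering of the stage-2 survivors into 960 clusters."""
    from vstriage import Stage2Thresholds, stage2_filter

    members = set(funnel["pool_members"])
    pool_records = [r for r in funnel["records"] if r.id in members]
    verdicts = stage2_filter(pool_records)
    passed = {v.compound_id for v in verdicts if v.passed}
    survivors = [r for r in pool_records if r.id in passed]
    fps = [fingerprint(r, radius=4, nbits=2048) for r in survivors]
    D = tanimoto_distance_matrix(fps)
    clustering = kmedoids(D, 960, seed=17)
    clustering.ids = [r.id for r in survivors]
    return survivors, clustering


@pytest.fixture(scope="session")
def model():
    return default_pharmacophore_model()


@pytest.fixture
def rec():
    """Factory for quick compound records."""
    counter = iter(range(10**6))

    def make(smiles: str, cid: str | None = None, **extra) -> CompoundRecord:
        return CompoundRecord.from_smiles(cid or f"c{next(counter)}", smiles, **extra)

    return make


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric non-negative matrix with zero diagonal."""
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return D
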