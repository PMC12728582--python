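import numpy as np
import pandas as pd
import pytest

from rhizofun import AsvTable, FunctionMatrix, SampleMetadata, CANONICAL_FUNCTIONS


@pytest.fixture
def tiny_table() -> AsvTable:
    """3 ASVs x 2 samples with counts [[3,0],[0,5],[1,1]]."""
    counts = pd.DataFrame(
        [[3, 0], [0, 5], [1, 1]],
        index=["a1", "a2", "a3"],
        columns=["s1", "s2"],
    )
    return AsvTable(counts=counts, kingdom="bacteria")


@pytest.fixture
def random_function_matrix() -> FunctionMatrix:
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(10.0, 3.0, size=(9, 12)),
        index=[f"s{i}" for i in range(9)],
        columns=list(CANONICAL_FUNCTIONS),
    )
    return FunctionMatrix(values=values)


def random_asv_table(rng, n_asvs=50, n_samples=9, kingdom="bacteria", depth=2000,
                     with_taxonomy=True) -> AsvTable:
    logits = rng.normal(0, 1, size=(n_asvs, n_samples))
    counts = np.zeros((n_asvs, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = np.exp(logits[:, j])
        counts[:, j] = rng.multinomial(depth, p / p.sum())
    ids = [f"{kingdom[0].upper()}{i:03d}" for i in range(n_asvs)]
    tax = None
    if with_taxonomy:
        tax = {
            a: [f"d__{kingdom}", f"p__P{i % 3}", f"c__C{i % 3}", f"o__O{i % 4}",
                f"f__F{i // 8}", f"g__G{i // 4}"]
            for i, a in enumerate(ids)
        }
    return AsvTable(
        counts=pd.DataFrame(counts, index=ids, columns=[f"s{j}" for j in range(n_samples)]),
        kingdom=kingdom,
        taxonomy=tax,
    )


@pytest.fixture
def metadata_3x3() -> SampleMetadata:
    samples = [f"{t}.{r}" for t in ("CK", "SBSH", "SBSF") for r in (1, 2, 3)]
    return SampleMetadata(table=pd.DataFrame(
        {"treatment": [s.split(".")[0] for s in samples],
         "replicate": [int(s.split(".")[1]) for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    ))
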