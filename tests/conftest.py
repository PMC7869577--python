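import numpy as np
import pandas as pd
import pytest

from gseaconcord import (
    EnrichmentResult,
    ExpressionMatrix,
    PhenotypeTable,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 28-sample cohort at reduced gene/set scale with strong planted signal."""
    return generate_dataset(
        SimulationConfig(
            n_genes=300, n_sets=20, set_size_range=(5, 15), effect_size=2.0, seed=7
        )
    )


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples, hand-set values."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(0, 10, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_pheno():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "mitotic_rate": [1.0, 2.0, 5.0, 12.0, 30.0, 80.0],
                "ki67": [2.0, 4.0, 10.0, 20.0, 60.0, 95.0],
                "subtype": ["carcinoid"] * 4 + ["LCNEC"] * 2,
            },
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
        )
    )


def make_result(name, q, es=0.5, leading=(), size=10):
    """Build a minimal enrichment result for concordance-layer tests."""
    return EnrichmentResult(
        set_name=name,
        set_size_in_universe=size,
        es=es,
        peak_index=1,
        nominal_p=min(1.0, max(q, 1e-4)),
        fdr_q=q,
        nes=es * 2,
        leading_edge=tuple(leading),
    )


def make_result_lists(rng, n_sets=20, universe_size=50):
    """Random paired result lists over one collection, for set-algebra tests."""
    genes = [f"g{i:03d}" for i in range(universe_size)]
    names = [f"S{i:02d}" for i in range(n_sets)]
    out = []
    for _ in range(2):
        results = []
        for name in names:
            le = tuple(
                sorted(rng.choice(genes, size=rng.integers(0, 10), replace=False))
            )
            results.append(
                make_result(
                    name,
                    q=float(rng.uniform(0, 1)),
                    es=float(rng.uniform(-1, 1)),
                    leading=le,
                )
            )
        out.append(results)
    return out[0], out[1]
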