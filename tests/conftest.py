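import numpy as np
import pytest

from gannet.classifiers import make_split
from gannet.pipeline import prepare
from gannet.simulate import (
    SimSpec,
    make_table1_fixtures,
    paper_like_spec,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def table1_rows():
    return make_table1_fixtures()


@pytest.fixture(scope="session")
def paper_like():
    """One paper-scale simulated dataset (262 samples, 92 SNPs, 2% missing)."""
    dataset, truth = simulate_genotypes(paper_like_spec(11))
    return dataset, truth


@pytest.fixture(scope="session")
def paper_like_complete():
    """Same conditions but no missing calls (for split-count checks)."""
    dataset, truth = simulate_genotypes(paper_like_spec(11, missing_rate=0.0))
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_prepared():
    """Small prepared dataset for fast model-level tests.

    200 samples, 20 SNPs, 3 strong causal markers, no missingness.
    """
    rng = np.random.default_rng(5)
    control_raf = rng.uniform(0.2, 0.8, size=20)
    causal_or = np.ones(20)
    causal_or[[2, 7, 12]] = 3.0
    spec = SimSpec(n_snps=20, n_cases=100, n_controls=100,
                   control_raf=control_raf, causal_or=causal_or,
                   missing_rate=0.0, seed=5)
    dataset, truth = simulate_genotypes(spec)
    prep = prepare(dataset, skip_qc=True)
    split = make_split(prep.dataset, seed=5)
    return prep, truth, split
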