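import numpy as np
import pandas as pd
import pytest

from chronoreg import SyntheticConfig, simulate_expression_pair
from chronoreg.expression import ExpressionSet


def make_expression(values, days, genotype="genoA", tissue="apex", units="counts"):
    """ExpressionSet from a genes x observations array and per-column days."""
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    reps = {}
    cols, meta = [], []
    for d in days:
        reps[d] = reps.get(d, 0) + 1
        name = f"{genotype}_{tissue}_day{d:g}_rep{reps[d]}"
        cols.append(name)
        meta.append((name, genotype, tissue, float(d), reps[d]))
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = pd.DataFrame(
        meta, columns=["sample", "genotype", "tissue", "day", "replicate"]
    ).set_index("sample")
    return ExpressionSet(pd.DataFrame(values, index=genes, columns=cols),
                         samples, units=units)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small noise-free cohort: every gene's (stretch, shift) is recoverable."""
    cfg = SyntheticConfig(n_genes=40, noise_sd=0.0, count_dispersion=0.0,
                          contamination_fraction=0.0, seed=11)
    return simulate_expression_pair(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort at the default replicate noise with contamination."""
    cfg = SyntheticConfig(n_genes=120, noise_sd=0.2, count_dispersion=0.0,
                          contamination_fraction=0.35, seed=5)
    return simulate_expression_pair(cfg)
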