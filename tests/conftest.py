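import numpy as np
import pandas as pd
import pytest

from lncage import ExpressionMatrix, generate_study, scaled_study_config


def make_expression(log2_values: np.ndarray, gene_ids=None, sample_ids=None,
                    pseudocount: float = 1.0) -> ExpressionMatrix:
    """Build an ExpressionMatrix directly from a log2 value array."""
    log2_values = np.asarray(log2_values, dtype=float)
    n_g, n_s = log2_values.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_g)]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{j}" for j in range(n_s)]
    log2 = pd.DataFrame(log2_values, index=gene_ids, columns=sample_ids)
    fpkm = (2.0 ** log2) - pseudocount
    fpkm[fpkm < 0] = 0.0
    return ExpressionMatrix(log2=log2, fpkm=fpkm,
                            detectable=pd.Series(True, index=gene_ids),
                            pseudocount=pseudocount)


def make_meta(tissues, ages, n_replicates) -> pd.DataFrame:
    rows = [(f"{t}_{a:03d}w_r{r}", t, a, r)
            for t in tissues for a in ages for r in range(1, n_replicates + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "age_weeks",
                                       "replicate"])


@pytest.fixture(scope="session")
def small_study():
    """A compact 2-tissue study reused by unit tests (no module planting)."""
    cfg = scaled_study_config(n_tissues=2, n_genes=600, seed=11,
                              n_tissue_specific=60, n_aging_up=30,
                              n_aging_down=30, module_specs=())
    return cfg, generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default scaled study with one planted module (3 tissues)."""
    cfg = scaled_study_config(seed=7)
    return cfg, generate_study(cfg)
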