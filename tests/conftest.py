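import numpy as np
import pandas as pd
import pytest

from ensembletx import CohortConfig, generate_cohort
from ensembletx.data import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with clear signal, shared across tests."""
    config = CohortConfig(n_train=90, n_test=30, n_asd=64, n_td=56,
                          n_genes=300, n_de_genes=50,
                          effect_size_full=1.5, effect_size_attenuated=0.5,
                          seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_gene_data(small_cohort):
    """Preprocessed gene-level training arrays from the small cohort."""
    from ensembletx.preprocess import preprocess_pipeline
    from ensembletx.data import labels_from_phenotype

    processed, _ = preprocess_pipeline(small_cohort.expression)
    pheno = small_cohort.phenotype
    train_ids = pheno.loc[pheno["split"] == "train", "sample_id"].to_numpy()
    test_ids = pheno.loc[pheno["split"] == "test", "sample_id"].to_numpy()
    return {
        "matrix": processed.values,
        "x_train": processed.values[train_ids].to_numpy().T,
        "x_test": processed.values[test_ids].to_numpy().T,
        "y_train": labels_from_phenotype(pheno, train_ids),
        "y_test": labels_from_phenotype(pheno, test_ids),
        "train_ids": train_ids,
        "test_ids": test_ids,
        "gene_names": processed.values.index.to_numpy(),
        "truth": small_cohort.truth,
        "phenotype": pheno,
    }


def make_expression(values, detection=None, genes=None, probes=None, samples=None):
    """Small helper to build an ExpressionMatrix from plain arrays."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = probes or [f"p{i}" for i in range(n_probes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    genes = genes or [f"g{i}" for i in range(n_probes)]
    frame = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                         columns=samples)
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=float),
                           index=frame.index, columns=samples)
    return ExpressionMatrix(values=frame, detection_p=det,
                            gene_ids=pd.Series(genes, index=frame.index))
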