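import warnings

import numpy as np
import pandas as pd
import pytest

import triadnet as tn


@pytest.fixture(scope="session")
def easy_dataset() -> tn.SynthDataset:
    """Default 'easy' synthetic design: 500 genes, 4 modules, 40 samples."""
    return tn.generate_dataset(seed=11)


@pytest.fixture(scope="session")
def fitted(easy_dataset):
    """Full preprocess + network fit on the easy dataset."""
    ds = easy_dataset
    filt = tn.preprocess.filter_expressed(ds.tpm, ds.samples.samples_of("meiotic_anther"))
    kept = ds.counts.subset_genes(filt.kept_gene_ids)
    normed = tn.preprocess.normalize(kept, tn.preprocess.size_factors(kept))
    model = tn.CoexpressionNetwork(normed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return ds, res


def expr_from_array(values, genes=None, samples=None, unit="normalized"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return tn.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)
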