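import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from ampscape.spatial import SECTION_ID_KEY, SPATIAL_KEY


def make_section(X, coords, genes, section_id="test"):
    """Assemble a spatial section AnnData from arrays."""
    X = np.asarray(X, dtype=float)
    section = AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"spot{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    section.obsm[SPATIAL_KEY] = np.asarray(coords, dtype=float)
    section.uns[SECTION_ID_KEY] = section_id
    return section


@pytest.fixture
def worked_section():
    """Four spots; anchor high at the origin, test gene high one unit away."""
    return make_section(
        X=np.array([[4.0, 1.0], [1.0, 4.0], [1.0, 1.0], [1.0, 1.0]]),
        coords=[(0, 0), (1, 0), (0, 1), (10, 10)],
        genes=["ANCHOR", "TEST"],
    )


@pytest.fixture
def small_cohort():
    """Hand-built alteration table: 2 sites, 3 histologies, 10 patients."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(10)],
            "site": ["ovary"] * 6 + ["uterus"] * 4,
            "histology": ["HGSOC"] * 4 + ["CCOC"] * 2 + ["UCS"] * 4,
            "sample_type": ["primary"] * 5 + ["metastatic"] * 5,
            "cn_CCNE1": [2, 2, 0, 1, 2, 0, 2, -2, 0, 0],
            "cn_MYC": [2, 0, 0, 0, 2, 0, 0, 0, 2, 0],
            "mut_TP53": [True, True, False, False, True, False, True,
                         False, False, False],
        }
    )


def make_cells(counts, sample="S1", cell_type="epithelial", genes=None):
    """Assemble a cell matrix AnnData with complete QC metadata."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes if genes is not None else [f"g{j}" for j in range(g)]
    samples = [sample] * n if isinstance(sample, str) else list(sample)
    types = [cell_type] * n if isinstance(cell_type, str) else list(cell_type)
    obs = pd.DataFrame(
        {
            "sample": samples,
            "cell_type": types,
            "n_genes_detected": (counts > 0).sum(axis=1),
            "pct_mito": np.zeros(n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    return AnnData(
        X=counts.astype(float),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
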