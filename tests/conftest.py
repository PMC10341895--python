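import numpy as np
import pandas as pd
import pytest

from mixdecon.core import ExpressionMatrix, ProportionMatrix, SignatureMatrix
from mixdecon.simulate import MixtureDesign, SignatureDesign, make_dataset

FIVE_TYPES = ("A", "B", "C", "D", "E")


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, spillover-free mixture: c=5, n=500 genes, m=12 samples."""
    return make_dataset(
        SignatureDesign(n_genes=500, cell_types=FIVE_TYPES, markers_per_type=10, seed=3),
        MixtureDesign(n_samples=12, proportion_mode="dirichlet", noise_cv=0.0, seed=7),
    )


@pytest.fixture(scope="session")
def tumor_dataset():
    """12-sample cancer/immune design with two pure-cancer samples, noiseless."""
    return make_dataset(
        SignatureDesign(seed=3),
        MixtureDesign(proportion_mode="gse64385_like", noise_cv=0.0, seed=7),
    )


@pytest.fixture(scope="session")
def planted_marker_dataset():
    """c=3 types, 5 markers each, 300 genes, noiseless: marker truth recoverable."""
    return make_dataset(
        SignatureDesign(n_genes=300, cell_types=("X", "Y", "Z"), markers_per_type=5, seed=11),
        MixtureDesign(n_samples=9, proportion_mode="dirichlet", noise_cv=0.0, seed=13),
    )


@pytest.fixture
def toy_signature():
    return SignatureMatrix(
        pd.DataFrame([[2.0, 1.0], [1.0, 3.0]], index=["g1", "g2"], columns=["t1", "t2"])
    )


def expression_from(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(np.asarray(values, float), index=genes, columns=samples))


def proportions_from(values, types, samples, mode="strict"):
    return ProportionMatrix(
        pd.DataFrame(np.asarray(values, float), index=types, columns=samples), mode=mode
    )
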