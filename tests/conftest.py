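import numpy as np
import pandas as pd
import pytest

from bonescore.cohort import default_config, generate_annulus_mask, generate_cohort
from bonescore.variables import TRABECULAR, TRABECULAR_VARIABLES


@pytest.fixture(scope="session")
def two_model_cohort():
    """Two models x two genotypes, trabecular only, default trisomic deficit."""
    cfg = default_config(
        n_per_group=12,
        factors={"model": ("Ts65Dn", "Ts66Yah"),
                 "genotype": ("euploid", "trisomic")},
        compartments=(TRABECULAR,),
    )
    return generate_cohort(cfg, seed=20)


@pytest.fixture(scope="session")
def annulus_mask():
    """Circular annulus, outer 1.0 mm / inner 0.5 mm at 10 um pixels."""
    return generate_annulus_mask(1.0, 0.5, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_z_table(rng):
    """A small standardized-looking table for PCA unit tests."""
    z = rng.normal(size=(6, 5))
    z -= z.mean(axis=0)
    return pd.DataFrame(z, columns=list(TRABECULAR_VARIABLES))
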