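"""Shared fixtures: small synthetic PLINK filesets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from basilnet import MISSING, SimulationSpec, open_store, simulate_genotypes, write_plink_fixture


@pytest.fixture(scope="session")
def tiny_dosages():
    """4 samples x 2 variants with one missing entry, hand-written."""
    return np.array(
        [[0, 1],
         [2, 1],
         [MISSING, 0],
         [0, 2]], dtype=np.uint8
    )


@pytest.fixture(scope="session")
def tiny_store(tiny_dosages, tmp_path_factory):
    prefix = tmp_path_factory.mktemp("tiny") / "tiny"
    bed, bim, fam = write_plink_fixture(tiny_dosages, prefix)
    return open_store(bed, bim, fam)


@pytest.fixture(scope="session")
def random_fixture(tmp_path_factory):
    """200 samples x 50 variants with ~5% missingness, plus its source matrix."""
    spec = SimulationSpec(
        n_samples=200, n_variants=50, missing_rate=0.05,
        maf_low=0.05, maf_high=0.5, n_causal=5, seed=123,
    )
    dosages, mafs = simulate_genotypes(spec)
    prefix = tmp_path_factory.mktemp("rand") / "rand"
    bed, bim, fam = write_plink_fixture(dosages, prefix)
    store = open_store(bed, bim, fam)
    return store, dosages, mafs


def imputed_dense(dosages: np.ndarray) -> np.ndarray:
    """Reference mean imputation used as the oracle in kernel tests."""
    X = dosages.astype(float)
    X[dosages == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.nonzero(np.isnan(X))
    X[idx] = mu[idx[1]]
    return X
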