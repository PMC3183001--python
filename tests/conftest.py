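"""Shared fixtures: small synthetic datasets sized for fast tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import msiagree as ma


def make_reduced(matrix, normalization="none", dataset_id="test",
                 grid_cols=None):
    """Wrap an arbitrary non-negative matrix as a ReducedDataset on a
    rectangular grid (row-major pixel order)."""
    matrix = np.asarray(matrix, dtype=float)
    n, f = matrix.shape
    cols = grid_cols or int(np.ceil(np.sqrt(n)))
    pixels = np.array([(i % cols, i // cols) for i in range(n)])
    features = [(2000.0 + 100.0 * j, 500.0) for j in range(f)]
    return ma.ReducedDataset(pixels=pixels, features=features, matrix=matrix,
                             normalization=normalization,
                             dataset_id=dataset_id)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the pipeline's informational warnings (zero-variance images,
    ridge regularization); tests that assert on warnings use pytest.warns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_spec():
    """Two-nodule phantom small enough for repeated full-pipeline runs."""
    return ma.default_nodule_spec(7, n_features=60, n_regions=2,
                                  grid_shape=(24, 32))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return ma.generate_reduced_phantom(small_spec, n_features=60)


@pytest.fixture(scope="session")
def small_agreement(small_phantom):
    """One shared full agreement run (plots + fitted components)."""
    reduced, truth = small_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        norm, _ = ma.tic_normalize(reduced)
        plots, components = ma.run_agreement(
            norm, ma.AgreementConfig(seed=7))
    return norm, truth, plots, components
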