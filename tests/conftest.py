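"""Shared fixtures: a small synthetic compendium, scored once per session."""

from __future__ import annotations

import numpy as np
import pytest

import infosig as isg

SMALL_SEED = 7


@pytest.fixture(scope="session")
def small_spec() -> isg.SyntheticSpec:
    """Small factor-model compendium used by most integration tests."""
    return isg.SyntheticSpec(
        n_datasets=3,
        n_genes=600,
        n_samples=60,
        n_planted_modules=5,
        module_size=30,
        n_conserved=3,
        n_redundant_pairs=2,
        n_background_signatures=20,
        seed=SMALL_SEED,
    )


@pytest.fixture(scope="session")
def small_compendium(small_spec):
    return isg.generate_compendium(small_spec)


@pytest.fixture(scope="session")
def scored_results(small_compendium):
    datasets, collection, _ = small_compendium
    cfg = isg.ActivityConfig(n_draws=300, seed=SMALL_SEED)
    results = []
    for ds in datasets:
        results.extend(isg.score_collection(collection, ds, cfg))
    return results


@pytest.fixture
def tiny_ds() -> isg.ExpressionDataset:
    """Deterministic 6-gene x 10-sample dataset for exact-value checks."""
    rng = np.random.default_rng(42)
    return isg.ExpressionDataset(
        dataset_id="TINY",
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(10)],
        values=rng.normal(size=(6, 10)),
    )


@pytest.fixture
def three_sig_collection() -> isg.SignatureCollection:
    return isg.SignatureCollection(
        [
            isg.GeneSignature("S1", "catA", ("g0", "g1", "g2")),
            isg.GeneSignature("S2", "catB", ("g2", "g3")),
            isg.GeneSignature("S3", "catA", ("g4", "g5", "g0")),
        ]
    )
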