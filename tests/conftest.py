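"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hybridase.simulate import (
    SimConfig,
    simulate_counts,
    simulate_genes,
    simulate_reference,
    simulate_truth,
)


@pytest.fixture(scope="session")
def default_sim():
    """Count-level simulation under the default study conditions."""
    return simulate_counts(SimConfig(seed=11))


@pytest.fixture(scope="session")
def reads_bundle(tmp_path_factory):
    """A small read-level dataset: reference, SNPs, genes, truth, SAM paths."""
    from hybridase.simulate import simulate_alignments

    config = SimConfig(
        seed=7,
        n_genes=30,
        chrom_length=40_000,
        depth=8_000,
        crosses=("BC",),
        n_wt_male=1,
        n_ko_male=1,
        n_wt_female=0,
        error_rate=0.0,
        duplicate_rate=0.0,
    )
    reference, snps = simulate_reference(config)
    genes = simulate_genes(config, reference)
    truth = simulate_truth(config, genes)
    out = tmp_path_factory.mktemp("reads")
    paths = simulate_alignments(config, reference, snps, genes, truth, out)
    return {
        "config": config,
        "reference": reference,
        "snps": snps,
        "genes": genes,
        "truth": truth,
        "sam_paths": paths,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
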