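"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

import eqtl_atlas as ea


@pytest.fixture(scope="session")
def small_cfg():
    """A compact study: 120 strains, 150 transcripts, 720 markers."""
    return ea.SimConfig(
        n_strains=120,
        n_transcripts=150,
        markers_per_chrom=120,
        n_local_eqtl=20,
        n_distant_eqtl=20,
        hotspot_spec=(60, 25, 1.0),
        divergent_frac=0.05,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return ea.simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """Full pipeline fit of the small study (shared across tests)."""
    return ea.EQTLStudy.from_simulation(small_study).fit(min_strains_retained=60)


@pytest.fixture(scope="session")
def pruned_panel():
    """Filtered+pruned genotypes with kinship, for mixed-model tests."""
    cfg = ea.SimConfig(
        n_strains=150,
        n_transcripts=1,
        markers_per_chrom=150,
        n_local_eqtl=0,
        n_distant_eqtl=0,
        hotspot_spec=(0, 0, 1.0),
        seed=11,
    )
    G = ea.ld_prune(ea.filter_markers(ea.sim_genotypes(cfg)))
    K = ea.kinship(G)
    return G, K


def random_expression(rng, n_strains=10, reps=2, n_transcripts=30, prefix="S"):
    """Replicate-level positive expression matrix with tight replicates."""
    base = rng.uniform(20, 400, size=(n_transcripts, n_strains))
    samples, cols = [], []
    for i in range(n_strains):
        for r in range(reps):
            cols.append(base[:, i] * rng.normal(1.0, 0.02, n_transcripts))
            samples.append((f"{prefix}{i}_r{r + 1}", f"{prefix}{i}", r + 1))
    return ea.ExpressionMatrix(
        np.array([f"T{j:03d}" for j in range(n_transcripts)], dtype=object),
        pd.DataFrame(samples, columns=["sample", "strain", "replicate"]),
        np.column_stack(cols),
    )
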