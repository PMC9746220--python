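import numpy as np
import pandas as pd
import pytest

from protmr import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """Four 5-variant LD blocks, n=500, moderate LD."""
    return sim.simulate_genotypes(
        500, [(5, 0.6, (0.1, 0.4)) for _ in range(4)], seed=11
    )


@pytest.fixture(scope="session")
def causal_study():
    """A study with one causal protein (theta=0.3) and three nulls."""
    panel = sim.simulate_genotypes(
        2000, [(10, 0.6, (0.1, 0.4)) for _ in range(4)], seed=21
    )
    manifest = sim.design_truth(
        panel, 4, {"Y1": {"P001": 0.3}}, b_cis=0.5, seed=22
    )
    proteins = sim.simulate_proteins(panel, manifest, noise_sd=1.0, seed=23)
    gwas = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=24)
    return panel, manifest, proteins, gwas


def make_sumstats(rows):
    """Build a summary-stats frame from (variant_id, chrom, pos, ea, nea,
    eaf, beta, se) tuples; pval/n filled with placeholders."""
    df = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ea", "nea", "eaf", "beta", "se"]
    )
    df["pval"] = 0.5
    df["n"] = 1000
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
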