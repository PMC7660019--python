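import numpy as np
import pandas as pd
import pytest

import admixkit as ak


def make_matrix(derived, ploidy, samples=None, chrom="c01"):
    """Build a GenotypeMatrix from plain per-sample x per-site arrays."""
    derived = np.asarray(derived, dtype=np.int16)
    ploidy = np.asarray(ploidy, dtype=np.int8)
    n_s, n_v = derived.shape
    samples = samples or [f"S{i}" for i in range(n_s)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_v + 1),
            "ref": "A",
            "alt": "C",
            "id": [f"v{j}" for j in range(n_v)],
        }
    )
    return ak.GenotypeMatrix(variants, samples, derived, ploidy)


def make_freq(pop_freqs, n=1000, chrom="c01"):
    """FreqTable with exact frequencies p = d/n for each population.

    ``pop_freqs`` maps population -> array of frequencies; every entry must
    be a multiple of 1/n.
    """
    pops = list(pop_freqs)
    p = np.stack([np.asarray(pop_freqs[q], dtype=float) for q in pops])
    d = np.rint(p * n).astype(np.int64)
    assert np.allclose(d / n, p), "frequencies must be multiples of 1/n"
    n_sites = p.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "C",
            "id": [f"v{j}" for j in range(n_sites)],
        }
    )
    return ak.FreqTable(pops, variants, d, np.full_like(d, n))


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated scenario-1 dataset shared across tests."""
    cfg = ak.default_scenario_config(1, seed=7, n_sites=8000)
    g, panel, freqs = ak.simulate_dataset(cfg)
    freq = ak.population_counts(g, panel)
    blocks = ak.assign_blocks(g.variants, 100)
    return {"g": g, "panel": panel, "freq": freq, "blocks": blocks, "truth": freqs}
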