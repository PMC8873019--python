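import numpy as np
import pandas as pd
import pytest

from cnvomics import simulate


@pytest.fixture(scope="session")
def design():
    return simulate.generate_design()


@pytest.fixture(scope="session")
def rna_1m(design):
    return (design[(design["assay"] == "rna")
                   & (design["timepoint"] == "org1M")]
            .reset_index(drop=True))


@pytest.fixture(scope="session")
def annotations():
    return simulate.generate_annotations(600, 29, 3, seed=1, module_size=60,
                                         n_markers_per_type=30)


@pytest.fixture(scope="session")
def small_counts(design, annotations):
    truth = simulate.SimTruth(seed=1)
    counts, tpm = simulate.simulate_rnaseq(design, annotations, truth)
    return counts, tpm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_block_expression(n_blocks=3, block_size=100, n_noise=200,
                          n_samples=40, intra_cor=0.7, seed=3,
                          hub_range=None):
    """Planted-module expression: each block driven by one latent factor.

    ``hub_range=(lo, hi)`` draws per-gene loadings in that range (hub
    structure); by default all members load equally.
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blocks):
        f = rng.normal(0, 1, n_samples)
        lam = np.sqrt(intra_cor) * (
            rng.uniform(*hub_range, block_size) if hub_range
            else np.ones(block_size))
        X = (lam[:, None] * f
             + np.sqrt(1 - lam ** 2)[:, None] * rng.normal(0, 1, (block_size, n_samples)))
        rows.append(X)
        truth += [f"B{b}"] * block_size
    rows.append(rng.normal(0, 1, (n_noise, n_samples)))
    truth += ["noise"] * n_noise
    expr = pd.DataFrame(np.vstack(rows),
                        index=[f"g{i}" for i in range(len(truth))])
    return expr, np.array(truth)
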