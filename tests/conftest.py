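import numpy as np
import pandas as pd
import pytest

from dmrkit import simulate as sim


@pytest.fixture(scope="session")
def toy_genome():
    return sim.generate_toy_genome(2, 500_000, 40, 60, seed=7, spare_last_chrom=True)


@pytest.fixture(scope="session")
def nb_null_counts():
    """Null NB counts (no group effect), 4 vs 5 samples, known dispersion 0.15."""
    rng = np.random.default_rng(42)
    phi, n_rows = 0.15, 1200
    cols = [f"CTRL_{i}" for i in range(5)] + [f"PILO_{i}" for i in range(4)]
    mu = rng.lognormal(np.log(60), 0.6, n_rows)
    lam = rng.gamma(1 / phi, np.outer(mu, np.ones(len(cols))) * phi)
    counts = pd.DataFrame(rng.poisson(lam), columns=cols)
    groups = pd.Series({c: c.split("_")[0] for c in cols}, name="group")
    return counts, groups, phi
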