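import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_landscape():
    """A 160x160 synthetic landscape shared across tests (read-only)."""
    from caribou_rsf.synthetic import SyntheticConfig, generate_landscape

    cfg = SyntheticConfig(grid_nrows=160, grid_ncols=160, seed=11)
    return generate_landscape(cfg)


@pytest.fixture()
def toy_strata():
    """Builder for matched-strata choice data with known beta."""

    def build(beta: float = 0.8, n_strata: int = 20, size: int = 6, seed: int = 7,
              n_covs: int = 1):
        rng = np.random.default_rng(seed)
        rows = []
        b = np.full(n_covs, beta) if np.isscalar(beta) else np.asarray(beta, float)
        for s in range(n_strata):
            X = rng.normal(size=(size, n_covs))
            p = np.exp(X @ b)
            p /= p.sum()
            u = rng.choice(size, p=p)
            for j in range(size):
                row = {"stratum_id": s, "used": int(j == u),
                       "animal_id": "A0",
                       "timestamp": pd.Timestamp("2006-06-01", tz="UTC") + pd.Timedelta(hours=2 * s)}
                for c in range(n_covs):
                    row[f"x{c}"] = X[j, c]
                rows.append(row)
        return pd.DataFrame(rows)

    return build
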