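import numpy as np
import pandas as pd
import pytest

from vocalphen import synthetic


@pytest.fixture(scope="session")
def community_config():
    return synthetic.make_paper_like_community(seed=11)


@pytest.fixture(scope="session")
def community_study(community_config):
    """Full-size synthetic season (30 sites/stratum, 6 species)."""
    return synthetic.simulate_study(community_config)


@pytest.fixture(scope="session")
def small_study():
    """A fast three-species study for plumbing-level tests."""
    cfg = synthetic.make_paper_like_community(seed=3)
    cfg.species = cfg.species[:3]
    cfg.n_sites_per_stratum = 8
    cfg.seed = 3
    return synthetic.simulate_study(cfg)


def make_cell(rates_by_site, days, n_segments=2800, seed=0,
              species="SPEC", stratum="Low"):
    """Binomial activity cell from per-site daily probability arrays."""
    rng = np.random.default_rng(seed)
    frames = []
    for site, p in rates_by_site.items():
        k = rng.binomial(n_segments, p)
        frames.append(
            pd.DataFrame({"species_code": species, "site_id": site, "stratum": stratum,
                          "day": days, "k_labels": k, "n_segments": n_segments})
        )
    return pd.concat(frames, ignore_index=True)
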