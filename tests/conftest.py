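import dendropy
import numpy as np
import pandas as pd
import pytest

from phylotrends.synthetic import ScenarioConfig, generate_dataset, simulate_yule_tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def hand_tree():
    """Four-tip tree with hand-computed patristic distances.

    A-B = 3.0, C-D = 2.0, A-C = 4.0, A-D = 3.0, B-C = 5.0, B-D = 4.0;
    root-to-tip depths: A 1.5, B 2.5, C 2.5, D 1.5.
    """
    return tree_from_newick("((A:1.0,B:2.0):0.5,(C:1.5,D:0.5):1.0);")


@pytest.fixture
def cherry_tree():
    return tree_from_newick("(A:1.0,B:2.0);")


@pytest.fixture
def star_tree():
    return tree_from_newick("(A:1.0,B:1.0,C:1.0,D:1.0);")


@pytest.fixture(scope="session")
def yule20():
    return simulate_yule_tree(20, 1.0, 2024)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale survey with every contamination rule planted."""
    cfg = ScenarioConfig(
        n_species=60,
        site_grid=[(-40.0, -60.0), (-10.0, 20.0), (10.0, 100.0), (45.0, -100.0), (60.0, 140.0)],
        year_range=(2010, 2019),
        richness_distribution=(10, 18),
        seed=99,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def trend_frame():
    """Independent-noise trend frame with a known linear signal."""
    rng = np.random.default_rng(11)
    n = 120
    df = pd.DataFrame(
        {
            "lat_2dp": rng.uniform(-60, 60, n).round(2),
            "lon_2dp": rng.uniform(-170, 170, n).round(2),
            "year": rng.integers(2000, 2020, n),
            "degenerate": False,
            "obs_mpd": 0.0,
        }
    )
    df["z"] = (
        -0.3
        + 0.02 * df["lat_2dp"].abs()
        + 0.4 * ((df["year"] - df["year"].mean()) / df["year"].std(ddof=0))
        + rng.normal(0, 0.8, n)
    )
    return df
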