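import logging

import numpy as np
import pandas as pd
import pytest

from dieltrait.simulate import SyntheticWorldConfig, generate_tree, generate_world

logging.getLogger("dieltrait").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_world():
    """250-species world with the default (study-condition) parameters."""
    return generate_world(SyntheticWorldConfig(n_species=250, seed=11))


@pytest.fixture(scope="session")
def tree200():
    return generate_tree(200, 1.0, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_csv(tmp_path):
    """Three-species CSV in the documented dialect, one missing litter size."""
    diet_cols = ",".join(f"diet_c{i}" for i in range(1, 11))
    diet_a = ",".join(["5"] * 10)
    diet_b = ",".join(["0"] * 5 + ["10"] * 5)
    diet_c = ",".join(["10"] * 5 + ["0"] * 5)
    text = (
        f"species_id,order,family,diel_niche,diel_flexible,body_mass_g,litter_size,"
        f"{diet_cols},foraging_stratum,habitat_breadth\n"
        f"sp_a,o1,f1,nocturnal,false,100,2,{diet_a},1,3\n"
        f"sp_b,o1,f2,diurnal,true,2500,,{diet_b},3,1\n"
        f"sp_c,o2,f3,cathemeral,false,40,4.5,{diet_c},2,7\n"
    )
    path = tmp_path / "toy.csv"
    path.write_text(text)
    return path


def trait_frame_of(world, **kwargs):
    from dieltrait.hypervolume import trait_frame

    return trait_frame(world.true_table, **kwargs)


@pytest.fixture(scope="session")
def complete_frame(small_world):
    """Standardised five-trait frame for the complete (true) table."""
    return trait_frame_of(small_world)


@pytest.fixture(scope="session")
def gaussian_scores():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((1000, 2))
    return pd.DataFrame(X, columns=["PC1", "PC2"],
                        index=[f"s{i}" for i in range(1000)])
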