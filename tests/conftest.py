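import numpy as np
import pandas as pd
import pytest

from panelomics import CrossDesign, PanelConfig, TraitTable, generate_panel, make_trait_meta

#: compact trait complement used throughout the suite to keep runs fast;
#: full-scale counts are a config change, not a code change
SMALL_COUNTS = {"phenotype": 3, "metabolite": 8, "enzyme": 8, "protein_spot": 15}


def small_config(seed: int = 0, **overrides) -> PanelConfig:
    kwargs = dict(
        n_traits_per_level=dict(SMALL_COUNTS),
        n_correlation_blocks=2,
        block_size=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return PanelConfig(**kwargs)


@pytest.fixture(scope="session")
def small_panel():
    """A seeded synthetic panel shared by read-only tests."""
    table, design, truth = generate_panel(small_config(seed=11))
    return table, design, truth


@pytest.fixture
def tiny_table():
    """Hand-built 3-genotype x 2-stage x 3-replicate table with two traits."""
    rng = np.random.default_rng(5)
    genotypes = ["Cervil", "Levovil", "H1"]
    stages = ["CE", "OR"]
    idx = pd.MultiIndex.from_product(
        [genotypes, stages, [1, 2, 3]], names=("genotype", "stage", "replicate"))
    base = {"Cervil": 4.0, "Levovil": 10.0, "H1": 7.0}
    rows = []
    for g, s, r in idx:
        shift = 2.0 if s == "OR" else 0.0
        rows.append([base[g] + shift + 0.1 * rng.standard_normal(),
                     5.0 + 0.1 * rng.standard_normal()])
    values = pd.DataFrame(rows, index=idx, columns=["glucose", "flat_trait"])
    meta = make_trait_meta(["glucose", "flat_trait"], ["metabolite", "metabolite"])
    return TraitTable(values, meta)


@pytest.fixture
def tiny_design():
    return CrossDesign([("H1", "Levovil", "Cervil")])
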