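import numpy as np
import pandas as pd
import pytest

from mgsquant.catalog import GeneCatalog, MgsDefinitionSet, Module, ModuleCatalog
from mgsquant.synthetic import SyntheticConfig, generate_catalog, generate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_mgs=8, genes_per_mgs=40, n_markers_per_mgs=10, core_fraction=0.5,
        n_modules=4, components_per_module=4, n_cases=12, n_controls=12,
        n_da_mgs=2, effect_log2fc=2.0, read_depth=4000, shared_read_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    catalog, defs, modules = generate_catalog(small_cfg)
    metadata, cells, truth = generate_cohort(small_cfg, catalog, defs, modules)
    return dict(cfg=small_cfg, catalog=catalog, defs=defs, modules=modules,
                metadata=metadata, cells=cells, truth=truth)


@pytest.fixture
def toy_catalog() -> GeneCatalog:
    """Hand-built two-MGS catalogue for exact-value tests."""
    rows = []
    for j in range(4):
        rows.append(("a_g%d" % j, 1000, "mgsA", j < 2, j < 3, frozenset({"K%d" % j})))
    for j in range(4):
        rows.append(("b_g%d" % j, 2000, "mgsB", j < 2, j < 3, frozenset()))
    table = pd.DataFrame(
        rows, columns=["gene_id", "length", "mgs_id", "is_marker", "is_core", "components"]
    ).set_index("gene_id")
    return GeneCatalog(table=table)


@pytest.fixture
def toy_defs(toy_catalog) -> MgsDefinitionSet:
    return MgsDefinitionSet.from_catalog(toy_catalog)


def make_module(module_id: str, *components) -> Module:
    return Module(module_id=module_id, name=module_id,
                  components=tuple(frozenset(c) for c in components))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
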