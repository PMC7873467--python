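import importlib.resources

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ceranet as cn

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def data_path(name: str):
    """Path to a packaged reference data file."""
    return importlib.resources.files("ceranet.data") / name


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 8 paired patients, planted 2-fold
    effects at noise 0.3, one hub and one disease-proximal lncRNA."""
    return cn.generate_dataset(cn.SyntheticConfig(rng_seed=0))


@pytest.fixture(scope="session")
def de_results(default_dataset):
    expr = default_dataset.expression
    return {c: cn.paired_moderated_test(expr, c) for c in ("mrna", "lncrna", "mirna")}


@pytest.fixture(scope="session")
def significant_features(de_results):
    return {c: r.index[r["significant"]].tolist() for c, r in de_results.items()}


@pytest.fixture(scope="session")
def cerna_builder(default_dataset, significant_features):
    sig = significant_features
    return cn.CeRNANetworkBuilder().fit(
        default_dataset.interactions, sig["mirna"], sig["mrna"], sig["lncrna"]
    )


@pytest.fixture(scope="session")
def cerna_network(cerna_builder):
    return cerna_builder.network_


@pytest.fixture(scope="session")
def reference_rankings():
    """Published top-ten centrality rankings (one list per metric)."""
    df = pd.read_csv(data_path("endometriosis_top10_centrality.tsv"), sep="\t", comment="#")
    return {m: df[m].tolist() for m in ("degree", "betweenness", "closeness")}


@pytest.fixture(scope="session")
def reference_interactions():
    """Curated lncRNA-miRNA interaction table for three endometriosis
    lncRNAs."""
    return cn.read_interactions(data_path("endometriosis_lncrna_mirna_interactions.tsv"))
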