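import pytest

from cocom.growth import LVParams, solve_lv
from cocom.simulate import SimScenario, default_times, simulate_dataset


@pytest.fixture(scope="session")
def times():
    return default_times()


@pytest.fixture(scope="session")
def lv_antagonistic():
    """Mutually inhibitory two-species system on a realistic abundance scale."""
    return LVParams(r_e=1.0, K_e=8e8, alpha_es=0.4, r_s=0.8, K_s=5e8, alpha_se=0.3)


@pytest.fixture(scope="session")
def solved_pair(lv_antagonistic, times):
    return solve_lv(lv_antagonistic, 5e3, 5e3, times)


@pytest.fixture(scope="session")
def null_co_dataset():
    """Null (no causal marker) co-culture dataset, 45 pairs, small panels."""
    sc = SimScenario(treatment="co", h2=0.0, n_markers_a=8, n_markers_b=8, seed=1234)
    return sc, simulate_dataset(sc)


@pytest.fixture(scope="session")
def causal_co_dataset():
    """Causal co-culture dataset at h2 = 0.1 with 100 pairs."""
    sc = SimScenario(treatment="co", h2=0.1, n_pairs=100, n_markers_a=6,
                     n_markers_b=6, causal_a=3, causal_b=3, seed=77)
    return sc, simulate_dataset(sc)


def pair_panels(ds):
    """Panels with rows reordered to pair order (helper used across tests)."""
    from cocom.static_mapping import GenotypePanel

    pa = GenotypePanel(ds.panel_a.markers, ds.genotype_rows("a"),
                       ds.strain_order("a"), ds.panel_a.species_tag)
    pb = GenotypePanel(ds.panel_b.markers, ds.genotype_rows("b"),
                       ds.strain_order("b"), ds.panel_b.species_tag)
    return pa, pb
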