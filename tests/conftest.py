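import numpy as np
import pytest

from ventpop import synthdata


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down three-species study with the default demography."""
    cfg = synthdata.StudyConfig(
        sample_sizes=(12, 10, 6),
        n_rad_loci=200,
        n_codon_genes=2,
        codon_gene_len=60,
        missing_rate=0.02,
        genotyping_error_rate=0.002,
        seed=5,
    )
    return synthdata.make_study(cfg)


@pytest.fixture(scope="session")
def clean_study():
    """Like small_study but without missingness or genotyping error."""
    cfg = synthdata.StudyConfig(
        sample_sizes=(10, 10, 6),
        n_rad_loci=150,
        n_codon_genes=1,
        codon_gene_len=40,
        missing_rate=0.0,
        genotyping_error_rate=0.0,
        seed=7,
    )
    return synthdata.make_study(cfg)


@pytest.fixture(scope="session")
def isolated_study():
    """Strict-isolation variant: no gene flow, deep splits (full lineage
    sorting expected)."""
    from dataclasses import replace

    older, sister = synthdata.default_scenarios()
    scenarios = (
        replace(older, scenario="SI", M12=0.0, M21=0.0),
        replace(sister, scenario="SI", M12=0.0, M21=0.0),
    )
    cfg = synthdata.StudyConfig(
        sample_sizes=(12, 10, 6),
        n_rad_loci=150,
        n_codon_genes=1,
        codon_gene_len=40,
        missing_rate=0.0,
        genotyping_error_rate=0.0,
        demographic_scenarios=scenarios,
        seed=9,
    )
    return synthdata.make_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
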