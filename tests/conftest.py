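import pytest

from nitrosyn import CommunityConfig, RunConfig, generate_community, run_binning_pipeline


@pytest.fixture(scope="session")
def default_community():
    """One draw of the default 8-genome, 3-timepoint community."""
    cfg = CommunityConfig(seed=2)
    contigs, cov, links = generate_community(cfg)
    return cfg, contigs, cov, links


@pytest.fixture(scope="session")
def binning_report():
    """Full binning pipeline report on the default community."""
    return run_binning_pipeline(RunConfig(seed=11))
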