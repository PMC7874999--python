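import pytest

from comparome.synthdata import (
    introgression_benchmark_config,
    simulate,
    sv_benchmark_config,
    ty_benchmark_config,
)


@pytest.fixture(scope="session")
def sv_fixture():
    """Six-strain SV benchmark panel (base + five derived strains, one
    planted event of each of the five types per derived strain)."""
    return simulate(sv_benchmark_config(1))


@pytest.fixture(scope="session")
def ty_fixture():
    """Three strains, each planted with solo LTRs and complete/truncated
    elements in all viability states."""
    return simulate(ty_benchmark_config(1))


@pytest.fixture(scope="session")
def intro_fixture():
    """Three focal + three non-focal strains with three ORFs introgressed
    at 8% divergence."""
    return simulate(introgression_benchmark_config(1))
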