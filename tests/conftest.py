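import pytest

from methdiv import dmr as dmr_mod
from methdiv import evaluation as ev
from methdiv.synth import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic two-cultivar cohort (1 chromosome, 1 Mb, 200
    planted whole-bin DMRs at delta 40, mean depth 30)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    return ev.build_calls(default_cohort)


@pytest.fixture(scope="session")
def default_recovery(default_cohort, default_calls):
    return ev.dmr_recovery(default_cohort, default_calls)


@pytest.fixture(scope="session")
def default_assoc(default_cohort, default_recovery):
    return dmr_mod.associate_dmrs(default_recovery["dmrs"],
                                  default_cohort.genome.genes,
                                  default_cohort.genome.tes)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural tests."""
    cfg = SimulationConfig(seed=7, chrom_length=150_000, control_length=8_000,
                           gene_count=25, te_count=20, n_planted_dmrs=20,
                           smrna_rate_per_kb=4.0)
    return generate_cohort(cfg)
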