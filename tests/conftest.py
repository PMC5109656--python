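import logging

import pytest

from fgi_typer import GeneratorConfig, generate_cohort, run_pipeline
from fgi_typer.alignment import warm_up

logging.getLogger("fgi_typer").setLevel(logging.ERROR)


@pytest.fixture(scope="session", autouse=True)
def _warm_aligner():
    warm_up()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (5 types x 3 strains + 5 FGI-)."""
    return generate_cohort(GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    c = default_cohort
    return run_pipeline(c.genomes, c.anchors, c.reference_db)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (2 types, short backbone) for I/O-heavy tests."""
    cfg = GeneratorConfig(
        seed=77,
        n_strains_per_type={"I": 1, "IV": 1},
        n_fgi_minus=2,
        backbone_len=30_000,
    )
    return generate_cohort(cfg)
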