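import numpy as np
import pytest

from regulonmap.coverage_io import MINUS, PLUS, StrandCoverage
from regulonmap.synthetic_data import (
    SimulationConfig,
    assign_gene_classes,
    generate_annotation,
    generate_chip_experiment,
    generate_expression_table,
)


@pytest.fixture(scope="session")
def spike_in_experiment():
    """A strongly enriched experiment (summits ~100x background) with two
    control-shared artifacts, used for recovery checks."""
    cfg = SimulationConfig(n_sites=10, site_enrichment=100.0,
                           background_rate=0.1, n_artifacts=2, seed=17)
    return generate_chip_experiment(cfg)


@pytest.fixture(scope="session")
def regulon_truth():
    """Annotation + gene classes + expression table from one seed."""
    cfg = SimulationConfig(seed=17)
    exp = generate_chip_experiment(cfg)
    genes = generate_annotation(cfg)
    truth = assign_gene_classes(exp.truth, genes, cfg)
    expression = generate_expression_table(truth, ("WT", "delta"), seed=cfg.seed)
    return cfg, exp, genes, truth, expression


def make_coverage(values, strand=PLUS, total=100_000_000.0, dataset="d"):
    return StrandCoverage(strand, np.asarray(values, dtype=float), total, dataset)


@pytest.fixture
def small_replicates():
    rng = np.random.default_rng(5)
    d1 = rng.poisson(1.0, size=600).astype(float)
    d2 = rng.poisson(1.0, size=600).astype(float)
    shared = rng.choice(600, size=6, replace=False)
    d1[shared] += 30
    d2[shared] += 30
    return make_coverage(d1), make_coverage(d2)
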