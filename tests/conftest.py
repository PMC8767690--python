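import pytest

from tcgtscope import simulate
from tcgtscope.pipeline import curate_catalog


@pytest.fixture(scope="session")
def study():
    """The packaged synthetic study: seed 42, 30 planted chimeras, 60 decoys."""
    return simulate.simulate_study(simulate.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def curated_catalog(study):
    ann = study.annotation
    exons = [(r.chrom, r.start, r.end) for r in ann.genes.itertuples(index=False)]
    return curate_catalog(ann.raw_records, ann.ltr_int_pairs, exons)
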