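import numpy as np
import pytest

from lincseek import (
    PipelineInputs,
    SyntheticConfig,
    generate_dataset,
    run_pipeline,
)
from lincseek.model import Interval, TranscriptModel


@pytest.fixture(scope="session")
def dataset():
    """The frozen synthetic study (seed 1, 30 lincRNA / 30 coding / 40 decoys)."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def pipeline_inputs(dataset):
    return PipelineInputs(
        protein_gene_loci=dataset.protein_gene_loci,
        utr_intervals=dataset.utr_intervals,
        protein_hits=dataset.protein_hits,
        domain_hits=dataset.domain_hits,
        rfam_hits=dataset.rfam_hits,
    )


@pytest.fixture(scope="session")
def pipeline_result(dataset, pipeline_inputs):
    return run_pipeline(dataset.transcripts, dataset.genome, pipeline_inputs)


def make_transcript(tid="t1", gid="g1", chrom="chr1", strand="+",
                    exons=((0, 100), (200, 300))):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=tuple(Interval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
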