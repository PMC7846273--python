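import numpy as np
import pytest

from nmdmutscan.annotation import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_transcript(exons, strand="+", chrom="chr1", tid="tx1", gene="g1",
                    cds=None):
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(transcript_id=tid, gene_id=gene, chrom=chrom,
                           strand=strand, exons=tuple(exons),
                           cds_start=cds_start, cds_end=cds_end)


@pytest.fixture
def se_event_parts():
    """A plus-strand cassette-exon event: exons at 0-100, 200-300 (cassette),
    400-500; inclusion keeps all three, exclusion skips the middle one."""
    inc = make_transcript([(0, 100), (200, 300), (400, 500)], tid="inc")
    exc = make_transcript([(0, 100), (400, 500)], tid="exc")
    return inc, exc
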