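"""Transcript parsing, the 50-nt rule, junction enumeration and event typing."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmdmutscan.annotation import (SpliceJunction, SplicingEvent,
                                   classify_event_nmd_relevance,
                                   classify_intron_type, classify_nmd,
                                   enumerate_junctions, infer_event_type,
                                   junction_dinucleotides, parse_annotation,
                                   reverse_complement)
from nmdmutscan.synthetic_data import generate_random_transcript

from conftest import make_transcript

GTF_TWO_EXON = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""

GTF_WITH_CDS = GTF_TWO_EXON + """\
chr1\ttest\tCDS\t121\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t301\t330\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

class TestParseAnnotation:
    def test_two_exon_transcript_round_trips(self):
        (tx,) = parse_annotation(io.StringIO(GTF_TWO_EXON))
        assert tx.transcript_id == "t1" and tx.gene_id == "g1"
        assert tx.strand == "+" and tx.exons == ((100, 200), (300, 400))

    def test_cds_features_populate_coding_interval(self):
        (tx,) = parse_annotation(io.StringIO(GTF_WITH_CDS))
        assert (tx.cds_start, tx.cds_end) == (120, 330)

    def test_unknown_strand_is_an_error(self):
        bad = GTF_TWO_EXON.replace("\t+\t", "\t.\t")
        with pytest.raises(ValueError, match="strand"):
            parse_annotation(io.StringIO(bad))

    def test_malformed_record_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_annotation(io.StringIO("chr1\tonly\tthree\n"))

    def test_exonless_transcript_skipped_with_warning(self, caplog):
        gtf = 'chr1\tt\tCDS\t10\t20\t.\t+\t.\tgene_id "g"; transcript_id "tX";\n'
        with caplog.at_level("WARNING"):
            assert parse_annotation(io.StringIO(gtf)) == []
        assert "tX" in caplog.text


# ---------------------------------------------------------------------------
# 50-nt rule
# ---------------------------------------------------------------------------

def _tx_with_stop_distance(distance):
    """Two-exon plus-strand transcript whose stop codon's last base lies
    exactly ``distance`` nt upstream of the single junction (first exon is
    300 nt, so the junction sits at spliced position 300)."""
    stop_last = 300 - distance  # 1-based spliced position of last stop base
    return make_transcript([(0, 300), (500, 800)],
                           cds=(stop_last - 9, stop_last))


class TestClassifyNMD:
    @pytest.mark.parametrize("distance,expected", [(51, True), (50, False), (100, True)])
    def test_boundary_is_strictly_greater_than_50(self, distance, expected):
        ann = classify_nmd(_tx_with_stop_distance(distance))
        assert ann.distance_nt == distance
        assert ann.is_nmd_substrate is expected

    def test_stop_in_last_exon_is_not_substrate(self):
        tx = make_transcript([(0, 300), (500, 800)], cds=(100, 650))
        ann = classify_nmd(tx)
        assert ann.distance_nt < 0 and not ann.is_nmd_substrate

    def test_single_exon_never_substrate(self):
        tx = make_transcript([(0, 500)], cds=(10, 100))
        ann = classify_nmd(tx)
        assert not ann.is_nmd_substrate and ann.status == "single_exon"

    def test_no_orf_is_flagged_not_defaulted(self):
        tx = make_transcript([(0, 30), (60, 90)])
        genome = {"chr1": "C" * 100}  # no ATG anywhere
        ann = classify_nmd(tx, genome)
        assert ann.status == "no_orf" and not ann.is_nmd_substrate

    def test_orf_derived_from_first_atg(self):
        # exon1 60 nt, exon2 60 nt: ATG at spliced offset 0, TAA at offsets 9-11
        seq = "ATGAAAAAATAA" + "C" * 108
        genome = {"chr1": seq[:60] + "NNNNN" + seq[60:]}
        tx = make_transcript([(0, 60), (65, 125)])
        ann = classify_nmd(tx, genome)
        assert ann.stop_codon_tx_pos == 12
        assert ann.distance_nt == 60 - 12
        assert not ann.is_nmd_substrate

    def test_minus_strand_annotated_cds(self):
        # mirror of the plus-strand boundary case
        tx = make_transcript([(500, 800), (0, 300)], strand="-")
        # junction at spliced position 300; want distance 51 -> stop last base
        # at spliced pos 249 -> genomic 800-1-248 = 551
        tx = make_transcript([(500, 800), (0, 300)], strand="-", cds=(551, 560))
        ann = classify_nmd(tx)
        assert ann.distance_nt == 51 and ann.is_nmd_substrate


def oracle_classify(tx, genome):
    """Independent brute-force 50-nt rule: spell the spliced sequence, scan
    codons from the first ATG, and measure the stop-to-junction distance
    directly on the spliced string."""
    if len(tx.exons) == 1:
        return False
    parts = []
    for s, e in sorted(tx.exons):
        parts.append(genome[tx.chrom][s:e])
    mrna = "".join(parts)
    if tx.strand == "-":
        mrna = reverse_complement(mrna)
    # spliced position (0-based) of each junction = cumulative exon length
    lens = [e - s for s, e in tx.exons]
    last_junction = sum(lens[:-1])
    start = mrna.find("ATG")
    if start < 0:
        return False
    stop_end = None
    for i in range(start, len(mrna) - 2, 3):
        if mrna[i:i + 3] in ("TAA", "TAG", "TGA"):
            stop_end = i + 3  # number of nt up to and including the stop
            break
    if stop_end is None:
        return False
    return (last_junction - stop_end) > 50


def test_random_models_agree_with_spliced_sequence_oracle(rng):
    """ORF-derived classification matches a brute-force oracle on random
    transcript models."""
    for _ in range(300):
        tx, genome = generate_random_transcript(rng)
        ann = classify_nmd(tx, genome)
        assert ann.is_nmd_substrate == oracle_classify(tx, genome), tx


def test_mirrored_gene_keeps_classification(rng):
    """Reversing strand and mirror-imaging coordinates leaves the 50-nt
    classification unchanged."""
    for _ in range(50):
        tx, genome = generate_random_transcript(rng)
        L = len(genome[tx.chrom])
        mirrored_exons = tuple((L - e, L - s) for s, e in tx.exons)
        flipped = make_transcript(mirrored_exons, chrom=tx.chrom,
                                  strand="-" if tx.strand == "+" else "+")
        mirrored_genome = {tx.chrom: reverse_complement(genome[tx.chrom])}
        a1 = classify_nmd(tx, genome)
        a2 = classify_nmd(flipped, mirrored_genome)
        assert a1.is_nmd_substrate == a2.is_nmd_substrate
        assert a1.distance_nt == a2.distance_nt


# ---------------------------------------------------------------------------
# junction enumeration
# ---------------------------------------------------------------------------

def brute_force_junctions(gene):
    """Double loop over all (donor, acceptor) pairs filtered by co-linearity."""
    strand = gene[0].strand
    donors, acceptors = set(), set()
    for tx in gene:
        genomic = sorted(tx.exons)
        for i, (s, e) in enumerate(genomic):
            if strand == "+":
                if i < len(genomic) - 1:
                    donors.add(e)
                if i > 0:
                    acceptors.add(s)
            else:
                if i > 0:
                    donors.add(s)
                if i < len(genomic) - 1:
                    acceptors.add(e)
    out = set()
    for d in donors:
        for a in acceptors:
            if (strand == "+" and d < a) or (strand == "-" and d > a):
                out.add((d, a))
    return out


class TestEnumerateJunctions:
    def test_four_exon_gene_yields_six_junctions(self):
        tx = make_transcript([(0, 10), (20, 30), (40, 50), (60, 70)])
        jxs = enumerate_junctions([tx])
        assert len(jxs) == 6
        assert {(j.donor, j.acceptor) for j in jxs} == brute_force_junctions([tx])

    def test_duplicate_transcripts_deduplicate(self):
        tx1 = make_transcript([(0, 10), (20, 30), (40, 50)], tid="a")
        tx2 = make_transcript([(0, 10), (20, 30), (40, 50)], tid="b")
        assert enumerate_junctions([tx1, tx2]) == enumerate_junctions([tx1])

    def test_single_exon_gene_is_empty(self):
        assert enumerate_junctions([make_transcript([(0, 100)])]) == []

    def test_unannotated_double_skip_junction_present(self, se_event_parts):
        inc, _exc = se_event_parts
        extra = make_transcript([(0, 100), (200, 300), (400, 500), (600, 700)],
                                tid="four")
        jxs = enumerate_junctions([extra])
        # exon1 donor to exon4 acceptor: skips exons 2 and 3 together
        assert SpliceJunction("chr1", 100, 600, "+") in jxs

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_genes(self, data):
        strand = data.draw(st.sampled_from("+-"))
        n_tx = data.draw(st.integers(1, 3))
        gene = []
        for t in range(n_tx):
            n_exons = data.draw(st.integers(1, 8))
            bounds = sorted(data.draw(st.sets(st.integers(0, 400),
                                              min_size=2 * n_exons,
                                              max_size=2 * n_exons)))
            exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
            gene.append(make_transcript(exons, strand=strand, tid=f"t{t}"))
        got = {(j.donor, j.acceptor) for j in enumerate_junctions(gene)}
        assert got == brute_force_junctions(gene)


# ---------------------------------------------------------------------------
# intron typing and NMD relevance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("donor,acceptor,expected", [
    ("GT", "AG", "U2"),
    ("AT", "AC", "U12"),
    ("GC", "AG", "unknown"),  # conservatively excluded, not assumed major
    ("NT", "AG", "unknown"),
    ("gt", "ag", "U2"),
])
def test_intron_type_classification(donor, acceptor, expected):
    assert classify_intron_type(donor, acceptor) == expected


def test_junction_dinucleotides_minus_strand():
    genome = {"chr1": "AAAAA" + "CT" + "A" * 6 + "AC" + "AAAAA"}
    # intron [5, 15) on the minus strand: donor at the right end
    jx = SpliceJunction("chr1", 15, 5, "-")
    assert junction_dinucleotides(jx, genome) == ("GT", "AG")
    assert classify_intron_type(*junction_dinucleotides(jx, genome)) == "U2"


class TestEventNMDRelevance:
    def _event(self, se_parts):
        inc, exc = se_parts
        return SplicingEvent("ev1", "SE", (inc, exc))

    @pytest.mark.parametrize("flags,expected", [
        ((True, False), True),
        ((True, True), False),
        ((False, False), False),
    ])
    def test_at_least_one_but_not_all(self, se_event_parts, flags, expected):
        from nmdmutscan.annotation import NMDAnnotation
        ev = self._event(se_event_parts)
        anns = {c.transcript_id: NMDAnnotation(c.transcript_id, 1, 2, 1, f)
                for c, f in zip(ev.children, flags)}
        assert classify_event_nmd_relevance(ev, anns) is expected

    def test_child_order_irrelevant(self, se_event_parts):
        from nmdmutscan.annotation import NMDAnnotation
        inc, exc = se_event_parts
        anns = {"inc": NMDAnnotation("inc", 1, 2, 1, True),
                "exc": NMDAnnotation("exc", 1, 2, 1, False)}
        fwd = SplicingEvent("e", "SE", (inc, exc))
        rev = SplicingEvent("e", "SE", (exc, inc))
        assert (classify_event_nmd_relevance(fwd, anns)
                == classify_event_nmd_relevance(rev, anns))

    def test_missing_annotation_is_an_error(self, se_event_parts):
        ev = self._event(se_event_parts)
        with pytest.raises(KeyError, match="inc"):
            classify_event_nmd_relevance(ev, {})


def test_infer_event_type_se(se_event_parts):
    inc, exc = se_event_parts
    assert infer_event_type(inc, exc) == "SE"


def test_infer_event_type_ri():
    inc = make_transcript([(0, 100), (200, 500), (600, 700)], tid="i")
    exc = make_transcript([(0, 100), (200, 300), (400, 500), (600, 700)], tid="e")
    assert infer_event_type(inc, exc) == "RI"
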