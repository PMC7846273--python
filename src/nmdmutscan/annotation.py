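"""Transcript models, the 50-nt NMD rule, splice junctions and splicing events.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open on the genome.  Exons of a
:class:`TranscriptModel` are stored in transcript 5'→3' order (ascending
genomic start on ``+`` transcripts, descending on ``-``).  GTF input/output
converts to and from the format's native 1-based, closed intervals at the
boundary.

The NMD classifier implements the 50-nt rule: an isoform is a predicted NMD
substrate when its termination codon lies more than 50 nt upstream of the
final exon–exon junction, measured in spliced (mRNA) coordinates.  The
distance is measured from the last (3') base of the stop codon to the last
exonic base preceding the final junction, so a transcript whose stop codon
ends exactly 50 nt before the junction is *not* a substrate and one ending
51 nt before it is.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
NMD_DISTANCE_NT = 50

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Extract ``[start, end)`` from a genome that is a dict of strings or a
    pyfaidx.Fasta-like mapping."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    return str(genome[chrom][start:end]).upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """Gene/transcript/exon/CDS geometry on a genome.

    ``exons`` are (start, end) pairs, 0-based half-open, in transcript
    5'→3' order.  ``cds_start``/``cds_end`` delimit the annotated coding
    region *including the termination codon* as a genomic interval
    (min/max over strands).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >=1 exon")
        exons = tuple(tuple(e) for e in self.exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        genomic = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        ordered = genomic if self.strand == "+" else genomic[::-1]
        object.__setattr__(self, "exons", tuple(ordered))
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS interval")
        if self.cds_start is not None:
            if not (self.cds_start < self.cds_end):
                raise ValueError(f"{self.transcript_id}: empty CDS")
            span = (self.cds_start, self.cds_end)
            covered = sum(
                max(0, min(e, span[1]) - max(s, span[0])) for s, e in self.exons
            )
            if covered <= 0:
                raise ValueError(f"{self.transcript_id}: CDS outside exon union")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic base (0-based) onto its 0-based spliced offset."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        raise ValueError(f"position {pos} not exonic in {self.transcript_id}")

    def spliced_sequence(self, genome: Mapping[str, object]) -> str:
        parts = []
        for s, e in self.exons:
            seq = fetch_sequence(genome, self.chrom, s, e)
            parts.append(seq if self.strand == "+" else reverse_complement(seq))
        return "".join(parts)

    def tx_to_genomic(self, offset: int) -> int:
        """Map a 0-based spliced offset back to its genomic base."""
        if not 0 <= offset < self.spliced_length:
            raise ValueError(f"spliced offset {offset} outside transcript")
        for s, e in self.exons:
            length = e - s
            if offset < length:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= length
        raise AssertionError("unreachable")

    def tx_to_genomic_blocks(self, t0: int, t1: int) -> tuple[tuple[int, int], ...]:
        """Project the spliced interval [t0, t1) onto genomic blocks
        (ascending, 0-based half-open)."""
        if not (0 <= t0 < t1 <= self.spliced_length):
            raise ValueError(f"spliced interval [{t0},{t1}) outside transcript")
        blocks = []
        offset = 0
        for s, e in self.exons:
            length = e - s
            lo, hi = max(t0, offset), min(t1, offset + length)
            if hi > lo:
                if self.strand == "+":
                    blocks.append((s + (lo - offset), s + (hi - offset)))
                else:
                    blocks.append((e - (hi - offset), e - (lo - offset)))
            offset += length
        return tuple(sorted(blocks))

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals in transcript order (start < end)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2) if self.strand == "+" else (e2, s1))
        return tuple(out)

    def junctions(self) -> tuple["SpliceJunction", ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(SpliceJunction(self.chrom, e1, s2, "+"))
            else:
                out.append(SpliceJunction(self.chrom, s1, e2, "-"))
        return tuple(out)


@dataclass(frozen=True)
class NMDAnnotation:
    """Outcome of the 50-nt rule for one isoform.

    Transcript positions are 1-based offsets along the spliced mRNA;
    ``last_junction_tx_pos`` is the position of the last exonic base before
    the final junction and ``distance_nt = last_junction_tx_pos -
    stop_codon_tx_pos``.  ``status`` is ``ok``, ``single_exon`` or
    ``no_orf``; only ``ok`` transcripts carry distances.
    """

    transcript_id: str
    stop_codon_tx_pos: Optional[int]
    last_junction_tx_pos: Optional[int]
    distance_nt: Optional[int]
    is_nmd_substrate: bool
    status: str = "ok"


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """One exon–exon junction.

    ``donor`` is the genomic coordinate where the intron begins on the donor
    (5' splice site) side and ``acceptor`` where it ends on the acceptor
    side, both half-open boundaries; on ``+`` donor < acceptor, on ``-``
    donor > acceptor, so the donor is always upstream in transcription
    direction.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self):
        if self.strand == "+" and not self.donor < self.acceptor:
            raise ValueError("donor must precede acceptor on + strand")
        if self.strand == "-" and not self.donor > self.acceptor:
            raise ValueError("donor must follow acceptor genomically on - strand")

    def intron_interval(self) -> tuple[int, int]:
        return (self.donor, self.acceptor) if self.strand == "+" else (self.acceptor, self.donor)


EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass
class SplicingEvent:
    """An alternative-splicing event with >=2 child isoform fragments.

    By convention the first child is the "inclusion" isoform (the one
    containing the alternative element) and PSI refers to it.
    """

    event_id: str
    event_type: str
    children: tuple[TranscriptModel, ...]
    nmd_relevant: Optional[bool] = None
    intron_class: str = "unknown"

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        self.children = tuple(self.children)
        if len(self.children) < 2:
            raise ValueError("event needs >=2 child isoforms")

    @property
    def chrom(self) -> str:
        return self.children[0].chrom


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def parse_annotation(gtf_source) -> list[TranscriptModel]:
    """Parse a GTF stream or path into transcript models.

    Uses ``exon`` features (required) and ``CDS``/``stop_codon`` features
    (optional); the stop codon is folded into the CDS interval so that the
    stored coding region includes the termination codon.  Transcripts with
    zero exons are skipped with a warning; malformed records raise a
    ``ValueError`` naming the line number.
    """
    if isinstance(gtf_source, (str, bytes)):
        handle = open(gtf_source)
        close = True
    else:
        handle = gtf_source
        close = False
    exons: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    cds: dict[str, list] = {}
    seen: dict[str, None] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "stop_codon", "transcript"):
                continue
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: non-integer coordinates") from exc
            if end1 <= start0:
                raise ValueError(f"GTF line {lineno}: empty interval {start}-{end}")
            attrd = _parse_attributes(attrs)
            tid = attrd.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF line {lineno}: missing transcript_id attribute")
            if strand not in ("+", "-"):
                raise ValueError(f"GTF line {lineno}: unsupported strand {strand!r}")
            seen.setdefault(tid)
            meta.setdefault(tid, (attrd.get("gene_id", tid), chrom, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append((start0, end1))
            elif feature in ("CDS", "stop_codon"):
                cds.setdefault(tid, []).append((start0, end1))
    finally:
        if close:
            handle.close()
    models = []
    for tid in seen:
        gene_id, chrom, strand = meta[tid]
        if tid not in exons:
            logger.warning("transcript %s has no exon features; skipped", tid)
            continue
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
                exons=tuple(exons[tid]), cds_start=cds_start, cds_end=cds_end,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str, source: str = "nmdmutscan") -> None:
    """Write transcript models as GTF (exon + CDS features, 1-based closed)."""
    with open(path, "w") as out:
        for tx in models:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for s, e in sorted(tx.exons):
                out.write("\t".join([tx.chrom, source, "exon", str(s + 1), str(e),
                                     ".", tx.strand, ".", attrs]) + "\n")
            if tx.cds_start is not None:
                for s, e in sorted(tx.exons):
                    cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                    if ce > cs:
                        out.write("\t".join([tx.chrom, source, "CDS", str(cs + 1), str(ce),
                                             ".", tx.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# ORF derivation and NMD classification
# ---------------------------------------------------------------------------

def derive_orf_stop(spliced: str) -> Optional[int]:
    """0-based spliced offset of the last base of the first in-frame stop
    codon of the ORF starting at the 5'-most AUG, or None when no complete
    ORF exists."""
    start = spliced.find(START_CODON)
    if start < 0:
        return None
    for i in range(start, len(spliced) - 2, 3):
        if spliced[i : i + 3] in STOP_CODONS:
            return i + 2
    return None


def classify_nmd(tx: TranscriptModel, genome: Optional[Mapping[str, object]] = None) -> NMDAnnotation:
    """Apply the 50-nt rule to one isoform.

    The termination codon comes from the annotated CDS when present (its
    3'-most coding base is taken as the last stop-codon base); otherwise,
    when a genome is supplied, from the ORF starting at the 5'-most AUG of
    the spliced sequence.  Single-exon transcripts are never substrates;
    transcripts without a determinable ORF are flagged ``no_orf`` and
    classified non-substrate, never silently defaulted.
    """
    if tx.n_exons == 1:
        return NMDAnnotation(tx.transcript_id, None, None, None, False, status="single_exon")
    last_junction_tx = tx.spliced_length - (tx.exons[-1][1] - tx.exons[-1][0])

    stop_offset: Optional[int] = None
    if tx.cds_start is not None:
        stop_genomic = tx.cds_end - 1 if tx.strand == "+" else tx.cds_start
        stop_offset = tx.genomic_to_tx(stop_genomic)
    elif genome is not None:
        stop_offset = derive_orf_stop(tx.spliced_sequence(genome))
    if stop_offset is None:
        return NMDAnnotation(tx.transcript_id, None, last_junction_tx, None, False, status="no_orf")

    stop_pos = stop_offset + 1  # 1-based position of the stop codon's last base
    distance = last_junction_tx - stop_pos
    return NMDAnnotation(
        transcript_id=tx.transcript_id,
        stop_codon_tx_pos=stop_pos,
        last_junction_tx_pos=last_junction_tx,
        distance_nt=distance,
        is_nmd_substrate=distance > NMD_DISTANCE_NT,
        status="ok",
    )


# ---------------------------------------------------------------------------
# junction enumeration and intron typing
# ---------------------------------------------------------------------------

def enumerate_junctions(gene: Iterable[TranscriptModel]) -> list[SpliceJunction]:
    """All co-linear (donor, acceptor) combinations over a gene's splice sites.

    Donors and acceptors are pooled across the gene's transcripts and every
    pair with the acceptor downstream of the donor in transcription
    direction is emitted, deduplicated on (chrom, donor, acceptor, strand).
    This includes junctions absent from any annotated isoform (e.g. an
    exon-9→exon-12 junction diagnostic for a double-exon skip).  A gene
    with only single-exon transcripts yields an empty list.
    """
    gene = list(gene)
    if not gene:
        return []
    chrom, strand = gene[0].chrom, gene[0].strand
    donors, acceptors = set(), set()
    for tx in gene:
        if tx.chrom != chrom or tx.strand != strand:
            raise ValueError("gene transcripts must share chromosome and strand")
        for jx in tx.junctions():
            donors.add(jx.donor)
            acceptors.add(jx.acceptor)
    out = set()
    for d, a in itertools.product(donors, acceptors):
        if (strand == "+" and d < a) or (strand == "-" and d > a):
            out.add(SpliceJunction(chrom, d, a, strand))
    return sorted(out)


def classify_intron_type(donor_dinucleotide: str, acceptor_dinucleotide: str) -> str:
    """U2 for GT..AG termini, U12 for AT..AC, otherwise ``unknown``.

    GC-AG and any non-ACGT input are conservatively ``unknown`` (excluded
    downstream so intron type cannot confound the differential analysis).
    """
    d = donor_dinucleotide.upper().replace("U", "T")
    a = acceptor_dinucleotide.upper().replace("U", "T")
    if len(d) != 2 or len(a) != 2:
        return "unknown"
    if d == "GT" and a == "AG":
        return "U2"
    if d == "AT" and a == "AC":
        return "U12"
    return "unknown"


def junction_dinucleotides(jx: SpliceJunction, genome: Mapping[str, object]) -> tuple[str, str]:
    """Intron-terminal dinucleotides of a junction in transcription orientation."""
    lo, hi = jx.intron_interval()
    if jx.strand == "+":
        return (fetch_sequence(genome, jx.chrom, lo, lo + 2),
                fetch_sequence(genome, jx.chrom, hi - 2, hi))
    return (reverse_complement(fetch_sequence(genome, jx.chrom, hi - 2, hi)),
            reverse_complement(fetch_sequence(genome, jx.chrom, lo, lo + 2)))


def classify_event_intron(event: SplicingEvent, genome: Mapping[str, object]) -> str:
    """Intron class of an event: U2 only when every intron of every child is
    U2-type; U12 when any is U12; otherwise unknown."""
    classes = set()
    for child in event.children:
        for jx in child.junctions():
            classes.add(classify_intron_type(*junction_dinucleotides(jx, genome)))
    if not classes:
        return "unknown"
    if classes == {"U2"}:
        return "U2"
    if "U12" in classes:
        return "U12"
    return "unknown"


# ---------------------------------------------------------------------------
# event typing and NMD relevance
# ---------------------------------------------------------------------------

def infer_event_type(inclusion: TranscriptModel, exclusion: TranscriptModel) -> str:
    """Structural relation between two child isoforms of a binary event.

    SE: exclusion drops one internal exon of inclusion.  RI: inclusion merges
    two adjacent exclusion exons across a retained intron.  A5SS/A3SS: exon
    chains identical except one donor (resp. acceptor) boundary.  MXE: one
    internal exon swapped for a disjoint alternative.
    """
    inc = sorted(inclusion.exons)
    exc = sorted(exclusion.exons)
    if len(inc) == len(exc) + 1:
        for i in range(1, len(inc) - 1):
            if inc[:i] + inc[i + 1 :] == exc:
                return "SE"
    if len(exc) == len(inc) + 1:
        for i in range(len(inc)):
            merged = exc[:i] + [(exc[i][0], exc[i + 1][1])] + exc[i + 2 :]
            if i + 1 < len(exc) and merged == inc:
                return "RI"
    if len(inc) == len(exc):
        diff = [i for i, (a, b) in enumerate(zip(inc, exc)) if a != b]
        if len(diff) == 1:
            i = diff[0]
            (s1, e1), (s2, e2) = inc[i], exc[i]
            donor_side_is_end = inclusion.strand == "+"
            if min(e1, e2) <= max(s1, s2):
                return "MXE"
            if s1 == s2 and e1 != e2:
                return "A5SS" if donor_side_is_end else "A3SS"
            if e1 == e2 and s1 != s2:
                return "A3SS" if donor_side_is_end else "A5SS"
    raise ValueError(
        f"no recognized structural relation between {inclusion.transcript_id} "
        f"and {exclusion.transcript_id}"
    )


def classify_event_nmd_relevance(
    event: SplicingEvent, annotations: Mapping[str, NMDAnnotation]
) -> bool:
    """An event is NMD relevant iff at least one, but not all, child isoforms
    are predicted NMD substrates."""
    flags = []
    for child in event.children:
        if child.transcript_id not in annotations:
            raise KeyError(f"missing NMD annotation for child {child.transcript_id}")
        flags.append(annotations[child.transcript_id].is_nmd_substrate)
    n_nmd = sum(flags)
    return 0 < n_nmd < len(flags)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_nmd_table(annotations: Sequence[NMDAnnotation], path: str) -> None:
    with open(path, "w") as out:
        out.write("transcript_id\tstop_codon_tx_pos\tlast_junction_tx_pos\t"
                  "distance_nt\tis_nmd_substrate\tstatus\n")
        for a in annotations:
            out.write("\t".join([
                a.transcript_id,
                "NA" if a.stop_codon_tx_pos is None else str(a.stop_codon_tx_pos),
                "NA" if a.last_junction_tx_pos is None else str(a.last_junction_tx_pos),
                "NA" if a.distance_nt is None else str(a.distance_nt),
                str(a.is_nmd_substrate), a.status]) + "\n")


def write_junction_table(junctions: Sequence[SpliceJunction], path: str) -> None:
    with open(path, "w") as out:
        out.write("chrom\tdonor\tacceptor\tstrand\tintron_start\tintron_end\n")
        for j in junctions:
            lo, hi = j.intron_interval()
            out.write(f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.strand}\t{lo}\t{hi}\n")


def write_event_catalog(events: Sequence[SplicingEvent], path: str) -> None:
    with open(path, "w") as out:
        out.write("event_id\tevent_type\tchrom\tchildren\tnmd_relevant\tintron_class\n")
        for ev in events:
            out.write("\t".join([
                ev.event_id, ev.event_type, ev.chrom,
                ",".join(c.transcript_id for c in ev.children),
                "NA" if ev.nmd_relevant is None else str(ev.nmd_relevant),
                ev.intron_class]) + "\n")
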