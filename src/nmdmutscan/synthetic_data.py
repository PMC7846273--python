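"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the corresponding analysis
stage assumes, and emits a machine-readable truth table so that every
downstream stage can be tested against known ground truth without any
external download:

* multi-isoform gene models (SE/RI/A5SS/A3SS/MXE structures) with NMD
  status planted by construction, including exact 50-nt-boundary cases;
* replicate informative-read counts drawn binomially around stated PSI
  values;
* tumor/normal read sets over small loci with somatic and germline variants
  planted at specified allele fractions, written as coordinate-sorted SAM
  plus a reference FASTA;
* a toy population-variant catalog VCF engineered to overlap a controlled
  fraction of a mutation list.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config; a fixed seed regenerates byte-identical files.  Sequencing error is
off by default so the calling thresholds see a clean signal; a per-base
substitution rate can be switched on to stress-test them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (EVENT_TYPES, SplicingEvent, TranscriptModel,
                         infer_event_type, reverse_complement, write_gtf)
from .somatic_calling import BASES, TargetLocus
from .splicing_quant import EventQuant
from .variant_catalog import ReportedMutation

__all__ = [
    "SimulationConfig", "PlannedVariant",
    "generate_annotation", "generate_random_transcript",
    "simulate_event_counts", "simulate_alignments",
    "generate_mutations", "generate_catalog",
]


@dataclass
class SimulationConfig:
    """Knobs of the full simulation; defaults mirror the study conditions
    (3 replicates per group, ~200 informative reads per event, 50-nt reads,
    thresholds exercised at depth well above the 9-read floor)."""

    seed: int = 0
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 6)
    psi_truth: float = 0.5
    replicates_per_group: int = 3
    read_depth: int = 200
    read_length: int = 50
    pileup_depth: int = 60
    error_rate: float = 0.0
    catalog_overlap_fraction: float = 0.45
    variant_plan: list = field(default_factory=list)

    def __post_init__(self):
        for frac in (self.psi_truth, self.error_rate, self.catalog_overlap_fraction):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0,1]")
        lo, hi = self.exons_per_gene
        if lo < 2 or hi < lo:
            raise ValueError("exons_per_gene must be a range with min >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

_EXON_LEN = (90, 180)     # keeps events comfortably larger than one read
_INTRON_LEN = (120, 300)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _plant_splice_motifs(seq: list, transcripts: Sequence[TranscriptModel]) -> None:
    """Force GT..AG termini onto every intron of every isoform (U2-type)."""
    for tx in transcripts:
        for lo, hi in tx.introns():
            if tx.strand == "+":
                seq[lo:lo + 2] = "GT"
                seq[hi - 2:hi] = "AG"
            else:
                seq[hi - 2:hi] = "AC"   # revcomp(GT)
                seq[lo:lo + 2] = "CT"   # revcomp(AG)


def _cds_for_distance(tx: TranscriptModel, distance_nt: int) -> tuple[int, int]:
    """Genomic CDS interval placing the stop codon's last base exactly
    ``distance_nt`` nt upstream of the final junction in spliced coords."""
    last_exon_len = tx.exons[-1][1] - tx.exons[-1][0]
    last_junction = tx.spliced_length - last_exon_len  # 1-based pos of last pre-junction base
    stop_pos = last_junction - distance_nt             # 1-based last stop base
    if stop_pos < 6 or stop_pos > tx.spliced_length:
        raise ValueError(f"distance {distance_nt} infeasible for {tx.transcript_id}")
    start_offset = (stop_pos - 3) % 3  # keep the ORF in frame from near the 5' end
    g1 = tx.tx_to_genomic(start_offset)
    g2 = tx.tx_to_genomic(stop_pos - 1)
    lo, hi = (g1, g2) if tx.strand == "+" else (g2, g1)
    return lo, hi + 1


def _event_structures(rng, chrom, offset, strand, event_type, n_flank):
    """Exon chains (genomic intervals) of the inclusion/exclusion isoforms."""
    def span(lo_hi):
        return int(rng.integers(*lo_hi))

    exons_inc, exons_exc = [], []
    cursor = offset
    flanks_before = n_flank
    for _ in range(flanks_before):
        e = (cursor, cursor + span(_EXON_LEN))
        exons_inc.append(e)
        exons_exc.append(e)
        cursor = e[1] + span(_INTRON_LEN)
    if event_type == "SE":
        cass = (cursor, cursor + span(_EXON_LEN))
        exons_inc.append(cass)
        cursor = cass[1] + span(_INTRON_LEN)
    elif event_type == "RI":
        a = (cursor, cursor + span(_EXON_LEN))
        intron = span(_INTRON_LEN)
        b = (a[1] + intron, a[1] + intron + span(_EXON_LEN))
        exons_inc.append((a[0], b[1]))   # intron retained
        exons_exc.extend([a, b])
        cursor = b[1] + span(_INTRON_LEN)
        tail = (cursor, cursor + span(_EXON_LEN))
        exons_inc.append(tail)
        exons_exc.append(tail)
        return exons_inc, exons_exc
    elif event_type in ("A5SS", "A3SS"):
        base = (cursor, cursor + span(_EXON_LEN))
        ext = span((30, 80))
        if (event_type == "A5SS") == (strand == "+"):
            longer = (base[0], base[1] + ext)          # donor-side difference
            exons_inc.append(longer); exons_exc.append(base)
            cursor = longer[1] + span(_INTRON_LEN)
        else:
            longer = (base[0] - ext, base[1])
            # shift so the acceptor-side extension stays past the previous intron
            exons_inc.append(longer); exons_exc.append(base)
            cursor = base[1] + span(_INTRON_LEN)
    elif event_type == "MXE":
        m1 = (cursor, cursor + span(_EXON_LEN))
        cursor2 = m1[1] + span(_INTRON_LEN)
        m2 = (cursor2, cursor2 + span(_EXON_LEN))
        exons_inc.append(m1)
        exons_exc.append(m2)
        cursor = m2[1] + span(_INTRON_LEN)
    else:
        raise ValueError(event_type)
    tail = (cursor, cursor + span(_EXON_LEN))
    exons_inc.append(tail)
    exons_exc.append(tail)
    return exons_inc, exons_exc


def generate_annotation(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    include_boundary: bool = True,
    out_dir: Optional[str] = None,
):
    """Generate multi-isoform gene models with planted NMD truth.

    Returns ``(transcripts, events, genome, truth)`` where ``truth`` is a
    DataFrame with one row per child isoform recording the planted
    stop-to-junction distance and NMD status.  Event types cycle through
    SE/RI/A5SS/A3SS/MXE; per event, the inclusion child is planted as a
    non-substrate and the exclusion child as a substrate (or the reverse),
    with distances drawn away from the 50-nt boundary except for dedicated
    exact-boundary genes (distance 50 and 51) added when
    ``include_boundary`` is set.  When ``out_dir`` is given, a GTF, genome
    FASTA, event catalog TSV and truth TSV are written there.
    """
    rng = rng or config.rng()
    transcripts, events, rows = [], [], []
    genome: dict[str, str] = {}
    distances_boundary = [(50, -10), (51, -10)] if include_boundary else []
    n_total = config.n_genes + len(distances_boundary)
    for g in range(n_total):
        chrom = f"chrS{g+1}"
        event_type = EVENT_TYPES[g % len(EVENT_TYPES)]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        boundary = g >= config.n_genes
        if boundary:
            event_type, strand = "SE", "+"
        exons_inc, exons_exc = _event_structures(rng, chrom, 100, strand, event_type, n_flank=1)
        gene_id = f"geneS{g+1}"
        inc = TranscriptModel(f"{gene_id}.inc", gene_id, chrom, strand, tuple(exons_inc))
        exc = TranscriptModel(f"{gene_id}.exc", gene_id, chrom, strand, tuple(exons_exc))
        def _last_junction(tx):
            return tx.spliced_length - (tx.exons[-1][1] - tx.exons[-1][0])

        def _draw_substrate_distance(tx):
            hi = min(120, _last_junction(tx) - 6)  # keep room for a short ORF
            return int(rng.integers(60, hi))

        if boundary:
            d_exc, d_inc = distances_boundary[g - config.n_genes]
        else:
            # one child planted clear of the boundary on each side
            if rng.integers(0, 2) == 0:
                d_inc, d_exc = int(rng.integers(-40, 30)), _draw_substrate_distance(exc)
            else:
                d_inc, d_exc = _draw_substrate_distance(inc), int(rng.integers(-40, 30))
        children = []
        for tx, dist in ((inc, d_inc), (exc, d_exc)):
            lo, hi = _cds_for_distance(tx, dist)
            tx = TranscriptModel(tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
                                 tx.exons, cds_start=lo, cds_end=hi)
            children.append((tx, dist))
        inc, exc = children[0][0], children[1][0]
        transcripts.extend([inc, exc])
        chrom_len = max(e for tx in (inc, exc) for _, e in tx.exons) + 200
        seq = list(_random_seq(rng, chrom_len))
        _plant_splice_motifs(seq, (inc, exc))
        genome[chrom] = "".join(seq)
        event = SplicingEvent(
            event_id=f"ev_{gene_id}", event_type=event_type,
            children=(inc, exc), intron_class="U2",
        )
        # truth by construction: distance > 50 defines the substrate child
        nmd_flags = {tx.transcript_id: dist > 50 for tx, dist in children}
        event.nmd_relevant = 0 < sum(nmd_flags.values()) < len(nmd_flags)
        events.append(event)
        for tx, dist in children:
            rows.append((gene_id, tx.transcript_id, event.event_id, event_type,
                         tx.n_exons, dist, dist > 50, boundary))
    truth = pd.DataFrame(rows, columns=[
        "gene_id", "transcript_id", "event_id", "event_type",
        "n_exons", "planted_distance_nt", "is_nmd_truth", "is_boundary_case",
    ])
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_gtf(transcripts, os.path.join(out_dir, "annotation.gtf"))
        write_fasta(genome, os.path.join(out_dir, "genome.fa"))
        truth.to_csv(os.path.join(out_dir, "annotation_truth.tsv"), sep="\t", index=False)
    return transcripts, events, genome, truth


def generate_random_transcript(rng: np.random.Generator,
                               max_exons: int = 6) -> tuple[TranscriptModel, dict[str, str]]:
    """One random CDS-free transcript plus its genome, for oracle testing of
    the ORF-derived 50-nt rule."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    exons = []
    cursor = int(rng.integers(0, 50))
    for _ in range(n_exons):
        length = int(rng.integers(20, 200))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(30, 150))
    chrom = "chrR"
    tx = TranscriptModel("txR", "geneR", chrom, strand, tuple(exons))
    genome = {chrom: _random_seq(rng, cursor + 50)}
    return tx, genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# event-count simulator
# ---------------------------------------------------------------------------

def simulate_event_counts(
    event_ids: Sequence[str],
    psi_a: Sequence[float],
    psi_b: Sequence[float],
    rng: np.random.Generator,
    n_replicates: int = 3,
    depth: int = 200,
    positions: tuple[int, int] = (1, 1),
    isoform_ids: tuple[str, str] = ("inc", "exc"),
) -> tuple[dict[str, list[EventQuant]], dict[str, list[EventQuant]], pd.DataFrame]:
    """Replicate informative-read counts around true PSI values.

    Per replicate, ``depth`` informative reads are split binomially between
    the two child isoforms with inclusion probability
    ``psi*L_inc / (psi*L_inc + (1-psi)*L_exc)`` so that the
    length-normalized PSI estimator is unbiased for the planted value.
    Returns per-event quant lists for groups A and B plus a truth table.
    """
    li, le = positions
    inc_id, exc_id = isoform_ids

    def _draw(psi):
        p = psi * li / (psi * li + (1 - psi) * le) if 0 < psi < 1 else float(psi)
        inc = int(rng.binomial(depth, p))
        return inc, depth - inc

    group_a: dict[str, list[EventQuant]] = {}
    group_b: dict[str, list[EventQuant]] = {}
    rows = []
    for eid, pa, pb in zip(event_ids, psi_a, psi_b):
        group_a[eid], group_b[eid] = [], []
        for group, psi, store in (("a", pa, group_a), ("b", pb, group_b)):
            for r in range(n_replicates):
                inc, exc = _draw(psi)
                store[eid].append(EventQuant(
                    event_id=eid, sample_id=f"{group}{r+1}",
                    reads={inc_id: inc, exc_id: exc},
                    positions={inc_id: li, exc_id: le},
                ))
        rows.append((eid, pa, pb, pb - pa))
    truth = pd.DataFrame(rows, columns=["event_id", "psi_a", "psi_b", "delta_psi"])
    return group_a, group_b, truth


# ---------------------------------------------------------------------------
# alignment simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedVariant:
    """A variant to plant: genomic position, alternate base, allele fraction
    and germline/somatic status."""

    locus: str
    chrom: str
    pos: int
    alt: str
    vaf: float
    is_germline: bool = False

    def __post_init__(self):
        if not 0 <= self.vaf <= 1:
            raise ValueError(f"vaf {self.vaf} outside [0,1]")
        if self.alt not in BASES:
            raise ValueError(f"alt must be one of {BASES}")


def simulate_alignments(
    loci: Sequence[TargetLocus],
    variant_plan: Sequence[PlannedVariant],
    rng: np.random.Generator,
    read_length: int = 50,
    depth: int = 60,
    error_rate: float = 0.0,
    out_dir: Optional[str] = None,
    sample: str = "patient",
):
    """Tumor and normal read sets over small loci with planted variants.

    Reads of fixed length tile every locus at stride 1, repeated until the
    interior coverage (``read_length`` per pass) reaches ``depth``.  At each
    planted variant, every covering read carries the alternate base
    independently with probability ``vaf`` (so alt counts are binomial in
    the local depth).  Germline variants are planted in both samples,
    somatic ones only in the tumor.  Returns ``(reference, tumor_reads,
    normal_reads)`` as a genome dict plus per-sample lists of
    ``(chrom, start, sequence)``; when ``out_dir`` is given, coordinate-
    sorted ``<sample>.tumor.sam``/``<sample>.normal.sam`` and a shared
    ``reference.fa`` are written with pysam.
    """
    reference: dict[str, str] = {}
    for locus in loci:
        current = len(reference.get(locus.chrom, ""))
        if locus.end > current:
            reference[locus.chrom] = (reference.get(locus.chrom, "")
                                      + _random_seq(rng, locus.end - current))
    by_locus: dict[str, list[PlannedVariant]] = {l.name: [] for l in loci}
    locus_by_name = {l.name: l for l in loci}
    for var in variant_plan:
        locus = locus_by_name.get(var.locus)
        if locus is None or not locus.contains(var.chrom, var.pos):
            raise ValueError(f"planted variant at {var.chrom}:{var.pos} outside locus {var.locus}")
        if reference[var.chrom][var.pos] == var.alt:
            # keep ref != alt: nudge the generated reference base instead
            seq = list(reference[var.chrom])
            seq[var.pos] = next(b for b in BASES if b != var.alt)
            reference[var.chrom] = "".join(seq)
        by_locus[var.locus].append(var)

    passes = max(1, -(-depth // read_length))
    bases = np.array(list("ACGT"))

    def _reads(include_somatic: bool):
        reads = []
        for locus in loci:
            variants = [v for v in by_locus[locus.name]
                        if v.is_germline or include_somatic]
            for _pass in range(passes):
                for start in range(locus.start, locus.end - read_length + 1):
                    seq = list(reference[locus.chrom][start:start + read_length])
                    for v in variants:
                        if start <= v.pos < start + read_length and rng.random() < v.vaf:
                            seq[v.pos - start] = v.alt
                    if error_rate > 0:
                        hits = np.nonzero(rng.random(read_length) < error_rate)[0]
                        for i in hits:
                            seq[i] = str(rng.choice(bases[bases != seq[i]]))
                    reads.append((locus.chrom, start, "".join(seq)))
        reads.sort(key=lambda r: (r[0], r[1]))
        return reads

    tumor = _reads(include_somatic=True)
    normal = _reads(include_somatic=False)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(reference, os.path.join(out_dir, "reference.fa"))
        write_sam(tumor, reference, os.path.join(out_dir, f"{sample}.tumor.sam"))
        write_sam(normal, reference, os.path.join(out_dir, f"{sample}.normal.sam"))
    return reference, tumor, normal


def write_sam(reads: Sequence[tuple], reference: Mapping[str, str],
              path: str) -> None:
    """Write reads as a coordinate-sorted SAM file.

    Each read is ``(chrom, start, seq)`` for an ungapped alignment or
    ``(chrom, start, seq, cigar)`` for a gapped (spliced) one.
    """
    import pysam

    chroms = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, read in enumerate(sorted(reads, key=lambda r: (r[0], r[1]))):
            chrom, start, seq = read[:3]
            cigar = read[3] if len(read) > 3 else f"{len(seq)}M"
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def spliced_read(tx: TranscriptModel, genome: Mapping[str, str], t0: int,
                 read_length: int) -> tuple[str, int, str, str]:
    """Project a read starting at spliced offset ``t0`` of an isoform onto
    the genome: returns (chrom, start, forward-strand seq, CIGAR with N gaps)."""
    blocks = tx.tx_to_genomic_blocks(t0, t0 + read_length)
    parts, seqs = [], []
    for j, (s, e) in enumerate(blocks):
        if j:
            parts.append(f"{s - blocks[j - 1][1]}N")
        parts.append(f"{e - s}M")
        seqs.append(str(genome[tx.chrom][s:e]))
    return tx.chrom, blocks[0][0], "".join(seqs), "".join(parts)


def simulate_isoform_reads(
    reads_per_isoform: Mapping[TranscriptModel, int],
    genome: Mapping[str, str],
    rng: np.random.Generator,
    read_length: int = 50,
) -> list[tuple[str, int, str, str]]:
    """Spliced reads drawn uniformly along each isoform — input for
    junction-support counting and informative-read assignment."""
    reads = []
    for tx, n in reads_per_isoform.items():
        hi = tx.spliced_length - read_length + 1
        if hi < 1:
            raise ValueError(f"{tx.transcript_id} shorter than the read length")
        for t0 in rng.integers(0, hi, size=n):
            reads.append(spliced_read(tx, genome, int(t0), read_length))
    return sorted(reads, key=lambda r: (r[0], r[1]))


# ---------------------------------------------------------------------------
# mutation roster and catalog generator
# ---------------------------------------------------------------------------

def generate_mutations(
    rng: np.random.Generator,
    n_patients: int = 18,
    n_mutations: int = 40,
    chrom: str = "chrV",
    region: tuple[int, int] = (1000, 40000),
    intronic_fraction: float = 0.6,
) -> list[ReportedMutation]:
    """A synthetic per-patient mutation roster with distinct positions.

    Every patient receives at least one mutation; the remainder are
    assigned uniformly.  Contexts are drawn intronic with the given
    fraction, exonic otherwise.
    """
    if n_mutations < n_patients:
        raise ValueError("need at least one mutation per patient")
    positions = rng.choice(np.arange(*region), size=n_mutations, replace=False)
    owners = list(range(n_patients)) + list(rng.integers(0, n_patients,
                                                         n_mutations - n_patients))
    rng.shuffle(owners)
    bases = np.array(list("ACGT"))
    muts = []
    for i, (pos, owner) in enumerate(zip(sorted(int(p) for p in positions), owners)):
        ref = str(rng.choice(bases))
        alt = str(rng.choice(bases[bases != ref]))
        context = "intronic" if rng.random() < intronic_fraction else "exonic"
        muts.append(ReportedMutation(
            patient_id=f"P{owner+1:02d}", chrom=chrom, pos=pos, ref=ref, alt=alt,
            context=context, label=f"mut{i+1}",
        ))
    return muts


def generate_catalog(
    mutations: Sequence[ReportedMutation],
    rng: np.random.Generator,
    overlap_fraction: float = 0.45,
    position_only_fraction: float = 0.2,
    n_padding: int = 50,
    ensure_patients_matched: Optional[int] = None,
    out_path: Optional[str] = None,
) -> tuple[list[tuple], set]:
    """Catalog entries engineered to overlap a controlled mutation fraction.

    Exactly ``round(overlap_fraction * n)`` distinct mutations receive an
    exact-allele entry; of the rest, ``position_only_fraction`` receive an
    entry at the same position with a different alternate base; padding
    entries are added at unrelated positions.  When
    ``ensure_patients_matched`` is set, the exact-matched set is chosen so
    that precisely that many patients own at least one matched mutation.
    Returns ``(entries, matched_keys)``; entries are (chrom, pos0, ref, alt)
    tuples, also written as a VCF when ``out_path`` is given.
    """
    muts = list({m.key: m for m in mutations}.values())
    n = len(muts)
    k = round(overlap_fraction * n)
    if ensure_patients_matched is None:
        matched = [muts[i] for i in rng.choice(n, size=k, replace=False)]
    else:
        m = ensure_patients_matched
        patients = sorted({mu.patient_id for mu in muts})
        if not 0 <= m <= len(patients) or k < m:
            raise ValueError("infeasible patient-match constraint")
        covered = [patients[i] for i in rng.choice(len(patients), size=m, replace=False)]
        pool = {p: [mu for mu in muts if mu.patient_id == p] for p in covered}
        matched = []
        for p in covered:
            pick = pool[p][int(rng.integers(0, len(pool[p])))]
            matched.append(pick)
        extra = [mu for p in covered for mu in pool[p] if mu not in matched]
        if k - m > len(extra):
            raise ValueError("not enough mutations among covered patients")
        if k - m:
            matched.extend(extra[i] for i in rng.choice(len(extra), size=k - m,
                                                        replace=False))
    matched_keys = {mu.key for mu in matched}
    entries = [(mu.chrom, mu.pos, mu.ref, mu.alt) for mu in matched]
    bases = np.array(list("ACGT"))
    used_positions = {(mu.chrom, mu.pos) for mu in muts}
    for mu in muts:
        if mu.key in matched_keys:
            continue
        if rng.random() < position_only_fraction:
            other = str(rng.choice(bases[(bases != mu.alt) & (bases != mu.ref)]))
            entries.append((mu.chrom, mu.pos, mu.ref, other))
    pad_chrom = muts[0].chrom if muts else "chrV"
    pad_pos = 10 ** 6
    for i in range(n_padding):
        pos = pad_pos + i * 37 + int(rng.integers(0, 10))
        if (pad_chrom, pos) in used_positions:
            continue
        ref = str(rng.choice(bases))
        alt = str(rng.choice(bases[bases != ref]))
        entries.append((pad_chrom, pos, ref, alt))
    entries.sort()
    if out_path is not None:
        write_catalog_vcf(entries, out_path)
    return entries, matched_keys


def write_catalog_vcf(entries: Sequence[tuple], path: str, source: str = "synthetic") -> None:
    """Write (chrom, pos0, ref, alt) entries as a minimal VCF 4.2 file."""
    chroms = sorted({e[0] for e in entries})
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source={source}\n")
        for c in chroms:
            out.write(f"##contig=<ID={c},length=2000000>\n")
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(entries):
            out.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
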