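"""Threshold-based somatic variant calling with matched-normal subtraction.

The caller reproduces a deliberately simple reanalysis scheme: per-site base
pileups over small target loci, a fixed calling rule (site depth >= 9 reads
and >= 2 reads supporting the alternate base, both at equality), and a
somatic definition by subtraction — a variant is somatic when called in the
tumor but not called, under the identical thresholds, in the patient-matched
normal.  The thresholds are calibrated for sensitivity by requiring that a
hotspot control mutation (KRAS codon G12/G13) is detected in every tumor
sample.  SNVs only; no base-quality filter is applied by default and no
minimum normal depth is required to assert absence (normals below the depth
floor are flagged ``low_coverage`` but do not veto the somatic call).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation import fetch_sequence

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

MIN_DEPTH_DEFAULT = 9
MIN_ALT_READS_DEFAULT = 2


@dataclass(frozen=True)
class TargetLocus:
    """A named genomic interval to pile up (0-based, half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.name}: require start < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


# hg19 gene loci used by the reanalysis (1-based inclusive in the source
# coordinates, stored 0-based half-open)
DEFAULT_LOCI = (
    TargetLocus("UPF1", "chr19", 18940304, 18979266),
    TargetLocus("KRAS", "chr12", 25356389, 25405419),
)

# KRAS codons 12-13 (hg19, minus strand): c.34-38 hotspot bases
KRAS_CONTROL_SITES = tuple(("chr12", p) for p in range(25398280, 25398286))


@dataclass
class SiteCall:
    """Per-site pileup summary with calling status."""

    chrom: str
    pos: int
    ref_base: str
    depth: int
    alt_counts: dict[str, int]
    called_alts: tuple[str, ...] = ()
    vaf_per_alt: dict[str, float] = field(default_factory=dict)


@dataclass
class SomaticCall:
    """One tumor alt allele after matched-normal subtraction."""

    site: SiteCall
    alt: str
    patient_id: str
    normal_status: str  # absent / present / low_coverage
    is_somatic: bool
    vaf: float
    gene: str = ""


@dataclass
class CalibrationReport:
    per_sample: dict[str, bool]
    overall_pass: bool
    failing_samples: tuple[str, ...]


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup_region(
    alignments: Iterable,
    locus: TargetLocus,
    reference: Optional[Mapping[str, object]] = None,
    min_baseq: Optional[int] = None,
    respect_duplicate_flag: bool = True,
) -> dict[int, dict[str, int]]:
    """Per-site A/C/G/T counts over a locus from aligned reads.

    ``alignments`` is an iterable of :class:`pysam.AlignedSegment`.  Aligned
    bases are counted at their reference positions; positions spanned by a
    read's deletions or splice gaps receive nothing from that read (they
    contribute neither depth nor alt).  Unmapped reads are skipped with a
    counter; reads flagged as duplicates are ignored when the input carries
    duplicate marks.  No base-quality filter is applied unless ``min_baseq``
    is set.
    """
    if reference is not None:
        if locus.chrom not in reference:
            raise ValueError(f"reference lacks {locus.chrom} for locus {locus.name}")
        if len(reference[locus.chrom]) < locus.end:
            raise ValueError(f"reference shorter than locus {locus.name}")
    counts: dict[int, dict[str, int]] = {}
    n_unmapped = 0
    for read in alignments:
        if read.is_unmapped:
            n_unmapped += 1
            continue
        if respect_duplicate_flag and read.is_duplicate:
            continue
        if read.reference_name != locus.chrom:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        quals = read.query_qualities if min_baseq is not None else None
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos < locus.start or rpos >= locus.end:
                continue
            if quals is not None and quals[qpos] < min_baseq:
                continue
            base = seq[qpos].upper()
            if base not in BASES:
                continue
            col = counts.setdefault(rpos, {b: 0 for b in BASES})
            col[base] += 1
    if n_unmapped:
        logger.info("pileup %s: skipped %d unmapped reads", locus.name, n_unmapped)
    return counts


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _site_call(chrom, pos, ref_base, col, min_depth, min_alt_reads) -> SiteCall:
    depth = sum(col.values())
    alt_counts = {b: c for b, c in col.items() if b != ref_base and c > 0}
    called = tuple(sorted(
        b for b, c in alt_counts.items()
        if depth >= min_depth and c >= min_alt_reads
    ))
    vafs = {b: alt_counts[b] / depth for b in called}
    return SiteCall(chrom, pos, ref_base, depth, alt_counts, called, vafs)


def call_variants(
    pileup: Mapping[int, Mapping[str, int]],
    locus: TargetLocus,
    reference: Mapping[str, object],
    min_depth: int = MIN_DEPTH_DEFAULT,
    min_alt_reads: int = MIN_ALT_READS_DEFAULT,
    emit_all_sites: bool = False,
) -> list[SiteCall]:
    """Apply the threshold rule to a pileup.

    An alternate base is called iff site depth >= ``min_depth`` and its
    supporting read count >= ``min_alt_reads``; multiple alts at one site
    are evaluated independently.  By default only sites with at least one
    called alt are returned.
    """
    if min_depth < 1 or min_alt_reads < 1:
        raise ValueError("thresholds must be >= 1")
    out = []
    for pos in sorted(pileup):
        ref_base = fetch_sequence(reference, locus.chrom, pos, pos + 1)
        call = _site_call(locus.chrom, pos, ref_base,
                          dict(pileup[pos]), min_depth, min_alt_reads)
        if call.called_alts or emit_all_sites:
            out.append(call)
    return out


def subtract_matched_normal(
    tumor_calls: Sequence[SiteCall],
    normal_pileup: Mapping[int, Mapping[str, int]],
    patient_id: str = "",
    min_depth: int = MIN_DEPTH_DEFAULT,
    min_alt_reads: int = MIN_ALT_READS_DEFAULT,
    gene: str = "",
) -> list[SomaticCall]:
    """Somatic = called in tumor, not called in the matched normal.

    The normal is evaluated under the identical thresholds.  A normal site
    below the depth floor cannot veto the call (the alt is still somatic by
    the literal subtraction rule) but is flagged ``low_coverage``.
    """
    if normal_pileup is None:
        raise ValueError(f"patient {patient_id}: missing matched normal pileup")
    out = []
    for site in tumor_calls:
        col = normal_pileup.get(site.pos, {b: 0 for b in BASES})
        normal_depth = sum(col.values())
        for alt in site.called_alts:
            alt_called_in_normal = (normal_depth >= min_depth
                                    and col.get(alt, 0) >= min_alt_reads)
            if alt_called_in_normal:
                status = "present"
            elif normal_depth < min_depth:
                status = "low_coverage"
            else:
                status = "absent"
            out.append(SomaticCall(
                site=site, alt=alt, patient_id=patient_id,
                normal_status=status, is_somatic=(status != "present"),
                vaf=site.vaf_per_alt[alt], gene=gene,
            ))
    return out


# ---------------------------------------------------------------------------
# calibration and summaries
# ---------------------------------------------------------------------------

def calibrate_sensitivity(
    calls_by_sample: Mapping[str, Sequence[SomaticCall]],
    control_sites: Sequence[tuple[str, int]],
    loci: Sequence[TargetLocus] = DEFAULT_LOCI,
) -> CalibrationReport:
    """Check that every tumor sample carries a somatic call at a control
    site (e.g. a KRAS G12/G13 hotspot) — the criterion used to fix the
    calling thresholds."""
    if not calls_by_sample:
        raise ValueError("empty sample set: nothing to calibrate against")
    control = set(control_sites)
    if not control:
        raise ValueError("no control sites given")
    for chrom, pos in control:
        if not any(l.contains(chrom, pos) for l in loci):
            raise ValueError(f"control site {chrom}:{pos} outside all target loci")
    per_sample = {}
    for sample, calls in calls_by_sample.items():
        per_sample[sample] = any(
            c.is_somatic and (c.site.chrom, c.site.pos) in control for c in calls
        )
    failing = tuple(s for s, ok in per_sample.items() if not ok)
    return CalibrationReport(per_sample, overall_pass=not failing, failing_samples=failing)


def summarize_af(calls_by_gene: Mapping[str, Sequence[SomaticCall]]) -> dict[str, float]:
    """Median VAF of somatic calls per gene (midpoint for even counts).
    Empty groups are omitted with a warning."""
    out = {}
    for gene, calls in calls_by_gene.items():
        vafs = [c.vaf for c in calls if c.is_somatic]
        if not vafs:
            warnings.warn(f"gene {gene}: no somatic calls; omitted from AF summary")
            continue
        out[gene] = float(np.median(vafs))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_loci_bed(path: str) -> list[TargetLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            loci.append(TargetLocus(name, chrom, start, end))
    return loci


def write_somatic_vcf(calls: Sequence[SomaticCall], path: str) -> None:
    """Write somatic calls as VCF 4.2 with DP/ALTC/VAF/NORMAL_STATUS INFO."""
    contigs = sorted({c.site.chrom for c in calls})
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=nmdmutscan\n")
        for chrom in contigs:
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Tumor site depth">\n')
        out.write('##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        out.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        out.write('##INFO=<ID=NORMAL_STATUS,Number=1,Type=String,'
                  'Description="Matched-normal status: absent/present/low_coverage">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sorted(calls, key=lambda c: (c.site.chrom, c.site.pos, c.alt))
        for c in ordered:
            if not c.is_somatic:
                continue
            info = (f"DP={c.site.depth};ALTC={c.site.alt_counts[c.alt]};"
                    f"VAF={c.vaf:.4f};NORMAL_STATUS={c.normal_status}")
            out.write(f"{c.site.chrom}\t{c.site.pos + 1}\t.\t{c.site.ref_base}\t"
                      f"{c.alt}\t.\tPASS\t{info}\n")


def write_calibration_tsv(report: CalibrationReport, path: str) -> None:
    with open(path, "w") as out:
        out.write("sample\tcontrol_detected\n")
        for sample, ok in report.per_sample.items():
            out.write(f"{sample}\t{ok}\n")
        out.write(f"#overall_pass\t{report.overall_pass}\n")


def write_af_summary_tsv(medians: Mapping[str, float], path: str) -> None:
    with open(path, "w") as out:
        out.write("gene\tmedian_vaf\n")
        for gene, vaf in medians.items():
            out.write(f"{gene}\t{vaf:.4f}\n")
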