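"""Overlap of reported tumor mutations with population variant catalogs.

Reported mutations (single-nucleotide, with genomic coordinates) are matched
against catalogs of standing genetic variation such as 1000 Genomes, ESP,
ExAC and gnomAD.  Each mutation receives one status:

``exact_allele``
    the catalog contains the same (chrom, pos, ref, alt) allele;
``in_reference``
    the mutation's supposed alternate base is the reference base itself
    (only detected when a reference FASTA is supplied, and only when there
    is no exact catalog match);
``position_only``
    the catalog holds variation at the position but with a different
    alternate base;
``none``
    no catalog variation at the position.

The headline summary fraction counts ``exact_allele`` matches over distinct
mutations; ``in_reference`` entries are tallied separately so they cannot
silently inflate the unmatched class.  Matching ignores catalog allele
frequencies unless a minimum frequency is requested.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import fetch_sequence

__all__ = [
    "ReportedMutation", "CatalogVariant", "OverlapReport",
    "load_catalog", "load_mutations_tsv", "match_mutations",
    "per_patient_overlap", "stratify_by_context",
    "write_overlap_tsv", "overlap_summary",
]

_SNV_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class ReportedMutation:
    """One reported tumor mutation (0-based position, single-base alleles)."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str  # intronic / exonic
    label: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.label or self.pos}: ref equals alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.label or self.pos}: alleles must be single bases")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CatalogVariant:
    """One population-catalog allele (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sources: tuple[str, ...] = ()
    allele_frequency: Optional[float] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class OverlapReport:
    """Per-mutation match statuses plus summary fractions."""

    rows: list[tuple[ReportedMutation, str]]
    n_distinct: int
    n_exact: int
    n_position_only: int
    n_in_reference: int

    @property
    def fraction_exact(self) -> float:
        return self.n_exact / self.n_distinct if self.n_distinct else 0.0

    @property
    def fraction_any_position(self) -> float:
        return ((self.n_exact + self.n_position_only) / self.n_distinct
                if self.n_distinct else 0.0)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_catalog(vcf_paths, min_af: Optional[float] = None) -> dict[tuple, CatalogVariant]:
    """Load one or more catalog VCFs into a deduplicated SNV dictionary.

    Multi-allelic records are decomposed to one entry per alternate allele;
    non-SNV records are skipped with a counter; the same allele seen in
    several files keeps a merged source list.
    """
    from cyvcf2 import VCF

    if isinstance(vcf_paths, (str, os.PathLike)):
        vcf_paths = [vcf_paths]
    catalog: dict[tuple, CatalogVariant] = {}
    n_non_snv = 0
    for path in vcf_paths:
        source = os.path.basename(str(path)).removesuffix(".gz").removesuffix(".vcf")
        for rec in VCF(str(path)):
            ref = rec.REF.upper()
            af = rec.INFO.get("AF")
            alts = rec.ALT or []
            for i, alt in enumerate(alts):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _SNV_BASES or alt not in _SNV_BASES:
                    n_non_snv += 1
                    continue
                freq = None
                if af is not None:
                    freq = float(af[i]) if isinstance(af, (tuple, list)) else float(af)
                    if min_af is not None and freq < min_af:
                        continue
                key = (rec.CHROM, rec.POS - 1, ref, alt)
                if key in catalog:
                    existing = catalog[key]
                    if source not in existing.sources:
                        existing.sources = existing.sources + (source,)
                else:
                    catalog[key] = CatalogVariant(rec.CHROM, rec.POS - 1, ref, alt,
                                                  sources=(source,), allele_frequency=freq)
    if n_non_snv:
        warnings.warn(f"skipped {n_non_snv} non-SNV catalog alleles")
    return catalog


def load_mutations_tsv(path) -> list[ReportedMutation]:
    """Read a mutation table (patient_id, chrom, pos, ref, alt, context[, label]);
    ``pos`` is 0-based as written by this package."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    muts = []
    for row in df.itertuples(index=False):
        muts.append(ReportedMutation(
            patient_id=str(row.patient_id), chrom=str(row.chrom), pos=int(row.pos),
            ref=str(row.ref).upper(), alt=str(row.alt).upper(),
            context=str(row.context), label=str(getattr(row, "label", "")),
        ))
    return muts


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_mutations(
    mutations: Sequence[ReportedMutation],
    catalog: Mapping[tuple, CatalogVariant],
    reference: Optional[Mapping[str, object]] = None,
) -> OverlapReport:
    """Assign each mutation a match status against the catalog.

    Statuses follow the precedence exact_allele > in_reference >
    position_only > none.  Summary counts are over distinct
    (chrom, pos, ref, alt) mutations: a mutation reported by several
    patients is counted once at the mutation level.
    """
    positions = {(v.chrom, v.pos) for v in catalog.values()}
    rows = []
    status_by_key: dict[tuple, str] = {}
    for mut in mutations:
        if mut.key in catalog:
            status = "exact_allele"
        elif (reference is not None
              and fetch_sequence(reference, mut.chrom, mut.pos, mut.pos + 1) == mut.alt):
            status = "in_reference"
        elif (mut.chrom, mut.pos) in positions:
            status = "position_only"
        else:
            status = "none"
        rows.append((mut, status))
        status_by_key[mut.key] = status
    counts = {"exact_allele": 0, "position_only": 0, "in_reference": 0, "none": 0}
    for status in status_by_key.values():
        counts[status] += 1
    return OverlapReport(
        rows=rows,
        n_distinct=len(status_by_key),
        n_exact=counts["exact_allele"],
        n_position_only=counts["position_only"],
        n_in_reference=counts["in_reference"],
    )


def per_patient_overlap(
    report: OverlapReport,
    roster: Optional[Mapping[str, Sequence[ReportedMutation]]] = None,
) -> tuple[dict[str, bool], float]:
    """Per-patient flag (>=1 exact-allele match among the patient's
    mutations) and the cohort fraction of flagged patients.

    The roster defaults to grouping the report's mutations by patient id;
    patients with zero mutations are excluded with a warning.
    """
    status_by_key = {mut.key: status for mut, status in report.rows}
    if roster is None:
        roster = {}
        for mut, _status in report.rows:
            roster.setdefault(mut.patient_id, []).append(mut)
    flags = {}
    for patient, muts in roster.items():
        if not muts:
            warnings.warn(f"patient {patient} has no mutations; excluded")
            continue
        flags[patient] = any(status_by_key.get(m.key) == "exact_allele" for m in muts)
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, fraction


def stratify_by_context(report: OverlapReport) -> pd.DataFrame:
    """Match fractions split by genic context (intronic vs exonic)."""
    rows = []
    for mut, status in report.rows:
        if mut.context not in ("intronic", "exonic"):
            raise ValueError(f"mutation {mut.label or mut.pos} lacks a valid context "
                             f"(got {mut.context!r})")
        rows.append((mut.context, mut.key, status))
    if not rows:
        return pd.DataFrame(columns=["context", "n", "n_exact", "fraction_exact"])
    df = pd.DataFrame(rows, columns=["context", "key", "status"]).drop_duplicates("key")
    out = []
    for context, grp in df.groupby("context"):
        n = len(grp)
        n_exact = int((grp["status"] == "exact_allele").sum())
        out.append((context, n, n_exact, n_exact / n))
    return pd.DataFrame(out, columns=["context", "n", "n_exact", "fraction_exact"])


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_overlap_tsv(report: OverlapReport, path: str) -> None:
    with open(path, "w") as out:
        out.write("patient_id\tchrom\tpos\tref\talt\tcontext\tlabel\tstatus\n")
        for mut, status in report.rows:
            out.write("\t".join([mut.patient_id, mut.chrom, str(mut.pos), mut.ref,
                                 mut.alt, mut.context, mut.label, status]) + "\n")


def overlap_summary(report: OverlapReport,
                    roster: Optional[Mapping[str, Sequence[ReportedMutation]]] = None) -> dict:
    flags, patient_fraction = per_patient_overlap(report, roster)
    context = stratify_by_context(report)
    return {
        "n_mutations": report.n_distinct,
        "n_exact": report.n_exact,
        "n_position_only": report.n_position_only,
        "n_in_reference": report.n_in_reference,
        "fraction_exact": report.fraction_exact,
        "n_patients": len(flags),
        "n_patients_matched": int(sum(flags.values())),
        "fraction_patients_matched": patient_fraction,
        "per_context": {row.context: {"n": int(row.n), "n_exact": int(row.n_exact),
                                      "fraction_exact": float(row.fraction_exact)}
                        for row in context.itertuples(index=False)},
    }


def write_overlap_summary_json(report: OverlapReport, path: str, roster=None) -> None:
    with open(path, "w") as out:
        json.dump(overlap_summary(report, roster), out, indent=2)
        out.write("\n")
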