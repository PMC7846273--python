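# Methods

This note documents the models and procedures `nmdmutscan` implements, the
conventions it fixes where the underlying rules are stated only loosely,
and what its synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based, half-open; GTF and VCF keep their
native 1-based conventions and are converted at the I/O boundary. SAM is
read and written through pysam, catalogs through cyvcf2, genomes through
pyfaidx (or any mapping of chromosome name to sequence). The stored CDS
interval of a transcript *includes* the termination codon (GTF
`stop_codon` features are folded into the CDS on parsing).

## NMD-substrate annotation (the 50-nt rule)

An isoform is a predicted NMD substrate when its termination codon lies
more than 50 nt upstream of the last exon–exon junction, measured in
spliced (mRNA) coordinates. Conventions fixed here:

- The distance is measured from the **last (3') base** of the stop codon to
  the last exonic base preceding the final junction:
  `distance_nt = last_junction_tx_pos − stop_codon_tx_pos`. A transcript
  with `distance_nt = 50` is *not* a substrate; `51` is. The boundary is
  exercised exactly in the tests. (Measuring from the first stop base
  instead would shift every distance by 2 nt; the convention is stated so
  results are reproducible.)
- The termination codon comes from the annotated CDS when present;
  otherwise, when a genome is supplied, from the ORF starting at the
  5'-most AUG of the spliced sequence, reading in-frame to the first stop.
  Annotated CDS is the least surprising default; the fallback covers
  annotation-free isoform fragments.
- Single-exon transcripts are never substrates (there is no junction).
  Transcripts with no determinable ORF are flagged `no_orf` and classified
  non-substrate — never a silent default.

Splice junctions are enumerated as **all co-linear combinations** of the
gene's donor and acceptor sites, pooled over its transcripts and
deduplicated on (chrom, donor, acceptor, strand). This deliberately
includes junctions absent from every annotated isoform (e.g. a double-exon
skip), which is what makes junction-level read support informative for
unannotated splicing outcomes.

Intron typing is conservative: GT..AG termini → U2 (major spliceosome),
AT..AC → U12 (minor), everything else — including the rare genuine GC-AG
donors and any non-ACGT sequence — `unknown` and excluded downstream, so
intron type cannot confound the differential analysis. An event is U2-class
only when every intron of every child isoform is U2.

A splicing event is **NMD relevant** iff at least one, but not all, of its
child isoforms is a predicted substrate.

## PSI estimation and the differential filter

A read is *informative* for an event when its gapped alignment touches a
splice junction or exonic base diagnostic for exactly one child isoform;
reads consistent with several children, or with none, are discarded. PSI is
a length-normalized count ratio: with `r_i` informative reads over `m_i`
informative positions per child, `psi = (r_inc/m_inc) / Σ_i (r_i/m_i)` for
the inclusion (first) child. `m_i` is computed by sliding a read of the
observed length along the child's spliced sequence and counting start
positions that yield an informative alignment. This is a deterministic
point estimator standing in the place a Bayesian posterior-inference tool
would occupy in a production RNA-seq pipeline; it is unbiased for the
planted value under the binomial sampling model of the simulator (verified
to 0.03 at depth 200 in the tests).

The differential filter applies three criteria:

1. **Informative-read floor**: ≥ 20 informative reads, by default required
   of *every* sample (strictest reading; configurable to a summed total via
   `min_reads_scope="total"`, since per-sample vs pooled application is
   genuinely ambiguous).
2. **Effect size**: |ΔΨ| ≥ 0.10 (inclusive, compared with a 1e-12 float
   guard) *or* a fold-change criterion on the inclusion isoform's read
   density. Two fold-change readings circulate for this kind of filter —
   linear `max(FC, 1/FC) ≥ 2` and `|log2 FC| ≥ 2`; both are implemented
   (`fc_scale={"linear","log2"}`) with linear as the default.
3. **Significance**: two-sided t-test on per-replicate PSI, p ≤ 0.05,
   Student pooled-variance by default (Welch by flag), and **no multiple
   testing correction** — the filter intentionally uses raw p-values, so
   its null behavior is the nominal 5% rate (verified at 0.05 ± 0.02 over
   2,000 null events).

Degenerate t-test inputs follow fixed conventions: both samples constant
with equal means → p = 1; constant with unequal means → p = 0.

The burden summary counts significant NMD-relevant U2-class events per
event type (SE, RI, A5SS, A3SS, MXE), split by whether the NMD-substrate
child rose (`nmd_up`) or fell (`nmd_down`) in the test condition; each
event counts once.

## Threshold somatic calling

The caller mirrors a deliberately simple sensitivity-first reanalysis
scheme rather than a genotype-likelihood model:

- Pileups count A/C/G/T from aligned bases only; positions spanned by a
  read's deletion or splice gap receive neither depth nor alt from that
  read. No base-quality filter is applied by default (`min_baseq`
  available); duplicate-flagged reads are ignored when the input carries
  duplicate marks, otherwise all reads count.
- An alt is called iff site depth ≥ 9 **and** alt-supporting reads ≥ 2,
  both at equality; each alt at a multi-allelic site is evaluated
  independently. The exact boundary — (9, 2) calls, (8, 2) and (9, 1) do
  not — is asserted in the tests, and calls are monotone in both
  thresholds.
- **Somatic** means called in tumor and not called, under the identical
  thresholds, in the patient-matched normal. No minimum normal depth is
  required to assert absence: a normal below the depth floor cannot veto
  the call, but the call is flagged `low_coverage` rather than `absent` so
  downstream users can see the weaker evidence. SNVs only; indels are out
  of scope.
- Calibration follows the scheme's own logic: thresholds are adequate when
  a hotspot control mutation (KRAS codon G12/G13-style) is detected in
  every tumor sample. Default hg19 loci for UPF1
  (chr19:18,940,305–18,979,266) and KRAS (chr12:25,356,390–25,405,419) are
  shipped, converted to 0-based internally.
- Per-gene allele-frequency summaries report the median of per-call VAFs
  (midpoint for even counts).

## Catalog overlap

Reported mutations are matched to population catalogs on genomic
coordinates — (chrom, pos, ref, alt) for `exact_allele`, position with a
different alt for `position_only`. A mutation whose claimed alternate base
equals the reference base (detectable only when a FASTA is supplied) gets
the dedicated status `in_reference` instead of silently inflating the
unmatched class; the headline match fraction counts `exact_allele` only,
with `in_reference` tallied separately. Multi-allelic catalog records are
decomposed; duplicates across files merge their source lists; matching
ignores allele frequency unless a minimum is requested. HGVS-style labels
(e.g. `IVS10+31G>A`) are carried as opaque strings — coordinates, not
nomenclature, are the matching key. Mutation-level summaries count each
distinct variant once even when several patients report it; patient-level
summaries flag a patient when ≥ 1 of their mutations matches exactly.

## Cohort statistics

The "binomial proportion test" is implemented as the pooled two-proportion
z-test without continuity correction, with Fisher's exact test as the
alternative; the headline cohort comparison (0/34 vs 18/23) is significant
at p < 10⁻⁸ under both, so the conclusion does not hinge on the variant.
Degenerate pooled proportions (0 or 1) return p = 1. Mann–Whitney U uses
the exact null distribution for combined n ≤ 20 without ties and the
tie-corrected normal approximation otherwise.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code and define the conditions under
which the pipeline's operating characteristics are measured:

- **Gene models**: two-isoform events of all five types with stop codons
  placed at chosen distances from the final junction (substrate children at
  60–120 nt, non-substrates at −40 to +29 nt, plus dedicated exact-boundary
  genes at 50 and 51 nt); introns carry planted GT..AG termini. Truth is
  known by construction.
- **Event counts**: informative reads split binomially with inclusion
  probability `psi·m_inc / (psi·m_inc + (1−psi)·m_exc)`, 3 replicates per
  group and ~200 informative reads per event by default — a clean
  binomial-sampling regime.
- **Alignments**: 50-nt reads tiling small loci at stride 1, repeated until
  coverage reaches the requested depth (default 60×, matched to exome-like
  coverage of short target regions); each covering read carries a planted
  alt independently with probability VAF, so alt counts are binomial.
  Germline variants go into both samples, somatic into the tumor only.
  Sequencing error is off by default — the calling thresholds are the
  object under test — with an optional per-base substitution rate for
  stress-testing.
- **Catalogs**: exactly `round(fraction·n)` mutations receive exact-allele
  entries (optionally constrained to cover an exact number of patients),
  a configurable share of the rest get position-only entries, plus padding
  at unrelated positions.

Everything is driven by `numpy.random.default_rng(seed)`; a fixed seed
regenerates byte-identical files.

What passing these tests shows: the implementation applies its stated rules
exactly, and under clean binomial sampling its sensitivity, specificity and
calibration match theory. What it does not show: robustness to alignment
artifacts, indels, strand bias, non-uniform coverage, sequencing-error
hotspots, or annotation errors — none of which the generators model.

## Validation-study sizes

The seeded studies in `nmdmutscan.validation` use 1,000 random transcript
models for the 50-nt-rule oracle comparison; 200 tumor/normal pairs (60×
coverage, somatic VAF drawn in [0.2, 0.5], germline VAF 0.5) for somatic
recovery; 2,000 null and 100 shifted events (ΔΨ = −0.3, depth 200, 3 vs 3)
for the differential filter; a 40-mutation, 18-patient roster at 45%
overlap covering 16 patients for the catalog stage; and 51 planted variants
per gene at 400× coverage (subclonal around 12%, clonal around 34%) for the
median-VAF recovery, sized so the recovered medians' sampling error is well
inside the planted contrast.

## Known limitations

- The PSI estimator is a point estimate; no posterior uncertainty is
  propagated into the t-test beyond replicate variance.
- The caller has no error model: at very high depth, a 2-read floor will
  call sequencing errors; the thresholds reproduce a sensitivity-first
  design, not a precision-first one.
- ORF derivation considers only the 5'-most AUG; uORFs, non-AUG starts and
  selenoprotein recoding are ignored.
- Event typing covers binary two-isoform events; complex multi-way events
  are out of scope.
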