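"""PSI quantification from informative reads and the differential-splicing filter.

A read is *informative* for a splicing event when its alignment is consistent
with exactly one child isoform: it touches a splice junction or an exonic
position that is diagnostic for (present in) that child only.  Reads that
touch no diagnostic feature, or features of more than one child, are
discarded as uninformative.

PSI is estimated as a length-normalized count ratio over informative
positions rather than by Bayesian posterior inference: with ``r_i``
informative reads over ``m_i`` informative positions per child,
``psi = (r_inc/m_inc) / sum_i (r_i/m_i)`` for the inclusion (first) child.

The differential filter applies three criteria jointly: an informative-read
floor (>=20, by default required of every sample), an effect-size criterion
(|delta psi| >= 0.10 or fold-change, linear >=2 by default with a log2 scale
available), and a two-sided t-test at p <= 0.05 on per-replicate PSI with no
multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import NMDAnnotation, SpliceJunction, SplicingEvent
from .cohort_stats import two_sided_t_test

__all__ = [
    "EventQuant", "FilterConfig", "DifferentialResult",
    "diagnostic_features", "informative_positions", "count_informative_reads",
    "estimate_psi", "test_differential", "summarize_nmd_burden",
    "load_counts_tsv", "write_counts_tsv", "write_differential_tsv",
]


@dataclass
class EventQuant:
    """Per-sample informative read counts for one event.

    ``reads``/``positions`` map child isoform ids to informative read counts
    and informative position counts; ``psi`` is filled by
    :func:`estimate_psi` and stays ``None`` when no informative read exists.
    """

    event_id: str
    sample_id: str
    reads: dict[str, int]
    positions: dict[str, int]
    psi: Optional[float] = None
    junction_support: dict[tuple, int] = field(default_factory=dict)
    n_uninformative: int = 0

    @property
    def total_informative(self) -> int:
        return sum(self.reads.values())


@dataclass
class FilterConfig:
    """Thresholds of the differential-splicing filter."""

    min_informative_reads: int = 20
    min_reads_scope: str = "per_sample"  # or "total"
    min_delta_psi: float = 0.10
    min_fold_change: float = 2.0
    fc_scale: str = "linear"  # or "log2"
    alpha: float = 0.05
    t_test: str = "pooled"  # or "welch"

    def __post_init__(self):
        if self.min_reads_scope not in ("per_sample", "total"):
            raise ValueError("min_reads_scope must be 'per_sample' or 'total'")
        if self.fc_scale not in ("linear", "log2"):
            raise ValueError("fc_scale must be 'linear' or 'log2'")


@dataclass
class DifferentialResult:
    event_id: str
    mean_psi_a: Optional[float]
    mean_psi_b: Optional[float]
    delta_psi: Optional[float]
    fold_change: Optional[float]
    p_value: Optional[float]
    passes_filter: bool
    direction: str = "none"  # nmd_up / nmd_down / none, for the NMD-substrate child
    excluded: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# informative-read counting
# ---------------------------------------------------------------------------

def diagnostic_features(event: SplicingEvent) -> dict[str, tuple[set, set]]:
    """Per child: (diagnostic junctions, diagnostic exonic positions).

    A junction or exonic base is diagnostic for a child when it occurs in
    that child and in no other child of the event.
    """
    jx_sets = {c.transcript_id: {j.intron_interval() for j in c.junctions()}
               for c in event.children}
    pos_sets = {c.transcript_id: {p for s, e in c.exons for p in range(s, e)}
                for c in event.children}
    out = {}
    for c in event.children:
        cid = c.transcript_id
        other_jx = set().union(*(jx_sets[o] for o in jx_sets if o != cid))
        other_pos = set().union(*(pos_sets[o] for o in pos_sets if o != cid))
        out[cid] = (jx_sets[cid] - other_jx, pos_sets[cid] - other_pos)
    return out


def _read_evidence(blocks: Sequence[tuple[int, int]]):
    """Junction intervals and covered positions of one gapped alignment."""
    junctions = set()
    positions = set()
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 > e1:
            junctions.add((e1, s2))
    for s, e in blocks:
        positions.update(range(s, e))
    return junctions, positions


def _assign_read(blocks, features) -> Optional[str]:
    jx, pos = _read_evidence(blocks)
    hits = [cid for cid, (djx, dpos) in features.items()
            if (jx & djx) or (pos & dpos)]
    return hits[0] if len(hits) == 1 else None


def informative_positions(event: SplicingEvent, read_length: int) -> dict[str, int]:
    """Number of distinct read placements on each child that yield an
    informative read of the given length — the per-child normalizer of the
    PSI estimator."""
    features = diagnostic_features(event)
    out = {}
    for child in event.children:
        n = 0
        for t0 in range(0, child.spliced_length - read_length + 1):
            blocks = child.tx_to_genomic_blocks(t0, t0 + read_length)
            if _assign_read(blocks, features) == child.transcript_id:
                n += 1
        out[child.transcript_id] = n
    return out


def count_informative_reads(
    alignments: Iterable,
    event: SplicingEvent,
    junctions: Optional[Sequence[SpliceJunction]] = None,
    sample_id: str = "sample",
    read_length: Optional[int] = None,
) -> EventQuant:
    """Assign gapped alignments to child isoforms of one event.

    ``alignments`` is an iterable of :class:`pysam.AlignedSegment` (e.g. a
    ``pysam.AlignmentFile``).  Each read counts for at most one child; reads
    consistent with several children, or touching no diagnostic feature, are
    uninformative.  When a junction database is given, per-junction support
    counts are tallied as well.  Alignments on other chromosomes are skipped
    and counted.
    """
    features = diagnostic_features(event)
    reads = {c.transcript_id: 0 for c in event.children}
    jx_support: dict[tuple, int] = {}
    jx_index = {}
    if junctions is not None:
        for j in junctions:
            jx_index[(j.chrom, j.intron_interval())] = (j.chrom, j.donor, j.acceptor, j.strand)
            jx_support[(j.chrom, j.donor, j.acceptor, j.strand)] = 0
    n_uninformative = 0
    n_skipped = 0
    lengths = []
    for read in alignments:
        if read.is_unmapped:
            continue
        if read.reference_name != event.chrom:
            n_skipped += 1
            continue
        blocks = read.get_blocks()
        if not blocks:
            continue
        lengths.append(read.query_length or sum(e - s for s, e in blocks))
        read_jx, _ = _read_evidence(blocks)
        for interval in read_jx:
            key = jx_index.get((read.reference_name, interval))
            if key is not None:
                jx_support[key] += 1
        assigned = _assign_read(blocks, features)
        if assigned is None:
            n_uninformative += 1
        else:
            reads[assigned] += 1
    if read_length is None:
        read_length = int(np.median(lengths)) if lengths else 0
    positions = (informative_positions(event, read_length)
                 if read_length > 0 else {c.transcript_id: 1 for c in event.children})
    # a child that no read placement can distinguish gets normalizer 1 so
    # that its (necessarily zero) count is still well-defined
    positions = {cid: max(1, n) for cid, n in positions.items()}
    return EventQuant(
        event_id=event.event_id, sample_id=sample_id, reads=reads,
        positions=positions, junction_support=jx_support,
        n_uninformative=n_uninformative,
    )


# ---------------------------------------------------------------------------
# PSI estimation
# ---------------------------------------------------------------------------

def estimate_psi(quant: EventQuant, inclusion_id: Optional[str] = None) -> Optional[float]:
    """Length-normalized PSI of the inclusion child (first child by default).

    Returns ``None`` (and leaves ``quant.psi`` unset) when the event has no
    informative reads in this sample.
    """
    ids = list(quant.reads)
    if inclusion_id is None:
        inclusion_id = ids[0]
    if quant.total_informative == 0:
        quant.psi = None
        return None
    densities = {}
    for cid in ids:
        m = quant.positions.get(cid, 0)
        if m <= 0:
            raise ValueError(f"{quant.event_id}: nonpositive informative positions for {cid}")
        densities[cid] = quant.reads[cid] / m
    total = sum(densities.values())
    psi = densities[inclusion_id] / total
    quant.psi = psi
    return psi


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def _inclusion_id(quants: Sequence[EventQuant]) -> str:
    return next(iter(quants[0].reads))


def _meets_floor(quants: Sequence[EventQuant], config: FilterConfig) -> bool:
    if config.min_reads_scope == "per_sample":
        return all(q.total_informative >= config.min_informative_reads for q in quants)
    return sum(q.total_informative for q in quants) >= config.min_informative_reads


def test_differential(
    group_a: Sequence[EventQuant],
    group_b: Sequence[EventQuant],
    config: Optional[FilterConfig] = None,
    event: Optional[SplicingEvent] = None,
    nmd_annotations: Optional[Mapping[str, NMDAnnotation]] = None,
) -> DifferentialResult:
    """Apply the three-part differential filter to one event.

    Events failing the informative-read floor, or with fewer than two
    replicates of defined PSI in either group, are excluded before testing.
    ``delta_psi`` is mean(B) − mean(A); the fold change is the ratio of mean
    inclusion-isoform read densities B/A.  When the event and per-child NMD
    annotations are supplied, ``direction`` reports whether the
    NMD-substrate child rose or fell in group B.
    """
    config = config or FilterConfig()
    event_id = group_a[0].event_id if group_a else (group_b[0].event_id if group_b else "?")

    def _excluded(reason):
        return DifferentialResult(event_id, None, None, None, None, None,
                                  passes_filter=False, excluded=True, reason=reason)

    if len(group_a) < 2 or len(group_b) < 2:
        return _excluded("fewer than 2 replicates")
    if not _meets_floor(list(group_a) + list(group_b), config):
        return _excluded("informative-read floor not met")

    inc = _inclusion_id(list(group_a) + list(group_b))
    psis_a = [estimate_psi(q, inc) if q.psi is None else q.psi for q in group_a]
    psis_b = [estimate_psi(q, inc) if q.psi is None else q.psi for q in group_b]
    if any(p is None for p in psis_a + psis_b):
        return _excluded("undefined PSI in a replicate")

    mean_a, mean_b = float(np.mean(psis_a)), float(np.mean(psis_b))
    delta = mean_b - mean_a

    dens_a = [q.reads[inc] / q.positions[inc] for q in group_a]
    dens_b = [q.reads[inc] / q.positions[inc] for q in group_b]
    ma, mb = float(np.mean(dens_a)), float(np.mean(dens_b))
    if ma == 0 and mb == 0:
        fc = 1.0
    elif ma == 0 or mb == 0:
        fc = math.inf if ma == 0 else 0.0
    else:
        fc = mb / ma

    if config.fc_scale == "linear":
        fc_met = max(fc, (1 / fc) if fc > 0 else math.inf) >= config.min_fold_change
    else:
        fc_met = (fc in (0.0, math.inf)) or abs(math.log2(fc)) >= config.min_fold_change

    p = two_sided_t_test(psis_a, psis_b, variant=config.t_test)
    # inclusive >= bound, robust to float rounding of count ratios
    delta_met = abs(delta) >= config.min_delta_psi - 1e-12
    passes = (delta_met or fc_met) and p <= config.alpha

    direction = "none"
    if passes and event is not None and nmd_annotations is not None:
        if classify_relevance_safe(event, nmd_annotations):
            nmd_children = [c.transcript_id for c in event.children
                            if nmd_annotations[c.transcript_id].is_nmd_substrate]
            nmd_is_inclusion = inc in nmd_children
            up = delta > 0 if nmd_is_inclusion else delta < 0
            direction = "nmd_up" if up else "nmd_down"

    return DifferentialResult(event_id, mean_a, mean_b, delta, fc, p,
                              passes_filter=passes, direction=direction)


def classify_relevance_safe(event, annotations) -> bool:
    from .annotation import classify_event_nmd_relevance
    if event.nmd_relevant is not None:
        return event.nmd_relevant
    return classify_event_nmd_relevance(event, annotations)


def summarize_nmd_burden(
    results: Sequence[DifferentialResult],
    events: Mapping[str, SplicingEvent],
) -> pd.DataFrame:
    """Counts of significant NMD-relevant events, per event type, split by
    whether the NMD-substrate isoform rose (nmd_up) or fell (nmd_down) in
    the test condition.  Restricted to U2-type events; each event counts
    once.
    """
    from .annotation import EVENT_TYPES
    table = pd.DataFrame(0, index=list(EVENT_TYPES), columns=["nmd_up", "nmd_down"])
    seen = set()
    for res in results:
        if not res.passes_filter or res.direction == "none" or res.event_id in seen:
            continue
        ev = events.get(res.event_id)
        if ev is None or not ev.nmd_relevant or ev.intron_class != "U2":
            continue
        seen.add(res.event_id)
        table.loc[ev.event_type, res.direction] += 1
    return table


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_counts_tsv(quants: Sequence[EventQuant], path: str) -> None:
    rows = []
    for q in quants:
        for cid in q.reads:
            rows.append((q.event_id, q.sample_id, cid, q.reads[cid], q.positions[cid]))
    pd.DataFrame(rows, columns=["event_id", "sample_id", "isoform_id", "reads", "positions"]) \
        .to_csv(path, sep="\t", index=False)


def load_counts_tsv(path) -> list[EventQuant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (eid, sid), grp in df.groupby(["event_id", "sample_id"], sort=False):
        out.append(EventQuant(
            event_id=str(eid), sample_id=str(sid),
            reads=dict(zip(grp["isoform_id"], grp["reads"].astype(int))),
            positions=dict(zip(grp["isoform_id"], grp["positions"].astype(int))),
        ))
    return out


def write_differential_tsv(results: Sequence[DifferentialResult], path: str) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, sep="\t", index=False, na_rep="NA")
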