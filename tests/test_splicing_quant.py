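"""Informative-read assignment, the PSI estimator and the differential filter."""

import numpy as np
import pytest

from nmdmutscan.annotation import NMDAnnotation, SplicingEvent, enumerate_junctions
from nmdmutscan.splicing_quant import (EventQuant, FilterConfig,
                                       count_informative_reads,
                                       diagnostic_features, estimate_psi,
                                       summarize_nmd_burden)
from nmdmutscan.splicing_quant import test_differential as run_differential
from nmdmutscan.synthetic_data import (simulate_event_counts, spliced_read,
                                       write_sam)

from conftest import make_transcript


def quant(inc, exc, positions=(1, 1), event_id="ev", sample_id="s"):
    return EventQuant(event_id, sample_id,
                      reads={"inc": inc, "exc": exc},
                      positions={"inc": positions[0], "exc": positions[1]})


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

class TestCountInformativeReads:
    GENOME = {"chr1": "ACGT" * 175}

    def _sam(self, tmp_path, reads):
        path = tmp_path / "ev.sam"
        write_sam(reads, self.GENOME, str(path))
        return str(path)

    def test_planted_junction_reads_recovered(self, tmp_path, se_event_parts):
        """7 reads across the inclusion junction and 3 across the skipping
        junction come back as counts (7, 3); junction support matches."""
        import pysam
        inc, exc = se_event_parts
        ev = SplicingEvent("ev", "SE", (inc, exc))
        reads = [spliced_read(inc, self.GENOME, 51 + i, 50) for i in range(7)]
        reads += [spliced_read(exc, self.GENOME, 60 + i, 50) for i in range(3)]
        reads += [spliced_read(inc, self.GENOME, 0, 50),  # shared exon: uninformative
                  spliced_read(exc, self.GENOME, 10, 50)]
        jxs = enumerate_junctions([inc, exc])
        with pysam.AlignmentFile(self._sam(tmp_path, reads)) as fh:
            q = count_informative_reads(fh, ev, junctions=jxs)
        assert q.reads == {"inc": 7, "exc": 3}
        assert q.n_uninformative == 2
        assert q.junction_support[("chr1", 100, 200, "+")] == 7
        assert q.junction_support[("chr1", 100, 400, "+")] == 3

    def test_wrong_chromosome_reads_skipped(self, tmp_path, se_event_parts):
        import pysam
        inc, exc = se_event_parts
        ev = SplicingEvent("ev", "SE", (inc, exc))
        genome = dict(self.GENOME, chr9="A" * 700)
        reads = [spliced_read(inc, self.GENOME, 51, 50),
                 ("chr9", 10, "A" * 50)]
        path = tmp_path / "x.sam"
        write_sam(reads, genome, str(path))
        with pysam.AlignmentFile(str(path)) as fh:
            q = count_informative_reads(fh, ev)
        assert q.reads == {"inc": 1, "exc": 0}

    def test_exclusion_has_only_junction_evidence(self, se_event_parts):
        inc, exc = se_event_parts
        feats = diagnostic_features(SplicingEvent("ev", "SE", (inc, exc)))
        assert feats["exc"][1] == set()          # no exclusive exonic base
        assert feats["exc"][0] == {(100, 400)}   # the skip junction
        assert feats["inc"][1] == set(range(200, 300))


# ---------------------------------------------------------------------------
# PSI estimator
# ---------------------------------------------------------------------------

class TestEstimatePsi:
    def test_all_inclusion_reads(self):
        assert estimate_psi(quant(25, 0)) == 1.0

    def test_symmetric_counts_and_lengths(self):
        assert estimate_psi(quant(10, 10)) == 0.5

    def test_length_normalization(self):
        # 30 reads over 3 positions vs 10 over 1: densities equal -> 0.5
        assert estimate_psi(quant(30, 10, positions=(3, 1))) == 0.5

    def test_zero_reads_flagged_undefined(self):
        q = quant(0, 0)
        assert estimate_psi(q) is None and q.psi is None

    def test_recovers_planted_psi_at_depth(self, rng):
        """Mean estimate within 0.03 of truth for psi 0.1..0.9 at depth 200."""
        for psi_true in np.arange(0.1, 0.95, 0.1):
            ga, _gb, _ = simulate_event_counts(
                [f"e{psi_true:.1f}"], [psi_true], [psi_true], rng,
                n_replicates=500, depth=200, positions=(3, 2))
            ests = [estimate_psi(q) for q in next(iter(ga.values()))]
            assert abs(np.mean(ests) - psi_true) < 0.03


# ---------------------------------------------------------------------------
# differential filter
# ---------------------------------------------------------------------------

class TestDifferentialFilter:
    def test_informative_read_floor_excludes(self):
        """An event with 19 informative reads in any sample is excluded
        regardless of effect size."""
        ga = [quant(19, 0, sample_id=f"a{i}") for i in range(3)]
        gb = [quant(0, 100, sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb)
        assert res.excluded and not res.passes_filter
        assert "floor" in res.reason

    def test_total_scope_allows_summed_floor(self):
        ga = [quant(8, 0, sample_id="a1"), quant(7, 0, sample_id="a2")]
        gb = [quant(0, 9, sample_id="b1"), quant(1, 9, sample_id="b2")]
        res = run_differential(ga, gb, FilterConfig(min_reads_scope="total"))
        assert not res.excluded

    def test_delta_psi_bound_is_inclusive(self):
        ga = [quant(50, 50) for _ in range(3)]
        gb = [quant(60, 40) for _ in range(3)]
        res = run_differential(ga, gb)
        assert res.delta_psi == pytest.approx(0.10)
        assert res.passes_filter  # zero within-group variance -> p = 0

    def test_identical_groups_fail(self):
        ga = [quant(50, 50) for _ in range(3)]
        res = run_differential(ga, [quant(50, 50) for _ in range(3)])
        assert res.delta_psi == 0 and res.p_value == 1.0 and not res.passes_filter

    def test_fewer_than_two_replicates_excluded(self):
        res = run_differential([quant(50, 50)], [quant(30, 70), quant(30, 70)])
        assert res.excluded and "replicates" in res.reason

    def test_fold_change_criterion_can_rescue_small_delta(self):
        # inclusion density more than doubles while psi moves < 0.10
        ga = [quant(30, 70, sample_id=f"a{i}") for i in range(3)]
        gb = [quant(65, 100, sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb)
        assert abs(res.delta_psi) < 0.10 < 1  # effect below the psi bound
        assert res.fold_change > 2 or res.fold_change < 0.5

    def test_log2_scale_is_stricter_here(self):
        ga = [quant(100, 100) for _ in range(3)]
        gb = [quant(230, 300) for _ in range(3)]
        lin = run_differential(ga, gb, FilterConfig(fc_scale="linear"))
        log = run_differential(ga, gb, FilterConfig(fc_scale="log2"))
        assert lin.fold_change == pytest.approx(2.3)
        assert abs(lin.delta_psi) < 0.10
        assert lin.passes_filter and not log.passes_filter

    def test_group_swap_mirrors_result(self, rng):
        """Swapping labels negates delta, inverts fold change, preserves the
        p-value and the verdict."""
        for _ in range(20):
            ga = [quant(int(rng.integers(10, 90)), int(rng.integers(10, 90)),
                        sample_id=f"a{i}") for i in range(3)]
            gb = [quant(int(rng.integers(10, 90)), int(rng.integers(10, 90)),
                        sample_id=f"b{i}") for i in range(3)]
            fwd = run_differential(ga, gb)
            rev = run_differential(gb, ga)
            assert rev.delta_psi == pytest.approx(-fwd.delta_psi)
            assert rev.fold_change == pytest.approx(1 / fwd.fold_change)
            assert rev.p_value == pytest.approx(fwd.p_value)
            assert rev.passes_filter == fwd.passes_filter


# ---------------------------------------------------------------------------
# burden summary
# ---------------------------------------------------------------------------

def _nmd_event(se_parts, event_id="ev", nmd_child="inc"):
    inc, exc = se_parts
    ev = SplicingEvent(event_id, "SE", (inc, exc), intron_class="U2")
    anns = {"inc": NMDAnnotation("inc", 10, 100, 90, nmd_child == "inc"),
            "exc": NMDAnnotation("exc", 10, 100, 90, nmd_child == "exc")}
    ev.nmd_relevant = True
    return ev, anns


class TestBurdenSummary:
    def test_empty_results_give_zero_table(self):
        table = summarize_nmd_burden([], {})
        assert (table.to_numpy() == 0).all()
        assert list(table.index) == ["SE", "RI", "A5SS", "A3SS", "MXE"]

    def test_single_significant_nmd_up_event(self, se_event_parts):
        ev, anns = _nmd_event(se_event_parts)
        ga = [quant(20, 80, event_id="ev", sample_id=f"a{i}") for i in range(3)]
        gb = [quant(80, 20, event_id="ev", sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb, event=ev, nmd_annotations=anns)
        assert res.direction == "nmd_up"
        table = summarize_nmd_burden([res], {"ev": ev})
        assert table.loc["SE", "nmd_up"] == 1 and table.to_numpy().sum() == 1

    def test_direction_tracks_the_nmd_child(self, se_event_parts):
        ev, anns = _nmd_event(se_event_parts, nmd_child="exc")
        ga = [quant(20, 80, event_id="ev", sample_id=f"a{i}") for i in range(3)]
        gb = [quant(80, 20, event_id="ev", sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb, event=ev, nmd_annotations=anns)
        assert res.direction == "nmd_down"  # inclusion rose, NMD child fell

    def test_no_event_counted_twice_and_totals_match(self, se_event_parts):
        ev, anns = _nmd_event(se_event_parts)
        ga = [quant(20, 80, event_id="ev", sample_id=f"a{i}") for i in range(3)]
        gb = [quant(80, 20, event_id="ev", sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb, event=ev, nmd_annotations=anns)
        table = summarize_nmd_burden([res, res], {"ev": ev})
        assert table.to_numpy().sum() == 1

    def test_non_u2_events_not_counted(self, se_event_parts):
        ev, anns = _nmd_event(se_event_parts)
        ev.intron_class = "U12"
        ga = [quant(20, 80, event_id="ev", sample_id=f"a{i}") for i in range(3)]
        gb = [quant(80, 20, event_id="ev", sample_id=f"b{i}") for i in range(3)]
        res = run_differential(ga, gb, event=ev, nmd_annotations=anns)
        table = summarize_nmd_burden([res], {"ev": ev})
        assert table.to_numpy().sum() == 0
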