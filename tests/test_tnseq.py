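import numpy as np
import pytest

from castkit.refio import FWD, REV, ReadRecord, Reference, build_kmer_index, revcomp
from castkit.tnseq import (
    DEFAULT_END_SEQ,
    FingerprintHit,
    IntegrationEvent,
    TargetSite,
    TnseqParams,
    analyze_sample,
    call_events,
    classify_event,
    extract_fingerprint,
    locate_fingerprint,
    normalize_across_samples,
    passes_quality,
    phred_error_prob,
    summarize_sample,
)

PARAMS = TnseqParams()


def _read(seq, quals=None, rid="r"):
    if quals is None:
        quals = [37] * len(seq)
    return ReadRecord(rid, seq, quals)


class TestQualityFilter:
    def test_all_high_quality_passes(self):
        assert passes_quality(_read("A" * 100))

    def test_majority_low_quality_fails(self):
        assert not passes_quality(_read("A" * 100, [15] * 60 + [30] * 40))

    def test_exactly_half_low_quality_fails(self):
        # "half of the bases" below Q20 triggers removal (boundary inclusive)
        assert not passes_quality(_read("A" * 100, [19] * 50 + [30] * 50))

    def test_q20_itself_is_not_low(self):
        assert passes_quality(_read("A" * 100, [20] * 100))

    def test_empty_read_fails(self):
        assert not passes_quality(_read(""))


class TestPhred:
    def test_q20_is_one_percent(self):
        assert phred_error_prob(20) == 0.01

    @pytest.mark.parametrize("q,p", [(0, 1.0), (10, 0.1), (30, 0.001)])
    def test_decade_scaling(self, q, p):
        assert phred_error_prob(q) == pytest.approx(p)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phred_error_prob(-1)


class TestFingerprintExtraction:
    def test_flank_after_end_sequence(self):
        flank = "ACGTACGTACGTACGTA"
        read = _read(DEFAULT_END_SEQ + flank + "GGGGGG")
        assert extract_fingerprint(read) == flank

    def test_short_flank_returns_none(self):
        assert extract_fingerprint(_read(DEFAULT_END_SEQ + "ACGTACGTAC")) is None

    def test_absent_end_returns_none(self):
        assert extract_fingerprint(_read("ACGT" * 40)) is None

    def test_first_occurrence_wins(self):
        first, second = "A" * 17, "C" * 17
        read = _read(DEFAULT_END_SEQ + first + DEFAULT_END_SEQ + second)
        assert extract_fingerprint(read) == first

    def test_mismatch_tolerant_end_detection(self):
        end_1mm = "A" + DEFAULT_END_SEQ[1:]
        read = _read(end_1mm + "G" * 17)
        assert extract_fingerprint(read) is None
        assert (
            extract_fingerprint(read, TnseqParams(end_max_mismatch=1)) == "G" * 17
        )


class TestLocate:
    @pytest.fixture
    def genome(self, make_reference):
        return make_reference(seed=50, length=2000)

    def test_unique_hit_has_coordinates(self, genome):
        fp = genome.sequence("c1")[700:717]
        idx = build_kmer_index(genome, 17)
        hit = locate_fingerprint(idx, None, fp, "r1")
        assert (hit.category, hit.contig_id, hit.fwd_start, hit.map_strand) == (
            "unique", "c1", 700, FWD,
        )

    def test_rev_strand_hit(self, genome):
        fp = revcomp(genome.sequence("c1")[700:717])
        idx = build_kmer_index(genome, 17)
        hit = locate_fingerprint(idx, None, fp)
        assert (hit.category, hit.fwd_start, hit.map_strand) == ("unique", 700, REV)

    def test_duplicated_fingerprint_is_multi(self, genome):
        seq = genome.sequence("c1")
        fp = seq[700:717]
        dup = Reference([("c1", seq + "TT" + fp)])
        assert locate_fingerprint(build_kmer_index(dup, 17), None, fp).category == "multi"

    def test_vector_only_is_donor_contamination(self, genome):
        fp = "ACGTACGTACGTACGTA"
        vector = Reference([("pME", "TTTT" + fp + "TTTT")])
        hit = locate_fingerprint(
            build_kmer_index(genome, 17), build_kmer_index(vector, 17), fp
        )
        assert hit.category == "vector"

    def test_nowhere_is_unmapped(self, genome):
        idx = build_kmer_index(genome, 17)
        assert locate_fingerprint(idx, None, "A" * 17).category == "unmapped"

    def test_fingerprint_length_checked(self, genome):
        idx = build_kmer_index(genome, 17)
        with pytest.raises(ValueError):
            locate_fingerprint(idx, None, "ACGT")


class TestCallEvents:
    def test_fwd_position_formula(self):
        hit = FingerprintHit("r1", "unique", "c1", 100, FWD)
        (event,) = call_events([hit])
        assert (event.position, event.strand) == (105, FWD)

    def test_reads_at_one_site_aggregate(self):
        hits = [FingerprintHit(f"r{i}", "unique", "c1", 100, FWD) for i in range(3)]
        (event,) = call_events(hits)
        assert event.read_count == 3

    def test_both_junction_orientations_coincide(self):
        """A fwd fingerprint at the TSD and the rev fingerprint of the same
        insertion (ending at the fifth TSD base) call one position."""
        t = 400
        fwd_hit = FingerprintHit("a", "unique", "c1", t, FWD)
        rev_hit = FingerprintHit("b", "unique", "c1", t + 5 - 17, REV)
        events = call_events([fwd_hit, rev_hit])
        assert {e.position for e in events} == {t + 5}

    def test_non_unique_hit_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            call_events([FingerprintHit("r1", "multi")])


class TestClassify:
    SITE = TargetSite("c1", 468, 500, FWD)  # protospacer ends at 0-based 500

    def _event(self, pos, strand=FWD):
        return IntegrationEvent("c1", pos, strand, read_count=1)

    def test_inside_window_is_on_target(self):
        assert classify_event(self._event(550), self.SITE).on_target

    def test_window_is_half_open_at_100(self):
        assert classify_event(self._event(600), self.SITE).on_target
        assert not classify_event(self._event(601), self.SITE).on_target

    def test_distant_event_untargeted(self):
        assert not classify_event(self._event(10_000), self.SITE).on_target

    def test_rev_site_window_points_upstream(self):
        site = TargetSite("c1", 500, 532, REV)
        assert classify_event(self._event(500), site).on_target
        assert classify_event(self._event(401), site).on_target
        assert not classify_event(self._event(400), site).on_target
        assert not classify_event(self._event(501), site).on_target

    def test_orientation_labels(self):
        ev = classify_event(self._event(550, FWD), self.SITE)
        assert ev.orientation == "T-RL"
        ev = classify_event(self._event(550, REV), self.SITE)
        assert ev.orientation == "T-LR"
        flipped = TnseqParams(trl_same_strand=False)
        assert classify_event(self._event(550, FWD), self.SITE, flipped).orientation == "T-LR"


class TestSummary:
    def _stats(self, on, off):
        events = []
        if on:
            events.append(IntegrationEvent("c1", 550, FWD, on, "T-RL", True))
        if off:
            events.append(IntegrationEvent("c1", 9000, FWD, off, "T-RL", False))
        totals = {"end_containing": on + off, "fingerprint_mapped_unique": on + off}
        return summarize_sample(events, totals)

    def test_specificity_of_984_16_mixture(self):
        assert self._stats(984, 16).specificity_pct == pytest.approx(98.4)

    def test_all_on_target(self):
        assert self._stats(1000, 0).specificity_pct == 100.0

    def test_zero_mapped_is_undefined(self):
        assert self._stats(0, 0).specificity_pct is None

    def test_read_partition(self):
        s = self._stats(984, 16)
        assert s.ontarget_reads + s.untargeted_reads == s.totals["fingerprint_mapped_unique"]


class TestNormalization:
    def _sample(self, sid, end_containing, site_counts):
        events = [
            IntegrationEvent("c1", pos, FWD, n, "T-RL", True)
            for pos, n in site_counts.items()
        ]
        return summarize_sample(events, {"end_containing": end_containing}, sid)

    def test_single_sample_identity(self):
        (s,) = normalize_across_samples([self._sample("a", 1000, {10: 100})])
        assert s.normalized[("c1", 10, FWD, "T-RL")] == 100

    def test_scaling_to_deepest_sample(self):
        a = self._sample("a", 1000, {10: 100})
        b = self._sample("b", 500, {10: 50})
        a, b = normalize_across_samples([a, b])
        key = ("c1", 10, FWD, "T-RL")
        assert a.normalized[key] == pytest.approx(100)
        assert b.normalized[key] == pytest.approx(100)
        assert a.scale_reference == b.scale_reference == 1000

    def test_depth_invariance(self):
        base = self._sample("a", 1000, {10: 100, 20: 30})
        doubled = self._sample("a2", 2000, {10: 200, 20: 60})
        deep = self._sample("ref", 4000, {10: 1})
        norm = dict(zip("a b c".split(), normalize_across_samples([base, doubled, deep])))
        k10 = ("c1", 10, FWD, "T-RL")
        k20 = ("c1", 20, FWD, "T-RL")
        assert norm["a"].normalized[k10] == pytest.approx(norm["b"].normalized[k10])
        assert norm["a"].normalized[k20] == pytest.approx(norm["b"].normalized[k20])

    def test_zero_depth_sample_flagged_missing(self):
        a = self._sample("a", 1000, {10: 100})
        z = self._sample("z", 0, {})
        a, z = normalize_across_samples([a, z])
        assert z.normalized is None

    def test_no_usable_samples_rejected(self):
        with pytest.raises(ValueError):
            normalize_across_samples([self._sample("z", 0, {})])


class TestPipelineAccounting:
    def test_raw_reads_conserved_across_categories(self, make_reference):
        """raw = qc_fail + no_end + short_flank + multi + unmapped + vector + unique."""
        genome = make_reference(seed=77, length=3000)
        seq = genome.sequence("c1")
        dup = Reference([("c1", seq + "TTTTT" + seq[100:117])])  # one multi fingerprint
        vector = Reference([("pME", "G" * 10 + "ACGTACGTACGTACGTA" + "G" * 10)])
        site = TargetSite("c1", 1000, 1032, FWD)
        reads = [
            _read(DEFAULT_END_SEQ + seq[1081:1098] + "A" * 20, rid="uniq"),
            _read(DEFAULT_END_SEQ + seq[100:117] + "A" * 20, rid="multi"),
            _read(DEFAULT_END_SEQ + "ACGTACGTACGTACGTA" + "A" * 20, rid="vec"),
            _read(DEFAULT_END_SEQ + "T" * 17, rid="unmapped"),
            _read(DEFAULT_END_SEQ + "ACGTAC", rid="short"),
            _read("A" * 60, rid="noend"),
            _read("A" * 60, [10] * 40 + [30] * 20, rid="lowq"),
        ]
        stats = analyze_sample(
            reads,
            build_kmer_index(dup, 17),
            build_kmer_index(vector, 17),
            site,
        )
        t = stats.totals
        assert t["raw_reads"] == 7
        assert (
            t["qc_fail"] + t["no_end"] + t["short_flank"] + t["multi"]
            + t["unmapped"] + t["donor_vector"] + t["fingerprint_mapped_unique"]
            == t["raw_reads"]
        )
        assert t["end_containing"] == 4
        assert {k: t[k] for k in ("qc_fail", "no_end", "short_flank", "multi",
                                  "unmapped", "donor_vector",
                                  "fingerprint_mapped_unique")} == {
            "qc_fail": 1, "no_end": 1, "short_flank": 1, "multi": 1,
            "unmapped": 1, "donor_vector": 1, "fingerprint_mapped_unique": 1,
        }
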