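import math

import numpy as np
import pytest

from gliosplice import PipelineConfig, ValidationError
from gliosplice.events import TranscriptModel
from gliosplice.filtering import (classify_impact, consolidate,
                                  consolidation_summary,
                                  direction_disruption_test,
                                  filter_significant, reciprocal_overlap)
from gliosplice import simulate as sim

from conftest import make_event, random_events


class TestFilterSignificant:
    def test_boundary_event_on_every_threshold_is_kept(self):
        ev = make_event(p_value=0.05, inclusion_reads=1, exclusion_reads=9,
                        psi_treated=0.60, psi_control=0.50)
        assert filter_significant([ev]) == [ev]

    def test_nine_total_reads_removed(self):
        ev = make_event(p_value=0.05, inclusion_reads=5, exclusion_reads=4,
                        psi_treated=0.9, psi_control=0.4)
        assert filter_significant([ev]) == []

    def test_negative_dpsi_kept_by_absolute_value(self):
        ev = make_event(psi_treated=0.3, psi_control=0.6)
        assert filter_significant([ev]) == [ev]

    def test_matches_bruteforce_oracle(self):
        events = random_events(2000, seed=3)
        kept = filter_significant(events)
        oracle = [ev for ev in events
                  if ev.p_value <= 0.05
                  and ev.inclusion_reads >= 1 and ev.exclusion_reads >= 1
                  and ev.inclusion_reads + ev.exclusion_reads >= 10
                  and abs(ev.psi_treated - ev.psi_control) >= 0.10]
        assert kept == oracle
        assert 0 < len(kept) < len(events)

    def test_subset_and_idempotent(self):
        events = random_events(500, seed=4)
        kept = filter_significant(events)
        assert set(e.event_id for e in kept) <= set(e.event_id for e in events)
        assert filter_significant(kept) == kept


class TestReciprocalOverlap:
    def test_99_percent_shift_matches(self):
        a = make_event(start=100, end=200)
        b = make_event(event_id="ev2", start=101, end=201)
        fa, fb, ok = reciprocal_overlap(a, b)
        assert (fa, fb) == (0.99, 0.99) and ok

    def test_half_overlap_no_match(self):
        a = make_event(start=100, end=200)
        b = make_event(event_id="ev2", start=150, end=250)
        fa, fb, ok = reciprocal_overlap(a, b)
        assert (fa, fb) == (0.50, 0.50) and not ok

    def test_opposite_strand_never_matches(self):
        a = make_event(start=100, end=200, strand="+")
        b = make_event(event_id="ev2", start=100, end=200, strand="-")
        assert not reciprocal_overlap(a, b)[2]

    def test_match_decision_is_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s1, s2 = rng.integers(0, 1000, 2)
            l1, l2 = rng.integers(50, 300, 2)
            a = make_event(start=int(s1), end=int(s1 + l1))
            b = make_event(event_id="b", start=int(s2), end=int(s2 + l2))
            assert reciprocal_overlap(a, b)[2] == reciprocal_overlap(b, a)[2]

    def test_zero_length_interval_rejected(self):
        a = make_event(start=100, end=200)
        b = make_event(event_id="b", start=100, end=200)
        b.end = b.start  # bypass constructor validation
        with pytest.raises(ValidationError):
            reciprocal_overlap(a, b)


class TestConsolidate:
    def test_recovers_planted_shared_events(self):
        tables, truth = sim.gen_ase_tables(400, 3, 0.05, seed=11)
        filtered = {k: filter_significant(v) for k, v in tables.items()}
        groups = consolidate(filtered)
        assert ({g.representative.event_id for g in groups}
                == truth.shared_significant_event_ids)

    def test_disjoint_coordinates_give_empty_result(self):
        a = [make_event(start=100, end=200)]
        b = [make_event(event_id="x", start=5000, end=5100)]
        assert consolidate({"s1": a, "s2": b}) == []

    def test_group_sets_invariant_to_sample_order(self):
        tables, _ = sim.gen_ase_tables(300, 3, 0.1, seed=12)
        filtered = {k: filter_significant(v) for k, v in tables.items()}
        fwd = consolidate(dict(filtered))
        rev = consolidate(dict(reversed(list(filtered.items()))))
        as_sets = lambda gs: {
            frozenset((s, e.event_id) for s, e in g.members.items()) for g in gs}
        assert as_sets(fwd) == as_sets(rev)

    def test_count_monotone_in_number_of_samples(self):
        tables, _ = sim.gen_ase_tables(300, 4, 0.1, seed=13)
        filtered = {k: filter_significant(v) for k, v in tables.items()}
        names = list(filtered)
        n2 = len(consolidate({k: filtered[k] for k in names[:2]}))
        n3 = len(consolidate({k: filtered[k] for k in names[:3]}))
        n4 = len(consolidate(filtered))
        assert n2 >= n3 >= n4

    def test_summary_counts_events_and_genes(self):
        tables, truth = sim.gen_ase_tables(200, 2, 0.1, seed=14)
        filtered = {k: filter_significant(v) for k, v in tables.items()}
        s = consolidation_summary(consolidate(filtered))
        assert s["n_events"] == len(truth.shared_significant_event_ids)
        assert 0 < s["n_genes"] <= s["n_events"]


class TestClassifyImpact:
    tx_inclusion = TranscriptModel("tx1", "GENE1", "+",
                                   exons=[(0, 1000)], coding_start=0)
    tx_exclusion = TranscriptModel("tx2", "GENE1", "+",
                                   exons=[(0, 100), (210, 1000)])

    def test_length_not_multiple_of_three_shifts_frame(self):
        ev = make_event(start=100, end=200)  # 100 nt
        call = classify_impact(ev, [self.tx_inclusion, self.tx_exclusion])
        assert call.call == "disruptive_frameshift"
        assert call.basis == "length_mod3"

    def test_multiple_of_three_without_sequence_preserves_frame(self):
        ev = make_event(start=100, end=199)  # 99 nt
        call = classify_impact(ev, [self.tx_inclusion, self.tx_exclusion])
        assert call.call == "in_frame_preserving"

    def test_in_frame_stop_codon_is_disruptive(self):
        # RI of 51 nt strictly inside the retained-form exon; TAA placed on
        # a codon boundary of the frame anchored at coding_start=0
        ev = make_event(event_class="RI", start=102, end=153)
        seq = list("GCA" * 17)
        seq[6:9] = "TAA"  # segment offset 6 -> genomic 108, 108 % 3 == 0
        call = classify_impact(ev, [self.tx_inclusion], segment_sequence="".join(seq))
        assert (call.call, call.basis) == ("disruptive_frameshift", "stop_codon")

    def test_out_of_frame_stop_is_not_called(self):
        ev = make_event(event_class="RI", start=102, end=153)
        seq = list("GCA" * 17)
        seq[7:10] = "TAA"  # off the codon grid
        call = classify_impact(ev, [self.tx_inclusion], segment_sequence="".join(seq))
        assert call.call == "in_frame_preserving"

    def test_unmapped_event_is_unknown(self):
        ev = make_event(gene="GENE2", start=5000, end=5100)
        lone = TranscriptModel("tx3", "GENE2", "+", exons=[(0, 100)])
        call = classify_impact(ev, [lone])
        assert (call.call, call.basis) == ("unknown", "no_transcript_match")

    def test_ri_needs_strict_containment(self):
        # RI flush against the exon edge is not "between two exons"
        ev = make_event(event_class="RI", start=0, end=99)
        call = classify_impact(ev, [self.tx_inclusion])
        assert call.call == "unknown"


class TestDirectionDisruptionTest:
    @staticmethod
    def _events_and_calls(table):
        from gliosplice.events import ImpactCall
        events, calls, n = [], {}, 0
        for i, sign in enumerate((1, -1)):
            for j, call in enumerate(("disruptive_frameshift",
                                      "in_frame_preserving")):
                for _ in range(table[i][j]):
                    eid = f"e{n}"
                    n += 1
                    events.append(make_event(
                        event_id=eid,
                        psi_treated=0.75 if sign > 0 else 0.25,
                        psi_control=0.5))
                    calls[eid] = ImpactCall(eid, call, "length_mod3")
        return events, calls

    def test_perfect_association_matches_enumeration(self):
        events, calls = self._events_and_calls([[10, 0], [0, 10]])
        table, odds, p = direction_disruption_test(events, calls)
        assert table == [[10, 0], [0, 10]]
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_no_association_gives_p_one(self):
        events, calls = self._events_and_calls([[5, 5], [5, 5]])
        _, odds, p = direction_disruption_test(events, calls)
        assert p == 1.0 and odds == 1.0

    def test_zero_margin_degenerate_warns(self):
        events, calls = self._events_and_calls([[5, 5], [0, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, p = direction_disruption_test(events, calls)
        assert p == 1.0

    def test_null_false_positive_rate(self):
        """Independent direction/impact assignments should rarely reach 0.05."""
        rng = np.random.default_rng(21)
        hits = 0
        n_seeds = 60
        for _ in range(n_seeds):
            table = [[int(rng.binomial(80, 0.25)) for _ in range(2)]
                     for _ in range(2)]
            if 0 in [sum(r) for r in table] + [table[0][j] + table[1][j]
                                               for j in range(2)]:
                continue
            events, calls = self._events_and_calls(table)
            _, _, p = direction_disruption_test(events, calls)
            hits += p < 0.05
        assert hits / n_seeds <= 0.1
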