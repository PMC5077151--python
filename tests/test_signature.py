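"""Delta-PSI calling, acceptor-window logos, signature classification, group tests."""

import math

import numpy as np
import pandas as pd
import pytest

from spliceratio.errors import (
    DataValidationError,
    InvalidParameterError,
    WindowRejected,
)
from spliceratio.events import SpliceEvent
from spliceratio.psi import PsiMatrix
from spliceratio.signature import (
    DeltaPsiRecord,
    build_logo,
    classify_signature,
    collect_windows,
    compare_signatures,
    delta_psi_vs_reference,
    extract_3ss_window,
    group_compare,
)
from spliceratio.synthetic import revcomp


def matrix_from(psi_dict):
    """Build a PsiMatrix from {sample: {event: psi}}."""
    psi = pd.DataFrame(psi_dict).T
    psi.index.name = "sample_id"
    informative = psi.notna() * 100.0
    return PsiMatrix(psi, informative)


class TestDeltaPsi:
    def test_delta_against_reference_median(self):
        m = matrix_from(
            {
                "r1": {"e1": 0.5}, "r2": {"e1": 0.5}, "r3": {"e1": 0.6},
                "q": {"e1": 0.7},
            }
        )
        (rec,) = delta_psi_vs_reference(m, ["r1", "r2", "r3"], "q")
        assert rec.delta_psi == pytest.approx(0.20)
        assert rec.call == "promoted"

    def test_threshold_is_inclusive_at_exactly_ten_percent(self):
        m = matrix_from(
            {"r1": {"e1": 0.5}, "r2": {"e1": 0.5}, "q": {"e1": 0.6}}
        )
        (rec,) = delta_psi_vs_reference(m, ["r1", "r2"], "q")
        assert rec.delta_psi == pytest.approx(0.10)
        assert rec.call == "promoted"

    def test_query_at_reference_median_is_unaffected(self):
        m = matrix_from(
            {"r1": {"e1": 0.4}, "r2": {"e1": 0.6}, "q": {"e1": 0.5}}
        )
        (rec,) = delta_psi_vs_reference(m, ["r1", "r2"], "q")
        assert rec.delta_psi == pytest.approx(0.0)
        assert rec.call == "unaffected"

    def test_query_in_reference_set_rejected(self):
        m = matrix_from({"r1": {"e1": 0.5}, "q": {"e1": 0.6}})
        with pytest.raises(InvalidParameterError):
            delta_psi_vs_reference(m, ["r1", "q"], "q")

    def test_events_with_sparse_reference_support_dropped(self):
        m = matrix_from(
            {
                "r1": {"e1": 0.5, "e2": math.nan},
                "r2": {"e1": 0.5, "e2": math.nan},
                "r3": {"e1": 0.5, "e2": 0.4},
                "r4": {"e1": 0.5, "e2": 0.4},
                "q": {"e1": 0.9, "e2": 0.9},
            }
        )
        records = delta_psi_vs_reference(m, ["r1", "r2", "r3", "r4"], "q")
        assert [r.event_id for r in records] == ["e1", "e2"]
        sparse = delta_psi_vs_reference(
            m, ["r1", "r2", "r3", "r4"], "q", min_reference_fraction=0.75
        )
        assert [r.event_id for r in sparse] == ["e1"]


class TestWindowExtraction:
    #            0         1         2         3         4         5
    #            0123456789012345678901234567890123456789012345678901234567890
    PLUS_CONTIG = "AAACCCGGGT" + "GT" + "CTCTCTCTCTCTCTCTCTCTCTCTCTTT" + "CAG" + "ATGCCCAAATTTGGG"
    # intron = [10, 43): GT...TTCAG? -> ends with CAG; acceptor AG at 41:43

    def make_event(self, strand="+", contig=None, start=10, end=43, length=None):
        contig = contig if contig is not None else self.PLUS_CONTIG
        if strand == "-":
            length = len(contig)
            start, end = length - end, length - start
        return SpliceEvent("ev", "G", "se", "c", start, end, strand), contig

    def test_plus_strand_window_ends_in_AG_plus_exonic(self):
        ev, contig = self.make_event("+")
        w = extract_3ss_window(ev, {"c": contig}, window=(-8, 3))
        assert w == contig[35:43] + contig[43:46]
        assert w[-5:-3] == "AG"

    def test_minus_strand_matches_reverse_complement_oracle(self):
        ev_plus, contig = self.make_event("+")
        w_plus = extract_3ss_window(ev_plus, {"c": contig}, window=(-8, 3))
        ev_minus, rc_contig = self.make_event("-", contig=revcomp(self.PLUS_CONTIG))
        # the revcomp genome holds the same intron on the minus strand
        w_minus = extract_3ss_window(ev_minus, {"c": rc_contig}, window=(-8, 3))
        assert w_minus == w_plus

    def test_non_canonical_intron_rejected(self):
        contig = self.PLUS_CONTIG[:41] + "AC" + self.PLUS_CONTIG[43:]
        ev, _ = self.make_event("+")
        with pytest.raises(WindowRejected) as err:
            extract_3ss_window(ev, {"c": contig})
        assert err.value.reason == "non_canonical"

    def test_window_beyond_contig_bounds_rejected(self):
        ev, contig = self.make_event("+")
        with pytest.raises(WindowRejected) as err:
            extract_3ss_window(ev, {"c": contig}, window=(-8, 30))
        assert err.value.reason == "out_of_bounds"

    def test_panel_windows_match_generator_truth(self, small_panel):
        windows, rejected = collect_windows(
            small_panel.splice_events, small_panel.genome
        )
        assert not rejected
        for sim_event in small_panel.sim_events:
            assert windows[sim_event.event_id] == sim_event.sequence_window


class TestLogo:
    def test_invariant_column_reaches_two_bits(self):
        logo = build_logo(["A", "A", "A", "A"], window=(-1, 0))
        assert logo.information_content.iloc[0] == pytest.approx(2.0)

    def test_uniform_column_is_zero_bits(self):
        logo = build_logo(["A", "C", "G", "T"], window=(-1, 0))
        assert logo.information_content.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_half_column_is_one_bit(self):
        logo = build_logo(["A", "A", "C", "C"], window=(-1, 0))
        assert logo.information_content.iloc[0] == pytest.approx(1.0)

    def test_frequencies_normalised_and_ic_bounded(self, small_panel):
        windows = [e.sequence_window for e in small_panel.sim_events]
        logo = build_logo(windows)
        sums = logo.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (logo.information_content >= 0).all()
        assert (logo.information_content <= 2).all()
        assert list(logo.frequencies.index)[:2] == [-20, -19]
        assert -3 in logo.frequencies.index

    def test_ambiguous_bases_dropped_with_renormalisation(self):
        logo = build_logo(["A", "A", "N", "C"], window=(-1, 0))
        f = logo.frequencies_at(-1)
        assert f["A"] == pytest.approx(2 / 3)
        assert f["C"] == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_logo([])

    def test_strand_invariance_of_panel_logos(self, small_panel):
        """Reverse-complementing the genome and flipping strands leaves logos identical."""
        windows_fwd, _ = collect_windows(small_panel.splice_events, small_panel.genome)
        flipped_genome = {c: revcomp(s) for c, s in small_panel.genome.items()}
        flipped_events = []
        for ev in small_panel.splice_events:
            L = len(small_panel.genome[ev.chrom])
            flipped_events.append(
                SpliceEvent(
                    ev.event_id, ev.gene_name, ev.event_type, ev.chrom,
                    L - ev.end, L - ev.start,
                    "-" if ev.strand == "+" else "+",
                )
            )
        windows_rev, rejected = collect_windows(flipped_events, flipped_genome)
        assert not rejected
        logo_fwd = build_logo(list(windows_fwd.values()))
        logo_rev = build_logo([windows_rev[k] for k in windows_fwd])
        pd.testing.assert_frame_equal(logo_fwd.frequencies, logo_rev.frequencies)


class TestClassification:
    def build(self, freqs):
        """Logo with a chosen -3 composition from 20 windows."""
        bases = []
        for b, f in freqs.items():
            bases.extend([b] * int(round(f * 20)))
        windows = [b + "AG" + "A" for b in bases]
        return build_logo(windows, window=(-3, 1))

    def test_mutant_pattern_called_typical(self):
        prom = self.build({"C": 0.50, "A": 0.30, "T": 0.15, "G": 0.05})
        rep = self.build({"T": 0.50, "A": 0.25, "C": 0.20, "G": 0.05})
        call = classify_signature(prom, rep)
        assert call.signature_class == "typical_S34F"
        assert call.score > 0

    def test_background_pattern_called_quasi_wt(self):
        background = {"C": 0.55, "T": 0.30, "A": 0.10, "G": 0.05}
        call = classify_signature(self.build(background), self.build(background))
        assert call.signature_class == "quasi_WT"

    def test_partial_pattern_collapses_to_quasi_wt(self):
        prom = self.build({"C": 0.50, "A": 0.30, "T": 0.15, "G": 0.05})
        rep = self.build({"C": 0.50, "T": 0.30, "A": 0.15, "G": 0.05})  # T !> C
        call = classify_signature(prom, rep)
        assert call.signature_class == "quasi_WT"

    def test_too_few_sequences_is_undetermined(self):
        small = build_logo(["CAGA"] * 5, window=(-3, 1))
        call = classify_signature(small, small, min_sequences=10)
        assert call.signature_class == "undetermined"


class TestCompareSignatures:
    def rec(self, event_id, sample, d):
        call = (
            "promoted" if d >= 0.1 else "repressed" if d <= -0.1 else "unaffected"
        )
        return DeltaPsiRecord(event_id, sample, d, call)

    def test_identical_signatures_fully_shared_with_zero_enhancement(self):
        a = [self.rec(f"e{i}", "a", 0.2) for i in range(5)]
        b = [self.rec(f"e{i}", "b", 0.2) for i in range(5)]
        cmpres = compare_signatures(a, b)
        assert cmpres.counts.loc["promoted", "shared"] == 5
        assert cmpres.counts.loc["promoted", ["only_a", "only_b"]].sum() == 0
        assert (cmpres.shared.enhancement == 0).all()

    def test_disjoint_promoted_sets_share_nothing(self):
        a = [self.rec("e1", "a", 0.2), self.rec("e2", "a", 0.0)]
        b = [self.rec("e1", "b", 0.0), self.rec("e2", "b", 0.2)]
        cmpres = compare_signatures(a, b)
        assert cmpres.counts.loc["promoted", "shared"] == 0
        assert cmpres.counts.loc["promoted", "only_a"] == 1
        assert cmpres.counts.loc["promoted", "only_b"] == 1

    def test_mismatched_event_universes_rejected(self):
        with pytest.raises(DataValidationError):
            compare_signatures([self.rec("e1", "a", 0.2)], [self.rec("e2", "b", 0.2)])

    def test_shared_events_gain_at_higher_ratio(self, small_panel):
        """Raising rho enhances the shared promoted signature (occupancy oracle)."""
        from spliceratio.psi import psi_matrix
        from spliceratio.synthetic import SimCohortConfig, simulate_cohort

        config = SimCohortConfig(
            noise_seed=21, n_wt_samples=20, n_mut_samples=2,
            ratio_per_mut_sample=[0.5, 2.0], read_depth_per_event=2000,
            biological_sd=0.05,
        )
        cohort = simulate_cohort(small_panel.sim_events, config)
        m = psi_matrix(cohort.junctions, small_panel.splice_events)
        refs = [s for s in m.samples if s.startswith("WT")]
        low = delta_psi_vs_reference(m, refs, "MUT_001")
        high = delta_psi_vs_reference(m, refs, "MUT_002")
        cmpres = compare_signatures(low, high)
        shared_prom = cmpres.shared[cmpres.shared.direction == "promoted"]
        assert len(shared_prom) > 0
        assert shared_prom.enhancement.median() > 0


class TestGroupCompare:
    def test_exact_u_statistic_for_separated_groups(self):
        res = group_compare([1, 2], [3, 4])
        assert res.statistic == 0.0

    def test_identical_groups_give_p_one(self):
        res = group_compare([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_two_sided_p_for_three_vs_three(self):
        # U=0; 2 * (1/20) over the C(6,3)=20 equally likely arrangements
        res = group_compare([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "mann_whitney[exact]"

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        res = group_compare(a, b)
        assert res.method == "mann_whitney[asymptotic]"
        assert 0 <= res.p_value <= 1

    def test_student_t_available_for_two_group_means(self):
        res = group_compare([1.0, 1.1, 0.9], [2.0, 2.1, 1.9], method="student_t")
        assert res.method == "student_t"
        assert res.p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            group_compare([], [1.0])
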