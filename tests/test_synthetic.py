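"""Occupancy model, cohort simulation, and titration generator."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spliceratio.errors import InvalidParameterError
from spliceratio.synthetic import (
    SimCohortConfig,
    SimEvent,
    bound_fraction,
    occupancy_psi,
    simulate_cohort,
    simulate_titration,
    write_junction_tsv,
)


def make_event(kawp=1.0, kawd=1.0, kamp=1.0, kamd=1.0, minus3="C"):
    return SimEvent(
        event_id="ev",
        minus3_base=minus3,
        ka_wt_prox=kawp,
        ka_wt_dist=kawd,
        ka_mut_prox=kamp,
        ka_mut_dist=kamd,
        sequence_window="T" * 17 + minus3 + "AG" + "AAA",
    )


class TestOccupancyPsi:
    def test_symmetric_wildtype_gives_half(self):
        ev = make_event(kawp=2.0, kawd=2.0)
        assert occupancy_psi(ev, 0.0) == pytest.approx(0.5)

    def test_pure_mutant_with_vanishing_proximal_affinity(self):
        ev = make_event(kamp=1e-12, kamd=1.0)
        assert occupancy_psi(ev, np.inf) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_mixture(self):
        # rho=1 -> f=1/2; proximal share (0.5*1 + 0.5*2)/(1.5 + 1.0) = 0.6
        ev = make_event(kawp=2.0, kawd=1.0, kamp=1.0, kamd=1.0)
        assert occupancy_psi(ev, 1.0) == pytest.approx(0.6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            occupancy_psi(make_event(), -0.5)
        with pytest.raises(InvalidParameterError):
            make_event(kamp=0.0)

    @given(
        kawp=st.floats(0.1, 10),
        kawd=st.floats(0.1, 10),
        kamp=st.floats(0.1, 10),
        kamd=st.floats(0.1, 10),
        r1=st.floats(0.0, 5.0),
        dr=st.floats(0.01, 5.0),
    )
    def test_monotone_in_rho_with_sign_from_affinity_cross_product(
        self, kawp, kawd, kamp, kamd, r1, dr
    ):
        ev = make_event(kawp=kawp, kawd=kawd, kamp=kamp, kamd=kamd)
        delta = occupancy_psi(ev, r1 + dr) - occupancy_psi(ev, r1)
        cross = kamp * kawd - kamd * kawp
        if abs(cross) > 1e-9:
            assert np.sign(delta) == np.sign(cross) or abs(delta) < 1e-12
        else:
            assert abs(delta) < 1e-9


class TestSimulateCohort:
    def test_empty_event_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_cohort([], SimCohortConfig(noise_seed=0))

    def test_zero_depth_yields_zero_counts(self):
        config = SimCohortConfig(
            noise_seed=1, n_wt_samples=2, n_mut_samples=1,
            ratio_per_mut_sample=[0.5], read_depth_per_event=0.0, allele_depth=0,
        )
        cohort = simulate_cohort([make_event()], config)
        assert (cohort.junctions[["inclusion_reads", "exclusion_reads"]] == 0).all().all()
        assert (cohort.alleles[["alt_reads", "ref_reads"]] == 0).all().all()

    def test_null_cohort_centred_on_reference_median(self):
        events = [make_event(kawp=k, kamp=k * 3) for k in (0.5, 1.0, 2.0)]
        events = [
            SimEvent(f"e{i}", e.minus3_base, e.ka_wt_prox, e.ka_wt_dist,
                     e.ka_mut_prox, e.ka_mut_dist, e.sequence_window)
            for i, e in enumerate(events)
        ]
        config = SimCohortConfig(
            noise_seed=2, n_wt_samples=40, n_mut_samples=0, ratio_per_mut_sample=[],
            read_depth_per_event=2000, biological_sd=0.0,
        )
        cohort = simulate_cohort(events, config)
        psi_hat = cohort.junctions.assign(
            psi=lambda d: d.inclusion_reads / (d.inclusion_reads + d.exclusion_reads)
        ).groupby("event_id").psi
        dpsi = psi_hat.mean() - psi_hat.median()
        assert np.abs(dpsi).max() < 0.02

    def test_minus3C_promoted_events_shift_more_at_higher_ratio(self):
        # Monte-Carlo check against the occupancy-model oracle: events with a
        # promoting mutant affinity at -3C move further at rho=0.8 than 0.3.
        events = [
            SimEvent(f"e{i}", "C", 1.0, 1.0, 2.5, 1.0, "T" * 17 + "CAG" + "AAA")
            for i in range(60)
        ]
        config = SimCohortConfig(
            noise_seed=3, n_wt_samples=0, n_mut_samples=2,
            ratio_per_mut_sample=[0.3, 0.8], read_depth_per_event=10_000,
            biological_sd=0.0,
        )
        cohort = simulate_cohort(events, config)
        psi_hat = cohort.junctions.assign(
            psi=lambda d: d.inclusion_reads / (d.inclusion_reads + d.exclusion_reads)
        ).groupby("sample_id").psi.mean()
        assert psi_hat["MUT_002"] > psi_hat["MUT_001"]
        expected = {
            0.3: occupancy_psi(events[0], 0.3), 0.8: occupancy_psi(events[0], 0.8)
        }
        assert psi_hat["MUT_001"] == pytest.approx(expected[0.3], abs=0.01)
        assert psi_hat["MUT_002"] == pytest.approx(expected[0.8], abs=0.01)

    def test_binomial_estimator_unbiased_at_high_depth(self):
        events = [make_event(kawp=1.3, kamp=2.0)]
        config = SimCohortConfig(
            noise_seed=4, n_wt_samples=0, n_mut_samples=100,
            ratio_per_mut_sample=[0.7] * 100, read_depth_per_event=100_000,
        )
        cohort = simulate_cohort(events, config)
        psi_hat = (
            cohort.junctions.inclusion_reads
            / (cohort.junctions.inclusion_reads + cohort.junctions.exclusion_reads)
        ).to_numpy()
        truth = cohort.truth.psi.to_numpy().ravel()
        assert abs((psi_hat - truth).mean()) < 0.01

    def test_identical_seeds_are_byte_identical(self, small_panel):
        outs = []
        for _ in range(2):
            cohort = simulate_cohort(
                small_panel.sim_events, SimCohortConfig(noise_seed=99)
            )
            buf = io.StringIO()
            write_junction_tsv(cohort.junctions, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_truth_psi_within_unit_interval(self, small_cohort):
        cohort, _ = small_cohort
        psi = cohort.truth.psi.to_numpy()
        assert ((psi >= 0) & (psi <= 1)).all()


class TestEventPanel:
    def test_windows_end_in_AG_before_exonic_bases(self, small_panel):
        for e in small_panel.sim_events:
            assert e.sequence_window[-5:-3] == "AG"
            assert e.sequence_window[-6] == e.minus3_base

    def test_contigs_carry_canonical_introns(self, small_panel):
        from spliceratio.synthetic import revcomp

        for ev in small_panel.splice_events[:50]:
            seq = small_panel.genome[ev.chrom]
            if ev.strand == "+":
                intron = seq[ev.start : ev.end]
            else:
                intron = revcomp(seq[ev.start : ev.end])
            assert intron.startswith("GT") and intron.endswith("AG")


class TestSimulateTitration:
    def test_zero_protein_gives_free_anisotropy(self):
        t = simulate_titration(10, 1, [0.0, 1.0, 1e6], a_free=0.05, a_bound=0.2)
        assert t.anisotropy[0] == pytest.approx(0.05)

    def test_saturation_approaches_bound_anisotropy(self):
        t = simulate_titration(10, 1, [0.0, 1e7], a_free=0.05, a_bound=0.2)
        assert t.anisotropy[-1] == pytest.approx(0.2, rel=1e-3)

    def test_trace_rna_half_bound_at_kd(self):
        # hyperbolic limit of the quadratic isotherm
        fb = bound_fraction(100.0, 0.01, 100.0)
        assert fb == pytest.approx(0.5, rel=0.01)

    def test_inverted_endpoints_flagged(self):
        with pytest.raises(InvalidParameterError):
            simulate_titration(10, 1, [0, 1], a_free=0.2, a_bound=0.1)

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_titration(10, 1, [5.0, 1.0], noise_sd=0.0)
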