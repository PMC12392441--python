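"""Monte Carlo engine: selection, update rule, genealogy, replicates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegscission import (
    ChainEnsemble,
    DomainError,
    EnsembleSpec,
    ExhaustedEnsembleError,
    RateModel,
    classify_chains,
    export_network,
    number_average_mw,
    run_replicates,
    run_simulation,
    simulate_scission_step,
)
from pegscission.simulate import (
    LABEL_DAUGHTER_FINAL,
    LABEL_INITIAL_FINAL,
    LABEL_INTERMEDIATE,
    _round_half_up,
)

SMALL_SPEC = EnsembleSpec(m=20, lambda_len=145, sigma_len=9.09)


class TestSingleStep:
    def test_forced_dimer_split(self):
        ens, event = simulate_scission_step(ChainEnsemble({2: 1}), rng=0)
        assert ens.counts == {1: 2}
        assert event.parent_length == 2 and event.cut_position == 1
        assert event.child_lengths == (1, 1)

    def test_mass_and_count_update(self):
        start = ChainEnsemble({10: 3, 50: 2})
        ens, event = simulate_scission_step(start, rng=7)
        assert ens.total_monomers == start.total_monomers
        assert ens.total_chains == start.total_chains + 1
        assert sum(event.child_lengths) == event.parent_length

    def test_exhausted(self):
        with pytest.raises(ExhaustedEnsembleError):
            simulate_scission_step(ChainEnsemble({1: 5}), rng=0)


class TestRunSimulation:
    @pytest.mark.parametrize("sic, events", [(1.0, 20), (8.0, 160)])
    def test_event_budget(self, sic, events):
        result = run_simulation(SMALL_SPEC, sic_target=sic, seed=3)
        assert result.n_events == events
        assert result.final_ensemble.total_chains == 20 + events

    def test_rounding_floor_case(self, study_spec):
        result = run_simulation(study_spec, sic_target=0.0002, seed=1)
        assert result.n_events == 1

    def test_round_half_up(self):
        assert _round_half_up(2.5) == 3
        assert _round_half_up(2.49999) == 2

    def test_zero_event_budget_rejected(self):
        with pytest.raises(DomainError):
            run_simulation(SMALL_SPEC, sic_target=0.001, seed=0)

    def test_determinism_bit_identical(self):
        a = run_simulation(SMALL_SPEC, sic_target=2.0, seed=11, track_genealogy=True)
        b = run_simulation(SMALL_SPEC, sic_target=2.0, seed=11, track_genealogy=True)
        assert a.final_ensemble.counts == b.final_ensemble.counts
        assert a.events == b.events
        assert np.array_equal(a.genealogy.length, b.genealogy.length)
        c = run_simulation(SMALL_SPEC, sic_target=2.0, seed=12)
        assert c.final_ensemble.counts != a.final_ensemble.counts

    @pytest.mark.parametrize("sic", [0.5, 1.0, 2.0, 8.0])
    @pytest.mark.parametrize("seed", [1, 17])
    def test_closed_form_mn_by_bookkeeping(self, sic, seed):
        """Mass and count conservation force Mn(t) = Mn(t0)/(SiC+1) exactly."""
        result = run_simulation(SMALL_SPEC, sic_target=sic, seed=seed)
        initial, final = result.initial_ensemble, result.final_ensemble
        assert final.total_monomers == initial.total_monomers
        assert final.total_chains == initial.total_chains + result.n_events
        expected = number_average_mw(initial) / (result.achieved_sic + 1.0)
        assert number_average_mw(final) == pytest.approx(expected, rel=1e-12)

    def test_achieved_sic_within_half_event(self):
        result = run_simulation(SMALL_SPEC, sic_target=1.24, seed=0)
        assert abs(result.achieved_sic - 1.24) <= 1 / (2 * 20)

    def test_genealogy_vs_histogram_same_final_law(self):
        """Both state representations satisfy the same bookkeeping laws."""
        tracked = run_simulation(SMALL_SPEC, sic_target=3.0, seed=5, track_genealogy=True)
        assert tracked.final_ensemble.total_chains == 20 + tracked.n_events
        assert len(tracked.events) == tracked.n_events

    def test_exhaustion_reports_partial_extent(self):
        spec = EnsembleSpec(m=2, lambda_len=2, sigma_len=0)
        with pytest.raises(ExhaustedEnsembleError) as err:
            run_simulation(spec, sic_target=5.0, seed=0)
        assert err.value.achieved_sic == pytest.approx(1.0)


class TestGenealogy:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_classification_identities(self, seed):
        result = run_simulation(SMALL_SPEC, sic_target=1.0, seed=seed, track_genealogy=True)
        table = classify_chains(result.genealogy)
        labels = table["label"].value_counts()
        assert labels.get(LABEL_INTERMEDIATE, 0) == result.n_events
        n_final = labels.get(LABEL_INITIAL_FINAL, 0) + labels.get(LABEL_DAUGHTER_FINAL, 0)
        assert n_final == 20 + result.n_events  # final pool = m + events
        # first-generation identity: 2 * reacted-initial - reacted-first-gen
        g = result.genealogy
        initial = g.parent_id < 0
        reacted_initial = int((g.reacted & initial).sum())
        first = g.generation == 1
        assert int((~g.reacted & first).sum()) == 2 * reacted_initial - int(
            (g.reacted & first).sum()
        )

    def test_generation_counts_scissions_to_form(self):
        result = run_simulation(SMALL_SPEC, sic_target=8.0, seed=9, track_genealogy=True)
        g = result.genealogy
        children = np.nonzero(g.parent_id >= 0)[0]
        assert np.all(g.generation[children] == g.generation[g.parent_id[children]] + 1)

    def test_network_export_counts(self):
        result = run_simulation(SMALL_SPEC, sic_target=1.0, seed=4, track_genealogy=True)
        edges = export_network(result.genealogy)
        assert len(edges) == 2 * result.n_events == 40
        nodes = set(edges["parent_id"]) | set(edges["child_id"])
        assert len(nodes) <= 20 + 2 * result.n_events
        assert result.genealogy.n_chains == 20 + 2 * result.n_events == 60

    def test_single_chain_single_event(self):
        spec = EnsembleSpec(m=1, lambda_len=145, sigma_len=0)
        result = run_simulation(spec, sic_target=1.0, seed=0, track_genealogy=True)
        edges = export_network(result.genealogy)
        assert len(edges) == 2 and result.genealogy.n_chains == 3


class TestReplicates:
    def test_mean_distribution_near_initial_at_one_event(self, study_spec):
        dist = run_replicates(study_spec, sic_target=0.0002, n_replicates=5, base_seed=1)
        # one scission among 5000 chains barely moves the distribution
        center = np.argmax(dist.mean_wt_pct)
        assert dist.bin_upper[center] == pytest.approx(6380.0, abs=150.0)
        assert dist.mean_wt_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_band_contains_mean(self, study_spec):
        dist = run_replicates(study_spec, sic_target=1.0, n_replicates=8, base_seed=2)
        assert np.all(dist.lo95 <= dist.mean_wt_pct + 1e-9)
        assert np.all(dist.mean_wt_pct <= dist.hi95 + 1e-9)

    def test_replicates_differ_but_are_reproducible(self, study_spec):
        a = run_replicates(study_spec, sic_target=1.0, n_replicates=4, base_seed=3)
        b = run_replicates(study_spec, sic_target=1.0, n_replicates=4, base_seed=3)
        assert np.array_equal(a.mean_wt_pct, b.mean_wt_pct)
        assert np.any(a.hi95 > a.lo95)  # replicates genuinely vary


@given(
    counts=st.dictionaries(st.integers(2, 100), st.integers(1, 5), min_size=1, max_size=6),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=30)
def test_step_conserves_mass_property(counts, seed):
    start = ChainEnsemble(dict(counts))
    ens, _ = simulate_scission_step(start, rng=seed)
    assert ens.total_monomers == start.total_monomers
    assert ens.total_chains == start.total_chains + 1
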