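"""Ensemble construction, the k(n) rate law and MW averages."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pegscission import (
    ChainEnsemble,
    DomainError,
    EnsembleSpec,
    ExhaustedEnsembleError,
    RateModel,
    build_initial_ensemble,
    chain_rate_constant,
    da_to_length,
    dispersity,
    number_average_mw,
    selection_weights,
    weight_average_mw,
)


class TestBuildInitialEnsemble:
    def test_degenerate_sigma_gives_single_length(self):
        ens = build_initial_ensemble(EnsembleSpec(m=1, lambda_len=145, sigma_len=0))
        assert ens.counts == {145: 1}

    def test_count_conservation_small(self):
        ens = build_initial_ensemble(EnsembleSpec(m=20, lambda_len=145, sigma_len=9.09))
        assert ens.total_chains == 20
        assert all(n >= 1 for n in ens.counts)

    def test_apportionment_matches_expected_counts(self, study_spec):
        """Largest-remainder counts sit within 1 of p(n)*m, totals exact."""
        ens = build_initial_ensemble(study_spec)
        assert ens.total_chains == 5000
        lengths = np.arange(1, ens.max_length + 50)
        z = (lengths - study_spec.lambda_len) / study_spec.sigma_len
        p = np.exp(-0.5 * z * z)
        p /= p.sum()
        for n, c in ens.counts.items():
            assert abs(c - p[n - 1] * 5000) <= 1.0
        mean_len = ens.total_monomers / ens.total_chains
        assert mean_len == pytest.approx(145.0, abs=0.1)

    def test_deterministic_policy_is_reproducible(self, study_spec):
        a = build_initial_ensemble(study_spec)
        b = build_initial_ensemble(study_spec)
        assert a.counts == b.counts

    def test_multinomial_policy_uses_seed(self):
        spec = EnsembleSpec(
            m=500, lambda_len=145, sigma_len=9.09, rounding_policy="multinomial"
        )
        a = build_initial_ensemble(spec, seed=1)
        b = build_initial_ensemble(spec, seed=1)
        c = build_initial_ensemble(spec, seed=2)
        assert a.counts == b.counts
        assert a.total_chains == c.total_chains == 500
        assert a.counts != c.counts


class TestRateLaw:
    def test_linear_branch_and_breakpoint(self):
        assert chain_rate_constant(30) == pytest.approx(0.8 * 2.1e9 * 30, rel=1e-12)
        assert chain_rate_constant(10) == pytest.approx(1.68e10, rel=1e-12)

    def test_sublinear_branch_oracle(self):
        expected = 0.8 * 2.1e9 * 30 * (300 / 30) ** 0.57
        assert chain_rate_constant(300) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.87e11, rel=0.01)

    def test_continuity_at_breakpoint(self):
        model = RateModel()
        left = model.prefactor * model.km * model.breakpoint
        assert chain_rate_constant(model.breakpoint, model) == pytest.approx(left)
        # approaching from above with the power branch
        just_above = model.prefactor * model.km * 30 * (31 / 30) ** 0.57
        assert chain_rate_constant(31, model) == pytest.approx(just_above)

    @given(n=st.integers(1, 10_000))
    def test_strictly_increasing(self, n):
        assert chain_rate_constant(n + 1) > chain_rate_constant(n)

    def test_rejects_sub_monomer_length(self):
        with pytest.raises(DomainError):
            chain_rate_constant(0)


class TestSelectionWeights:
    def test_two_chain_example(self):
        w = selection_weights(ChainEnsemble({10: 1, 100: 1}))
        k10, k100 = chain_rate_constant(10), chain_rate_constant(100)
        assert w[100] == pytest.approx(k100 / (k10 + k100), rel=1e-12)
        assert w[100] == pytest.approx(0.856, abs=5e-4)

    def test_single_class_and_monomer_exclusion(self):
        assert selection_weights(ChainEnsemble({50: 2})) == {50: 1.0}
        w = selection_weights(ChainEnsemble({1: 1000, 50: 1}))
        assert w[1] == 0.0 and w[50] == 1.0

    def test_exhausted_ensemble(self):
        with pytest.raises(ExhaustedEnsembleError):
            selection_weights(ChainEnsemble({1: 10}))

    @given(
        counts=st.dictionaries(
            st.integers(1, 200), st.integers(1, 5), min_size=1, max_size=8
        )
    )
    def test_matches_per_chain_brute_force(self, counts):
        """Class weights m(n)k(n) equal the sum of per-chain probabilities."""
        ens = ChainEnsemble(dict(counts))
        try:
            w = selection_weights(ens)
        except ExhaustedEnsembleError:
            assert all(n < 2 for n in counts)
            return
        chains = [n for n, c in ens.counts.items() for _ in range(c)]
        ks = [chain_rate_constant(n) if n >= 2 else 0.0 for n in chains]
        total = sum(ks)
        for n in ens.counts:
            brute = sum(k for length, k in zip(chains, ks) if length == n) / total
            assert w[n] == pytest.approx(brute, abs=1e-12)


class TestAverages:
    def test_monodisperse(self):
        ens = ChainEnsemble({145: 1})
        assert number_average_mw(ens) == weight_average_mw(ens) == 6380.0
        assert dispersity(ens) == 1.0

    def test_hand_computed_two_class(self):
        ens = ChainEnsemble({1: 1, 3: 1})
        assert number_average_mw(ens) == pytest.approx(88.0)
        assert weight_average_mw(ens) == pytest.approx(110.0)
        assert dispersity(ens) == pytest.approx(1.25)

    @given(
        counts=st.dictionaries(
            st.integers(1, 500), st.integers(1, 20), min_size=1, max_size=10
        )
    )
    def test_dispersity_at_least_one(self, counts):
        assert dispersity(ChainEnsemble(dict(counts))) >= 1.0 - 1e-12


def test_da_to_length_conversion():
    assert da_to_length(6380.0) == pytest.approx(145.0)
    assert da_to_length(400.0) == pytest.approx(9.0909, abs=1e-4)


def test_csv_round_trip(tmp_path):
    ens = ChainEnsemble({5: 3, 145: 10, 7: 1})
    path = tmp_path / "ens.csv"
    ens.to_csv(path)
    back = ChainEnsemble.from_csv(path)
    assert back.counts == ens.counts
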