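"""Truthful/noisy/repeated answers, fragmentation, and the modularity oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensembletree.engines import NussinovEngine
from ensembletree.oracle import (
    ErrorRates,
    KnownTargetOracle,
    ModularityOracle,
    default_theta,
    embed,
    error_rate_curves,
    extract,
    modularity_answer,
    noisy_answer,
    posterior_error_after_k,
    repeated_answer,
    splitting_experiment,
    truthful_answer,
)
from ensembletree.structures import RnaSequence, SecondaryStructure, signature_of


class TestTruthfulAnswers:
    def test_pair_present(self):
        t = SecondaryStructure([(1, 8)], 8)
        assert truthful_answer(t, (1, 8)) == 1
        assert truthful_answer(t, (2, 7)) == 0

    def test_matches_indicator(self, random_structures):
        for s in random_structures[:20]:
            for pair in list(s.pairs)[:3]:
                assert truthful_answer(s, pair) == 1
            assert truthful_answer(s, (1, s.n)) == int((1, s.n) in s.pairs)


class TestNoisyAnswers:
    def test_zero_rates_are_truthful(self, random_structures):
        rng = np.random.default_rng(0)
        t = random_structures[0]
        for pair in [(1, t.n), (2, t.n - 1)] + list(t.pairs)[:3]:
            bit, rec = noisy_answer(t, pair, ErrorRates(0, 0), rng)
            assert bit == rec.truthful == truthful_answer(t, pair)

    def test_certain_lie(self):
        t = SecondaryStructure([], 8)
        rng = np.random.default_rng(0)
        bit, rec = noisy_answer(t, (1, 8), ErrorRates(1.0, 0.0), rng)
        assert rec.truthful == 0 and bit == 1

    def test_empirical_flip_rate(self):
        t = SecondaryStructure([], 10)
        rates = ErrorRates(0.052, 0.007)
        rng = np.random.default_rng(1)
        flips = sum(noisy_answer(t, (1, 10), rates, rng)[0] for _ in range(100_000))
        se = np.sqrt(0.052 * (1 - 0.052) / 100_000)
        assert flips / 100_000 == pytest.approx(0.052, abs=3.5 * se)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            ErrorRates(1.2, 0.0)


class TestRepeatedQueries:
    def test_posterior_reference_values(self):
        post = posterior_error_after_k(ErrorRates(0.052, 0.007), 2)
        assert round(post.e0, 3) == 0.003
        assert round(post.e1, 5) == 0.00005

    def test_k_one_unchanged(self):
        rates = ErrorRates(0.3, 0.1)
        assert posterior_error_after_k(rates, 1) == rates

    def test_monotone_decreasing_in_k(self):
        rates = ErrorRates(0.2, 0.05)
        seq0 = [posterior_error_after_k(rates, k).e0 for k in range(1, 8)]
        seq1 = [posterior_error_after_k(rates, k).e1 for k in range(1, 8)]
        assert all(a > b for a, b in zip(seq0, seq0[1:]))
        assert all(a > b for a, b in zip(seq1, seq1[1:]))

    def test_repeated_k1_equals_noisy(self):
        t = SecondaryStructure([(1, 8)], 8)
        rates = ErrorRates(0.1, 0.1)
        bit, eff = repeated_answer(t, (1, 8), rates, 1, np.random.default_rng(3))
        assert eff == rates

    def test_concordance_mode_returns_posterior(self):
        t = SecondaryStructure([(1, 8)], 8)
        rates = ErrorRates(0.052, 0.007)
        bit, eff = repeated_answer(t, (1, 8), rates, 2, np.random.default_rng(4))
        assert eff == posterior_error_after_k(rates, 2)

    def test_large_k_drives_error_to_zero(self):
        t = SecondaryStructure([], 12)
        rates = ErrorRates(0.2, 0.2)
        rng = np.random.default_rng(5)
        wrong = sum(
            repeated_answer(t, (1, 12), rates, 9, rng)[0] for _ in range(2000)
        )
        # majority of 9 at e=0.2 has error ~0.020, far below the per-answer 0.2
        assert wrong / 2000 < 0.05

    def test_even_k_above_two_rejected(self):
        t = SecondaryStructure([], 8)
        with pytest.raises(ValueError):
            repeated_answer(t, (1, 8), ErrorRates(0.1, 0.1), 4, np.random.default_rng(0))


class TestFragmentation:
    def test_extract_example(self):
        frag = extract(RnaSequence("AUCGAUCG"), 3, 6)
        assert str(frag.inner) == "CGAU"
        assert str(frag.outer) == "AUCG"

    def test_full_span_extraction(self):
        frag = extract(RnaSequence("AUCGAUCG"), 1, 8)
        assert str(frag.inner) == "AUCGAUCG"
        assert len(frag.outer) == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            extract(RnaSequence("AUCGAUCG"), 0, 5)

    def test_length_mismatch_on_embed(self):
        with pytest.raises(ValueError):
            embed([1, 0], [0, 0, 0], 2, 5)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_embed_inverts_extract_on_vectors(self, data):
        n = data.draw(st.integers(min_value=2, max_value=30))
        vec = data.draw(st.lists(st.integers(0, 9), min_size=n, max_size=n))
        i = data.draw(st.integers(1, n - 1))
        j = data.draw(st.integers(i + 1, n))
        frag = extract(vec, i, j)
        assert len(frag.inner) + len(frag.outer) == n
        assert embed(frag.inner, frag.outer, i, j) == vec

    def test_round_trip_on_sequences_and_arrays(self):
        x = RnaSequence("GGGAAAUCCCAGC")
        frag = extract(x, 4, 9)
        assert embed(frag.inner, frag.outer, 4, 9) == str(x)
        arr = np.arange(13)
        fa = extract(arr, 4, 9)
        assert np.array_equal(embed(fa.inner, fa.outer, 4, 9), arr)


class TestModularityOracle:
    def test_default_theta_scaling(self):
        assert default_theta(500) == 31
        assert default_theta(250) == round(31 * 250 / 500)
        assert default_theta(5) >= 1

    def test_perfect_refold_gives_zero_distance(self, toy_engine):
        # two independent hairpins: cutting at the closing pair of one
        # leaves both fragments refolding exactly as embedded
        x = RnaSequence("GGGGAAAACCCCAAAGGGGAAAACCCC")
        s = toy_engine.mfe(x)
        closing = min(s.pairs)
        bit, dec = modularity_answer(x, closing, signature_of(s), toy_engine, theta=5)
        assert dec.distance == 0
        assert bit == 1

    def test_threshold_is_strict(self, toy_engine):
        x = RnaSequence("GGGGAAAACCCCAAAGGGGAAAACCCC")
        s = toy_engine.mfe(x)
        closing = min(s.pairs)
        bit, dec = modularity_answer(x, closing, signature_of(s), toy_engine, theta=0)
        assert dec.distance == 0 and bit == 0  # distance < theta must be strict

    def test_oracle_object_records_decisions(self, toy_engine):
        x = RnaSequence("GGGGAAAACCCCAAAGGGGAAAACCCC")
        s = toy_engine.mfe(x)
        orc = ModularityOracle(x, signature_of(s), toy_engine)
        orc.answer(min(s.pairs))
        assert len(orc.decisions) == 1


@pytest.fixture(scope="module")
def distances():
    return splitting_experiment([60], 12, NussinovEngine(pair_weight=2.0), seed=5)


class TestSplittingExperiment:

    def test_modular_splits_closer_than_random(self, distances):
        med = distances.groupby("kind")["d_sn"].median()
        assert med["modular"] < med["random"]

    def test_error_curves_monotone_trend(self, distances):
        # FOR/FDR move monotonically with the threshold as a trend; local
        # wiggles from discreteness are tolerated via a rank statistic
        from scipy.stats import spearmanr

        curves = error_rate_curves(distances, range(1, 40)).dropna()
        assert spearmanr(curves.theta, curves.e0).statistic <= -0.9
        assert spearmanr(curves.theta, curves.e1).statistic >= 0.9
        assert curves.e0.iloc[0] > curves.e0.iloc[-1]
        assert curves.e1.iloc[0] < curves.e1.iloc[-1]

    def test_unpairable_sequences_yield_no_modular_splits(self):
        from ensembletree.sampling import Composition

        df = splitting_experiment(
            [30], 2, NussinovEngine(), seed=6,
            composition=Composition(1, 0, 0, 0), random_splits_per_sequence=0,
        )
        assert df.empty or (df["kind"] == "random").all()


def test_known_target_oracle_records(random_structures):
    t = random_structures[0]
    orc = KnownTargetOracle(t, ErrorRates(0, 0), seed=1)
    pair = next(iter(t.pairs))
    assert orc.answer(pair, "01") == 1
    assert orc.records[0].node_key == "01"
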