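"""Discriminative motif discovery: seeds, refinement, statistics, Pareto."""

import numpy as np
import pytest
from scipy import stats

from crmkit.discovery import (
    DiscoveryParams,
    DiscriminationResult,
    build_pwm,
    canonical_word,
    dinucleotide_shuffle,
    discover,
    discriminate,
    enumerate_seeds,
    generalize_seed,
    overrepresentation,
    pareto_rank,
    seed_to_motif,
)
from crmkit.io import OrthoRegion
from crmkit.motifs import MotifDefinition, reverse_complement
from crmkit.simulate import SimConfig, background_sequence, plant, simulate_benchmark


def _region(rid, seq, n_species=1):
    seqs = {"dmel": seq}
    for i in range(n_species - 1):
        seqs[f"s{i}"] = seq
    return OrthoRegion(rid, "dmel", seqs)


class TestEnumerateSeeds:
    def test_single_window_sequence(self):
        regions = [_region("r", "ACGTACGTAC")]
        seeds = enumerate_seeds(regions, 10)
        assert seeds == [canonical_word("ACGTACGTAC")]

    def test_reverse_complement_collapsed(self):
        w = "ACGTACGTAA"
        regions = [_region("a", w), _region("b", reverse_complement(w))]
        seeds = enumerate_seeds(regions, 10, min_regions=2)
        assert seeds == [canonical_word(w)]

    def test_short_regions_contribute_nothing(self):
        assert enumerate_seeds([_region("r", "ACGTA")], 10) == []

    def test_matches_hashset_oracle(self, rng):
        w = 8
        regions = [_region(f"r{i}", background_sequence(120, 0.42, rng))
                   for i in range(3)]
        expected = set()
        for r in regions:
            s = r.reference_sequence
            for i in range(len(s) - w + 1):
                expected.add(canonical_word(s[i : i + w]))
        assert set(enumerate_seeds(regions, w)) == expected


class TestSeedToMotif:
    def test_identical_conserved_instances_sharpen_to_indicators(self, rng):
        word = "ACAGTTAG"
        regions = []
        for i in range(4):
            seq = plant(background_sequence(200, 0.42, rng), word, 50 + 10 * i, "+")
            regions.append(_region(f"r{i}", seq, n_species=5))
        params = DiscoveryParams(word_length=8, pseudocount=1e-9)
        motif = seed_to_motif(word, regions, params)
        for i, b in enumerate(word):
            assert motif.pwm[i, "ACGT".index(b)] == pytest.approx(1.0, abs=1e-6)

    def test_column_frequencies_equal_counting_oracle(self):
        words = ["ACGT", "ACGA", "TCGT"]
        pc = 0.5
        pwm = build_pwm(words, pc)
        for i in range(4):
            for j, b in enumerate("ACGT"):
                n = sum(w[i] == b for w in words)
                assert pwm[i, j] == pytest.approx((n + pc) / (len(words) + 4 * pc))

    def test_fewer_than_two_instances_discarded(self, rng):
        regions = [_region("r", background_sequence(100, 0.42, rng), n_species=5)]
        assert seed_to_motif("ACGTACGT", regions, DiscoveryParams(word_length=8)) is None

    def test_refinement_terminates_on_random_seeds(self, rng):
        """Bounded-iteration contract on many random seeds over one region set."""
        regions = [_region(f"r{i}", background_sequence(300, 0.42, rng), n_species=3)
                   for i in range(5)]
        params = DiscoveryParams(word_length=8, max_refine_iters=5, min_species=1)
        for _ in range(200):
            seed = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            seed_to_motif(seed, regions, params)  # must return, not loop


class TestOverrepresentation:
    def test_k_zero_is_one(self):
        assert overrepresentation(0, 100, 0.1) == 1.0

    def test_all_hits_closed_form(self):
        assert overrepresentation(5, 5, 0.1) == pytest.approx(1e-5)

    def test_zero_rate_sentinel(self):
        assert overrepresentation(3, 10, 0.0) == 0.0
        assert overrepresentation(0, 10, 0.0) == 1.0

    def test_matches_binomial_mass_summation(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            rate = float(rng.uniform(0.01, 0.5))
            expected = sum(stats.binom.pmf(j, n, rate) for j in range(k, n + 1))
            assert overrepresentation(k, n, rate) == pytest.approx(expected, rel=1e-6)


class TestDiscriminate:
    def test_perfect_separation(self, rng):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        pos = [_region(f"p{i}", plant(background_sequence(200, 0.42, rng),
                                      "ACAGTTAG", 50, "+"), n_species=5)
               for i in range(3)]
        neg = [_region(f"n{i}", background_sequence(200, 0.2, rng), n_species=5)
               for i in range(3)]
        res = discriminate(motif, pos, neg, DiscoveryParams(word_length=8))
        assert (res.sensitivity, res.fpr) == (1.0, 0.0)
        assert (res.n_pos_hit, res.n_neg_hit) == (3, 0)

    def test_empty_set_rejected(self):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        with pytest.raises(ValueError):
            discriminate(motif, [], [], DiscoveryParams())

    def test_threshold_monotonicity(self, small_benchmark):
        """Raising the bit threshold never increases sensitivity or fpr."""
        params = DiscoveryParams(word_length=8)
        base = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        prev = (1.1, 1.1)
        for thr in (base.score_threshold - 2, base.score_threshold,
                    base.score_threshold + 2):
            res = discriminate(base.with_threshold(thr), small_benchmark.positives,
                               small_benchmark.negatives, params)
            assert res.sensitivity <= prev[0] + 1e-12
            assert res.fpr <= prev[1] + 1e-12
            prev = (res.sensitivity, res.fpr)


class TestParetoRank:
    def _res(self, name, sens, fpr, p=0.5):
        motif = MotifDefinition(name=name, consensus="ACGTACGT")
        return DiscriminationResult(motif=motif, sensitivity=sens, fpr=fpr, overrep_p=p)

    def test_single_motif_layer_one(self):
        (r,) = pareto_rank([self._res("a", 0.5, 0.1)])
        assert r.pareto_layer == 1

    def test_dominance_two_layers(self):
        out = pareto_rank([self._res("a", 0.9, 0.1), self._res("b", 0.5, 0.3)])
        assert [r.pareto_layer for r in out] == [1, 2]

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            results = [self._res(f"m{i}", float(rng.uniform()), float(rng.uniform()))
                       for i in range(n)]
            ranked = pareto_rank([*results])
            layer_of = {r.motif.name: r.pareto_layer for r in ranked}
            # oracle: peel non-dominated fronts with explicit O(n^2) dominance
            remaining = {r.motif.name: (r.sensitivity, r.fpr) for r in results}
            layer = 1
            while remaining:
                front = [a for a, (sa, fa) in remaining.items()
                         if not any((sb >= sa and fb <= fa) and (sb > sa or fb < fa)
                                    for b, (sb, fb) in remaining.items() if b != a)]
                for a in front:
                    assert layer_of[a] == layer
                    del remaining[a]
                layer += 1


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        seq = background_sequence(500, 0.42, rng)
        shuf = dinucleotide_shuffle(seq, rng)
        def counts(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert counts(shuf) == counts(seq)
        assert shuf != seq


@pytest.fixture(scope="module")
def tiny():
    cfg = SimConfig(seed=5, n_positive=8, n_negative=10, region_length=800,
                    n_genes=10, n_target_genes=2)
    return simulate_benchmark(cfg)


class TestDiscoverChain:
    def test_deterministic(self, tiny):
        params = DiscoveryParams(word_length=8)
        a = discover(tiny.positives, tiny.negatives, params=params)
        b = discover(tiny.positives, tiny.negatives, params=params)
        assert [r.motif.name for r in a] == [r.motif.name for r in b]
        for x, y in zip(a, b):
            assert np.array_equal(x.motif.pwm, y.motif.pwm)
            assert (x.sensitivity, x.fpr, x.overrep_p) == (y.sensitivity, y.fpr, y.overrep_p)

    def test_reverse_complement_invariance(self, tiny):
        """Discovery on reverse-complemented inputs finds the same motifs
        (identical up to reverse complement)."""
        def rc_region(r):
            return OrthoRegion(r.region_id, r.reference_species,
                               {sp: reverse_complement(s) for sp, s in r.sequences.items()})

        params = DiscoveryParams(word_length=8)
        fwd = discover(tiny.positives, tiny.negatives, params=params)
        rev = discover([rc_region(r) for r in tiny.positives],
                       [rc_region(r) for r in tiny.negatives], params=params)
        assert len(fwd) == len(rev)
        for x, y in zip(fwd, rev):
            same = np.allclose(x.motif.pwm, y.motif.pwm)
            mirrored = np.allclose(x.motif.pwm, y.motif.pwm[::-1, ::-1])
            assert same or mirrored
            assert (x.sensitivity, x.fpr) == (y.sensitivity, y.fpr)

    def test_positives_equal_negatives_no_discrimination(self, tiny):
        """With identical sets, no motif separates beyond noise."""
        params = DiscoveryParams(word_length=8)
        res = discover(tiny.positives, tiny.positives, params=params)
        for r in res:
            assert abs(r.sensitivity - r.fpr) == pytest.approx(0.0)

    def test_conservation_relaxation_monotone(self, tiny):
        """Lowering the required species support never loses sensitivity."""
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        sens = []
        for c in (8, 6, 4, 2, 1):
            res = discriminate(motif, tiny.positives, tiny.negatives,
                               DiscoveryParams(word_length=8, min_species=c))
            sens.append(res.sensitivity)
        assert sens == sorted(sens)


class TestGeneralizeSeed:
    def test_returns_seed_when_nothing_improves(self, rng):
        regions = [_region(f"r{i}", background_sequence(120, 0.42, rng), n_species=3)
                   for i in range(3)]
        params = DiscoveryParams(word_length=8, min_species=1)
        seed = "ACGTTGCA"
        assert generalize_seed(seed, regions, regions, params) == seed

    def test_recovers_degenerate_consensus_from_variants(self, rng):
        """Variant planted words in different regions merge into the IUPAC
        consensus that covers them."""
        words = ["ACAGTTAG", "ACTGTTAT", "ACCGTTAG", "ACAGTTAT", "ACTGTTAG"]
        pos = [_region(f"p{i}", plant(background_sequence(300, 0.42, rng), w, 80, "+"),
                       n_species=5)
               for i, w in enumerate(words)]
        neg = [_region(f"n{i}", background_sequence(300, 0.42, rng), n_species=5)
               for i in range(5)]
        params = DiscoveryParams(word_length=8)
        out = generalize_seed("ACAGTTAG", pos, neg, params)
        assert out in ("ACHGTTAK", "ACNGTTAK", "ACHGTTAD")  # covers all variants
        from crmkit.motifs import IUPAC
        for w in words:
            assert all(b in IUPAC[c] for b, c in zip(w, out))
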