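"""Motif core: consensus expansion, log-odds, scanning, conservation, clustering."""

import itertools

import numpy as np
import pytest

from crmkit.io import OrthoRegion
from crmkit.motifs import (
    MotifDefinition,
    assess_conservation,
    cluster,
    consensus_min_score,
    dedupe_by_offset,
    iupac_to_pwm,
    log_odds,
    reverse_complement,
    scan,
)
from crmkit.simulate import background_sequence, plant

UNIFORM = np.array([0.25] * 4)


class TestIupacToPwm:
    def test_concrete_base_soft_zero(self):
        assert np.allclose(iupac_to_pwm("AAAA", soft=0.0)[0], [1, 0, 0, 0])

    def test_h_splits_three_ways(self):
        col = iupac_to_pwm("HHHH", soft=0.0)[0]
        assert np.allclose(col, [1 / 3, 1 / 3, 0, 1 / 3])

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            iupac_to_pwm("ACXG")

    def test_consensus_threshold_separates_matching_words(self):
        """The 6 words matching ACHGTTAK, and no others, pass the default
        threshold — brute force over all 4^8 words."""
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        matching = {
            "AC" + h + "GTTA" + k
            for h in "ACT"
            for k in "GT"
        }
        assert len(matching) == 6
        lod = np.log2(motif.pwm / UNIFORM)
        passing = set()
        for word in map("".join, itertools.product("ACGT", repeat=8)):
            s = sum(lod[i, "ACGT".index(b)] for i, b in enumerate(word))
            if s >= motif.score_threshold:
                passing.add(word)
        assert passing == matching


class TestLogOdds:
    def test_background_pwm_scores_zero(self):
        pwm = np.full((5, 4), 0.25)
        assert log_odds(pwm, UNIFORM, "ACGTA") == pytest.approx(0.0)

    def test_single_position_bits(self):
        pwm = iupac_to_pwm("AAAA", soft=0.0)
        assert log_odds(pwm[:1].repeat(4, axis=0), UNIFORM, "AAAA") == pytest.approx(8.0)

    def test_word_with_n_is_never_a_hit(self):
        pwm = np.full((4, 4), 0.25)
        assert log_odds(pwm, UNIFORM, "ACNT") == float("-inf")

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 12))
            pwm = rng.dirichlet(np.ones(4), size=L)
            word = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            expected = 0.0
            for i, b in enumerate(word):
                expected += np.log2(pwm[i, "ACGT".index(b)] / 0.25)
            assert log_odds(pwm, UNIFORM, word) == pytest.approx(expected)


def brute_force_scan(sequence, motif, threshold):
    """Independent oracle: score every window on both strands directly."""
    L = len(motif)
    out = set()
    for off in range(len(sequence) - L + 1):
        fwd = sequence[off : off + L]
        s = log_odds(motif.pwm, motif.background, fwd) if "N" not in fwd else float("-inf")
        if s >= threshold:
            out.add((off, "+"))
        rev = reverse_complement(fwd)
        s = log_odds(motif.pwm, motif.background, rev) if "N" not in rev else float("-inf")
        if s >= threshold:
            out.add((off, "-"))
    return out


class TestScan:
    def test_planted_word_found_at_offset(self, rng):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        seq = plant(background_sequence(400, 0.42, rng), "ACAGTTAG", 100, "+")
        hits = [(h.offset, h.strand) for h in scan(seq, motif)]
        assert (100, "+") in hits

    def test_equals_bruteforce_oracle_on_random_sequences(self, rng):
        """Exact hit-set equality with a per-window scoring oracle; relaxed
        threshold so random sequences yield hits."""
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK").with_threshold(6.0)
        for _ in range(20):
            seq = background_sequence(500, 0.42, rng)
            got = {(h.offset, h.strand) for h in scan(seq, motif)}
            assert got == brute_force_scan(seq, motif, 6.0)

    def test_all_n_sequence_yields_nothing(self):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        assert scan("N" * 100, motif) == []

    def test_short_sequence_yields_nothing(self):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        assert scan("ACG", motif) == []

    def test_reverse_complement_symmetry(self, rng):
        """Scanning the reverse complement mirrors offsets and flips strands."""
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK").with_threshold(5.0)
        L = len(motif)
        for _ in range(100):
            seq = background_sequence(300, 0.42, rng)
            fwd = {(h.offset, h.strand) for h in scan(seq, motif)}
            rc = {(len(seq) - h.offset - L, "+-"[h.strand == "+"])
                  for h in scan(reverse_complement(seq), motif)}
            assert fwd == rc

    def test_threshold_monotonicity(self, rng):
        motif = MotifDefinition(name="svbF7", consensus="ACHGTTAK")
        seq = background_sequence(2000, 0.42, rng)
        loose = {(h.offset, h.strand) for h in scan(seq, motif, score_threshold=4.0)}
        tight = {(h.offset, h.strand) for h in scan(seq, motif, score_threshold=8.0)}
        assert tight <= loose


def _planted_ortho(rng, offsets_by_species, word="ACAGTTAG", length=300):
    """Ortho region with the word planted at a per-species offset."""
    ref = background_sequence(length, 0.42, rng)
    seqs = {}
    for sp, off in offsets_by_species.items():
        base = background_sequence(length, 0.42, rng) if sp != "dmel" else ref
        seqs[sp] = plant(base, word, off, "+") if off is not None else base
    return OrthoRegion("r", "dmel", seqs)


class TestConservation:
    MOTIF = MotifDefinition(name="svbF7", consensus="ACHGTTAK")

    def test_same_offset_all_species_full_support(self, rng):
        n_sp = 10
        offsets = {sp: 120 for sp in ["dmel"] + [f"s{i}" for i in range(n_sp - 1)]}
        region = _planted_ortho(rng, offsets)
        (ch,) = assess_conservation(region, self.MOTIF, min_species=1)
        assert ch.support == n_sp
        assert set(ch.supporting_species) == set(offsets)

    def test_reference_only_hit_dropped_at_c6(self, rng):
        offsets = {"dmel": 120, **{f"s{i}": None for i in range(9)}}
        region = _planted_ortho(rng, offsets)
        assert assess_conservation(region, self.MOTIF, min_species=6) == []

    def test_shift_beyond_window_not_supported(self, rng):
        """Support counting equals a brute-force check over planted shifts."""
        delta = 20
        offsets = {"dmel": 120, **{f"s{i}": 120 + delta + 1 for i in range(9)}}
        region = _planted_ortho(rng, offsets)
        (ch,) = assess_conservation(region, self.MOTIF, min_species=1,
                                    shift_window=delta)
        assert ch.support == 1
        # within the window, every species supports
        offsets = {"dmel": 120, **{f"s{i}": 120 + delta for i in range(9)}}
        region = _planted_ortho(rng, offsets)
        (ch,) = assess_conservation(region, self.MOTIF, min_species=1,
                                    shift_window=delta)
        assert ch.support == 10

    def test_c1_returns_reference_scan(self, small_benchmark):
        """With min_species=1 conservation reduces to the reference scan."""
        for region in small_benchmark.positives[:5]:
            ref_hits = dedupe_by_offset(
                scan(region.reference_sequence, self.MOTIF, region_id=region.region_id))
            kept = assess_conservation(region, self.MOTIF, min_species=1)
            assert [ch.hit for ch in kept] == ref_hits

    def test_single_species_support_one(self, rng):
        region = _planted_ortho(rng, {"dmel": 50})
        (ch,) = assess_conservation(region, self.MOTIF, min_species=1)
        assert ch.support == 1


def brute_force_clusters(offsets, window, min_count):
    """Oracle: greedy partition recomputed with an explicit pairwise check."""
    offsets = sorted(offsets)
    groups = []
    cur = []
    for off in offsets:
        if cur and any(abs(off - o) > window for o in cur):
            groups.append(cur)
            cur = []
        cur.append(off)
    if cur:
        groups.append(cur)
    return [g for g in groups if len(g) >= min_count]


class TestCluster:
    def _hits(self, offsets):
        from crmkit.motifs import MotifHit

        return [MotifHit("r", o, "+", 10.0, "ACAGTTAG") for o in offsets]

    def test_two_hits_within_kilobase(self):
        (cl,) = cluster(self._hits([100, 900]))
        assert len(cl.hits) == 2
        assert (cl.span.start, cl.span.end) == (100, 908)

    def test_hits_beyond_window_do_not_cluster(self):
        assert cluster(self._hits([100, 1200])) == []

    def test_equals_sliding_window_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 12))
            offsets = sorted(set(rng.integers(0, 5000, n).tolist()))
            got = [[h.offset for h in cl.hits] for cl in cluster(self._hits(offsets))]
            assert got == brute_force_clusters(offsets, 1000, 2)

    def test_plus_minus_at_same_offset_count_once(self):
        from crmkit.motifs import MotifHit

        hits = [MotifHit("r", 100, "+", 10.0, "ACAGTTAG"),
                MotifHit("r", 100, "-", 12.0, "CTAACTGT"),
                MotifHit("r", 500, "+", 10.0, "ACAGTTAG")]
        (cl,) = cluster(hits)
        assert len(cl.hits) == 2  # palindromic double hit deduplicated
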