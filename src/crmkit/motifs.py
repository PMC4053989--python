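"""Motif representation, bidirectional scanning, cross-species conservation
assessment, and the two-sites-per-kilobase clustering rule.

A motif is either an IUPAC consensus, a position probability matrix, or both.
Consensus motifs are concretized as PWMs such that, at the default score
threshold, PWM scanning is exactly equivalent to IUPAC string matching: the
threshold is the minimum log-odds score over the words the consensus matches,
and a small probability mass (``soft``) left on disallowed bases keeps every
non-matching word strictly below it while allowing deliberate relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import GenomicInterval, OrthoRegion

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

NEG_INF = float("-inf")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_iupac(consensus: str) -> str:
    return consensus.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 and N -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def iupac_to_pwm(consensus: str, soft: float = 0.04) -> np.ndarray:
    """Concretize an IUPAC consensus as an L x 4 probability matrix.

    At each position the allowed bases share ``1 - soft`` equally and the
    disallowed bases share ``soft`` equally; a position allowing all four
    bases is uniform.
    """
    consensus = consensus.upper()
    if not 0 <= soft < 1:
        raise ValueError(f"soft mass must be in [0,1), got {soft}")
    pwm = np.empty((len(consensus), 4), dtype=float)
    for i, code in enumerate(consensus):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC character {code!r} at position {i}")
        k = len(allowed)
        if k == 4:
            pwm[i] = 0.25
            continue
        pwm[i] = soft / (4 - k)
        for b in allowed:
            pwm[i, BASE_INDEX[b]] = (1.0 - soft) / k
    return pwm


def consensus_min_score(consensus: str, pwm: np.ndarray, background: np.ndarray) -> float:
    """Minimum log-odds score over the words matching the consensus.

    Positions are independent, so the minimum total is the sum of per-position
    minima over the allowed bases.
    """
    lod = np.log2(pwm / background[None, :])
    total = 0.0
    for i, code in enumerate(consensus.upper()):
        allowed = IUPAC[code]
        total += min(lod[i, BASE_INDEX[b]] for b in allowed)
    return total


@dataclass
class MotifDefinition:
    """A named motif with consensus and/or PWM, background, and threshold.

    ``score_threshold`` is in bits; when omitted it defaults to the minimum
    score over consensus-matching words (consensus present) or 0 bits.
    """

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    score_threshold: float | None = None
    soft: float = 0.04

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError(f"motif {self.name}: need a consensus or a PWM")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"motif {self.name}: background must be 4 probabilities summing to 1")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            if any(c not in IUPAC for c in self.consensus):
                raise ValueError(f"motif {self.name}: invalid IUPAC consensus {self.consensus!r}")
        if self.pwm is None:
            self.pwm = iupac_to_pwm(self.consensus, self.soft)
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError(f"motif {self.name}: PWM must be L x 4")
            sums = self.pwm.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"motif {self.name}: PWM rows must sum to 1")
        if len(self.pwm) < 4:
            raise ValueError(f"motif {self.name}: motif length must be >= 4")
        if self.consensus is not None and len(self.consensus) != len(self.pwm):
            raise ValueError(f"motif {self.name}: consensus/PWM length mismatch")
        if self.score_threshold is None:
            if self.consensus is not None:
                self.score_threshold = consensus_min_score(
                    self.consensus, self.pwm, self.background
                )
            else:
                self.score_threshold = 0.0

    def __len__(self) -> int:
        return len(self.pwm)

    @property
    def log_odds_matrix(self) -> np.ndarray:
        """L x 5 log-odds (bits); column 4 (N) is -inf so N never matches."""
        with np.errstate(divide="ignore"):
            lod = np.log2(self.pwm / np.asarray(self.background)[None, :])
        out = np.full((len(self.pwm), 5), NEG_INF)
        out[:, :4] = lod
        return out

    def with_threshold(self, bits: float) -> "MotifDefinition":
        return replace(self, score_threshold=bits)

    def reverse_complement(self) -> "MotifDefinition":
        return MotifDefinition(
            name=self.name,
            consensus=None if self.consensus is None else reverse_complement_iupac(self.consensus),
            pwm=self.pwm[::-1, ::-1].copy(),
            background=np.asarray(self.background).copy(),
            score_threshold=self.score_threshold,
            soft=self.soft,
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on a reference sequence.

    ``offset`` is the 0-based position of the window on the forward strand;
    minus-strand hits score the reverse complement of the window but are
    reported at the forward offset, with ``matched_word`` being the scored
    (strand-oriented) word.
    """

    region_id: str
    offset: int
    strand: str
    score: float
    matched_word: str


@dataclass
class ConservedHit:
    """A reference hit plus the species whose independent scans support it.

    ``species_words`` maps each supporting species (the reference included)
    to the motif-oriented word of its nearest supporting hit; downstream
    motif refinement builds PWMs from these columns.
    """

    hit: MotifHit
    supporting_species: list[str]
    species_words: dict[str, str] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.supporting_species)


@dataclass
class MotifCluster:
    region_id: str
    hits: list[MotifHit]
    span: GenomicInterval


def log_odds(pwm: np.ndarray, background: Sequence[float], word: str) -> float:
    """Log2 odds of ``word`` under the PWM vs the background, in bits.

    Any N in the word yields -inf (N never matches a motif position).
    """
    pwm = np.asarray(pwm, dtype=float)
    if len(word) != len(pwm):
        raise ValueError(f"word length {len(word)} != motif length {len(pwm)}")
    bg = np.asarray(background, dtype=float)
    total = 0.0
    for i, b in enumerate(word.upper()):
        if b == "N":
            return NEG_INF
        j = BASE_INDEX[b]
        if pwm[i, j] == 0.0:
            return NEG_INF
        total += float(np.log2(pwm[i, j] / bg[j]))
    return total


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Scores of all L-windows of an encoded sequence under an L x 5 log-odds."""
    L = len(lod)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    # -inf propagates through the sum, so windows containing N never pass
    return lod[np.arange(L)[None, :], win].sum(axis=1)


def scan(sequence: str, motif: MotifDefinition, both_strands: bool = True,
         region_id: str = "", score_threshold: float | None = None) -> list[MotifHit]:
    """Report every window whose log-odds meets the motif threshold.

    Hits are sorted by offset (then strand, + first). Minus-strand hits score
    the reverse complement of the window at the same forward offset.
    """
    thr = motif.score_threshold if score_threshold is None else score_threshold
    codes = encode(sequence)
    lod = motif.log_odds_matrix
    L = len(motif)
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, lod)
    for off in np.nonzero(fwd >= thr)[0]:
        word = sequence[off : off + L].upper()
        hits.append(MotifHit(region_id, int(off), "+", float(fwd[off]), word))
    if both_strands:
        rc_lod = lod[::-1, [3, 2, 1, 0, 4]]
        rev = _window_scores(codes, rc_lod)
        for off in np.nonzero(rev >= thr)[0]:
            word = reverse_complement(sequence[off : off + L].upper())
            hits.append(MotifHit(region_id, int(off), "-", float(rev[off]), word))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def dedupe_by_offset(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Collapse +/- hits at one offset to the better-scoring one.

    Clustering and discrimination count a palindromic double hit once.
    """
    best: dict[int, MotifHit] = {}
    for h in hits:
        cur = best.get(h.offset)
        if cur is None or h.score > cur.score or (h.score == cur.score and h.strand < cur.strand):
            best[h.offset] = h
    return [best[k] for k in sorted(best)]


def assess_conservation(
    ortho_region: OrthoRegion,
    motif: MotifDefinition,
    shift_window: int = 20,
    min_species: int | None = None,
    score_threshold: float | None = None,
    dedupe: bool = True,
) -> list[ConservedHit]:
    """Alignment-free conservation: independent per-species scans.

    Each species' sequence is scanned at the same threshold; a species
    supports a reference hit if it has a hit (any strand) whose offset,
    rescaled by the sequence-length ratio, lies within ±``shift_window``.
    The reference species always supports its own hits. Hits are kept iff
    support >= ``min_species`` (default: ceil(0.6 x number of species)).
    """
    species = ortho_region.species
    n_sp = len(species)
    c = min_species if min_species is not None else int(np.ceil(0.6 * n_sp))
    ref = ortho_region.reference_species
    ref_seq = ortho_region.sequences[ref]
    ref_hits = scan(ref_seq, motif, region_id=ortho_region.region_id,
                    score_threshold=score_threshold)
    if dedupe:
        ref_hits = dedupe_by_offset(ref_hits)
    if not ref_hits:
        return []
    other_hits: dict[str, list[MotifHit]] = {}
    for sp in species:
        if sp == ref:
            continue
        sp_hits = scan(ortho_region.sequences[sp], motif, score_threshold=score_threshold)
        other_hits[sp] = dedupe_by_offset(sp_hits)
    out: list[ConservedHit] = []
    ref_len = len(ref_seq)
    for h in ref_hits:
        supporters = [ref]
        words = {ref: h.matched_word}
        for sp, sp_hits in other_hits.items():
            if not sp_hits:
                continue
            expected = h.offset * len(ortho_region.sequences[sp]) / ref_len
            dists = [abs(s.offset - expected) for s in sp_hits]
            j = int(np.argmin(dists))
            if dists[j] <= shift_window:
                supporters.append(sp)
                words[sp] = sp_hits[j].matched_word
        if len(supporters) >= c:
            out.append(ConservedHit(hit=h, supporting_species=supporters, species_words=words))
    return out


def cluster(hits: Sequence[MotifHit], window: int = 1000, min_count: int = 2,
            motif_length: int | None = None) -> list[MotifCluster]:
    """Greedy left-to-right grouping of hits pairwise within ``window`` bp.

    Hits are deduplicated by offset first; clusters never share hits. A group
    is emitted only when it has at least ``min_count`` hits.
    """
    uniq = dedupe_by_offset(hits)
    clusters: list[MotifCluster] = []
    i = 0
    L = motif_length or (len(uniq[0].matched_word) if uniq else 0)
    while i < len(uniq):
        j = i
        while j + 1 < len(uniq) and uniq[j + 1].offset - uniq[i].offset <= window:
            j += 1
        group = uniq[i : j + 1]
        if len(group) >= min_count:
            region = group[0].region_id or "region"
            span = GenomicInterval(region, group[0].offset, group[-1].offset + max(L, 1))
            clusters.append(MotifCluster(region_id=region, hits=list(group), span=span))
        i = j + 1
    return clusters


def pwm_column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation between two same-length PWMs,
    maximized over strand orientation of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"PWM shapes differ: {a.shape} vs {b.shape}")

    def mean_corr(x, y):
        out = []
        for i in range(len(x)):
            sx, sy = np.std(x[i]), np.std(y[i])
            if sx == 0 or sy == 0:
                out.append(1.0 if np.allclose(x[i], y[i]) else 0.0)
            else:
                out.append(float(np.corrcoef(x[i], y[i])[0, 1]))
        return float(np.mean(out))

    return max(mean_corr(a, b), mean_corr(a, b[::-1, ::-1]))


# Canonical motif definitions from the trichome-enhancer study: the in-vitro
# Ovo/Svb site (OvoQ6), its refined form svbF7, and the two accessory motifs.
def builtin_motifs() -> dict[str, MotifDefinition]:
    return {
        "OvoQ6": MotifDefinition(name="OvoQ6", consensus="CNGTTA"),
        "svbF7": MotifDefinition(name="svbF7", consensus="ACHGTTAK"),
        "blue": MotifDefinition(name="blue", consensus="WAGAAAGCSR"),
        "yellow": MotifDefinition(name="yellow", consensus="TTATGCAA"),
    }
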