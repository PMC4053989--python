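"""De-novo discovery of fixed-length conserved motifs that discriminate
positive (enhancer) regions from negative (inactive) regions.

The procedure is deliberately simple and fully deterministic:

1. enumerate every w-mer present in the positive set (reverse-complement
   collapsed to a canonical key), keeping seeds seen in enough regions;
2. generalize each seed into an IUPAC consensus by greedy single-base code
   expansion, accepting a step only when it strictly improves conserved
   per-region presence in positives minus presence in negatives (the move
   DREME makes with Fisher scoring, here with conservation built in);
3. refine each generalized consensus into a PWM from its evolutionarily
   conserved instances — matches supported by independent scans of the
   orthologous sequences, with the supporting species' words contributing
   columns — iterating rescan/rebuild at the minimum instance score until
   the instance set is stable;
4. filter motifs by a binomial over-representation test of conserved-hit
   counts in positives against a background pool (negative regions plus
   dinucleotide-shuffled positives);
5. score each surviving motif by per-region presence in positives
   (sensitivity) and negatives (false-positive rate) and rank the motifs
   by Pareto dominance in that plane.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import OrthoRegion
from .motifs import (
    BASES,
    IUPAC,
    MotifDefinition,
    assess_conservation,
    log_odds,
    reverse_complement,
    reverse_complement_iupac,
)

log = logging.getLogger("crmkit")


@dataclass
class DiscoveryParams:
    """Tunables of the discovery chain.

    ``word_length`` is the seed length in bp; ``shift_window`` and
    ``min_species`` parameterize conservation (see
    :func:`crmkit.motifs.assess_conservation`); ``pseudocount`` is added per
    base when building PWMs from instance columns; ``bg_order`` selects the
    shuffle preserving mono- (0) or di-nucleotide (1) composition for the
    background pool; seeds seen in fewer than ``min_positive_regions``
    positives are skipped.
    """

    word_length: int = 10
    shift_window: int = 20
    min_species: int | None = None
    pseudocount: float = 0.5
    max_refine_iters: int = 20
    bg_order: int = 1
    p_threshold: float = 1e-3
    min_positive_regions: int = 3
    max_instances: int = 200
    max_generalize_sweeps: int = 16
    shuffle_seed: int = 20130 % (2**31)

    def __post_init__(self) -> None:
        if self.word_length < 6:
            raise ValueError("word_length must be >= 6")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.bg_order not in (0, 1):
            raise ValueError("bg_order must be 0 or 1")


@dataclass
class DiscriminationResult:
    """Per-motif discrimination summary: presence fractions and ranking."""

    motif: MotifDefinition
    sensitivity: float
    fpr: float
    overrep_p: float = float("nan")
    pareto_layer: int = 0
    n_pos_hit: int = 0
    n_pos: int = 0
    n_neg_hit: int = 0
    n_neg: int = 0


def canonical_word(word: str) -> str:
    rc = reverse_complement(word)
    return word if word <= rc else rc


def enumerate_seeds(positive_regions: list[OrthoRegion], w: int,
                    min_regions: int = 1) -> list[str]:
    """All distinct w-mers in the positives' reference sequences, collapsed
    with their reverse complements, present in >= ``min_regions`` regions.
    """
    counts: dict[str, int] = {}
    for region in positive_regions:
        seq = region.reference_sequence
        seen: set[str] = set()
        for i in range(len(seq) - w + 1):
            word = seq[i : i + w]
            if "N" in word:
                continue
            seen.add(canonical_word(word))
        for word in seen:
            counts[word] = counts.get(word, 0) + 1
    return sorted(word for word, n in counts.items() if n >= min_regions)


def _iupac_regex(consensus: str) -> re.Pattern:
    """Overlap-aware regex matching the consensus on either strand."""
    def charset(code: str) -> str:
        allowed = IUPAC[code]
        return allowed if len(allowed) == 1 else f"[{allowed}]"

    fwd = "".join(charset(c) for c in consensus)
    rev = "".join(charset(c) for c in reverse_complement_iupac(consensus))
    pattern = fwd if fwd == rev else f"{fwd}|{rev}"
    return re.compile(f"(?=(?:{pattern}))")


def _consensus_conserved_regions(
    consensus: str,
    regions: list[OrthoRegion],
    params: DiscoveryParams,
) -> tuple[int, int]:
    """(regions with >= 1 conserved consensus match, total conserved matches).

    String matching here is exactly equivalent to PWM scanning at the
    default consensus threshold, but orders of magnitude cheaper, which is
    what makes greedy generalization affordable.
    """
    rx = _iupac_regex(consensus)
    n_regions = 0
    n_hits = 0
    for region in regions:
        species = region.species
        c = (params.min_species if params.min_species is not None
             else int(np.ceil(0.6 * len(species))))
        ref = region.reference_species
        ref_seq = region.sequences[ref]
        ref_offs = [m.start() for m in rx.finditer(ref_seq)]
        if not ref_offs:
            continue
        sp_offs = {sp: np.array([m.start() for m in rx.finditer(region.sequences[sp])],
                                dtype=float)
                   for sp in species if sp != ref}
        found = 0
        for off in ref_offs:
            support = 1
            for sp, offs in sp_offs.items():
                if offs.size == 0:
                    continue
                expected = off * len(region.sequences[sp]) / len(ref_seq)
                if np.min(np.abs(offs - expected)) <= params.shift_window:
                    support += 1
            if support >= c:
                found += 1
        if found:
            n_regions += 1
            n_hits += found
    return n_regions, n_hits


def generalize_seed(seed: str, positives: list[OrthoRegion],
                    negatives: list[OrthoRegion], params: DiscoveryParams) -> str:
    """Greedy IUPAC generalization of an exact seed word.

    At each sweep, every position/extra-base expansion of the current
    consensus is scored by conserved per-region presence (fraction of
    positives minus fraction of negatives with >= 1 conserved match); the
    best strictly-improving candidate is taken, lexicographic ties first.
    The concrete seed itself is returned when nothing improves.
    """
    def score(consensus: str) -> float:
        pos, _ = _consensus_conserved_regions(consensus, positives, params)
        neg, _ = _consensus_conserved_regions(consensus, negatives, params)
        return pos / len(positives) - neg / len(negatives)

    cur = seed
    cur_score = score(cur)
    for _sweep in range(params.max_generalize_sweeps):
        best_cand, best_score = None, cur_score
        for i, code in enumerate(cur):
            allowed = IUPAC[code]
            for b in BASES:
                if b in allowed:
                    continue
                merged = "".join(sorted(set(allowed) | {b}))
                new_code = next(k for k, v in IUPAC.items() if "".join(sorted(v)) == merged)
                cand = cur[:i] + new_code + cur[i + 1:]
                s = score(cand)
                # ties broken on the strand-canonical form so mirrored inputs
                # walk mirrored greedy paths
                if s > best_score or (
                    s == best_score and best_cand is not None
                    and min(cand, reverse_complement_iupac(cand))
                    < min(best_cand, reverse_complement_iupac(best_cand))
                ):
                    best_cand, best_score = cand, s
        if best_cand is None:
            break
        cur, cur_score = best_cand, best_score
    return cur


def _conserved_instance_words(
    motif: MotifDefinition,
    regions: list[OrthoRegion],
    params: DiscoveryParams,
) -> tuple[list[str], list[tuple[str, int, str]]]:
    """Motif-oriented words of all conserved instances across ``regions``.

    Returns the words (reference hit word plus the nearest supporting word
    from every supporting species) and the reference instance keys
    (region, offset, strand) used to detect refinement convergence.
    """
    words: list[str] = []
    keys: list[tuple[str, int, str]] = []
    for region in regions:
        hits = assess_conservation(
            region, motif,
            shift_window=params.shift_window,
            min_species=params.min_species,
        )
        for ch in hits:
            keys.append((region.region_id, ch.hit.offset, ch.hit.strand))
            words.append(ch.hit.matched_word)
            words.extend(ch.species_words[sp] for sp in ch.supporting_species
                         if sp != region.reference_species)
    return words, keys


def build_pwm(words: list[str], pseudocount: float) -> np.ndarray:
    """Column base frequencies of aligned equal-length words, plus pseudocount."""
    if not words:
        raise ValueError("no instance words")
    L = len(words[0])
    counts = np.full((L, 4), pseudocount, dtype=float)
    for word in words:
        for i, b in enumerate(word):
            counts[i, BASES.index(b)] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def seed_to_motif(seed: str, positive_regions: list[OrthoRegion],
                  params: DiscoveryParams) -> MotifDefinition | None:
    """Refine a seed (exact word or IUPAC consensus) into a PWM motif.

    Conserved instances of the seed are collected by consensus-exact
    matching; the PWM grows from the reference and supporting-species
    instance columns. Returns None (sentinel) when the seed has fewer than
    two conserved instances. Each refinement iteration rebuilds the PWM from
    the current instance words and rescans at the minimum score those words
    reach under the new PWM, until the reference instance set is stable.
    """
    name = f"m_{seed}"
    seed_motif = MotifDefinition(name=name, consensus=seed)
    words, keys = _conserved_instance_words(seed_motif, positive_regions, params)
    if len(keys) < 2:
        return None
    motif = seed_motif
    prev_keys = set(keys)
    for _ in range(params.max_refine_iters):
        pwm = build_pwm(words, params.pseudocount)
        thr = min(log_odds(pwm, motif.background, w) for w in words)
        motif = MotifDefinition(name=name, pwm=pwm,
                                background=motif.background, score_threshold=thr)
        words, keys = _conserved_instance_words(motif, positive_regions, params)
        if len(keys) < 2:
            return None
        if len(keys) > params.max_instances:
            # the threshold has collapsed and the motif matches everywhere;
            # such a motif cannot discriminate, so drop it
            return None
        cur = set(keys)
        if cur == prev_keys:
            break
        prev_keys = cur
    return motif


def overrepresentation(k_conserved_hits: int, n_positions_scanned: int,
                       bg_rate: float) -> float:
    """Binomial upper-tail probability of >= k conserved hits in n positions."""
    if not 0 <= k_conserved_hits <= n_positions_scanned:
        raise ValueError("need 0 <= k <= n")
    if bg_rate <= 0.0:
        if k_conserved_hits > 0:
            log.warning("background rate 0 with k=%d: p-value sentinel 0", k_conserved_hits)
            return 0.0
        return 1.0
    if k_conserved_hits == 0:
        return 1.0
    return float(stats.binom.sf(k_conserved_hits - 1, n_positions_scanned, bg_rate))


def _conserved_hit_count(motif: MotifDefinition, regions: list[OrthoRegion],
                         params: DiscoveryParams) -> tuple[int, int]:
    """Total conserved (offset-deduplicated) hits and scanned positions."""
    k = 0
    n = 0
    L = len(motif)
    for region in regions:
        hits = assess_conservation(region, motif, shift_window=params.shift_window,
                                   min_species=params.min_species)
        k += len(hits)
        n += max(len(region.reference_sequence) - L + 1, 0)
    return k, n


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erikson shuffle preserving dinucleotide composition.

    Builds the multigraph of observed dinucleotide transitions and samples a
    random Eulerian path starting and ending at the original terminal bases.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random "last edge" per non-terminal vertex forming a tree into `last`
    # (standard Eulerian-path construction); retry until connectivity holds
    vertices = sorted(edges)
    for _ in range(100):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if _reaches_last(last_edge, vertices, last):
            break
    else:  # pragma: no cover - pathological composition
        return seq
    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        idx = rng.permutation(len(rest))
        order = [rest[i] for i in idx]
        if v != last:
            order.append(last_edge[v])
        shuffled_edges[v] = order
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _reaches_last(last_edge: dict[str, str], vertices: list[str], last: str) -> bool:
    for v in vertices:
        if v == last:
            continue
        seen = {v}
        cur = v
        while cur != last:
            cur = last_edge.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))])


def shuffled_background(positives: list[OrthoRegion], params: DiscoveryParams) -> list[OrthoRegion]:
    """Per-species independent shuffles of the positive ortholog sets.

    Shuffling every species independently preserves composition but destroys
    both planted motifs and cross-species correspondence, giving a null for
    conserved-hit frequency.
    """
    rng = np.random.default_rng(params.shuffle_seed)
    shuffle = dinucleotide_shuffle if params.bg_order == 1 else mononucleotide_shuffle
    out = []
    for region in positives:
        seqs = {sp: shuffle(s, rng) for sp, s in sorted(region.sequences.items())}
        out.append(OrthoRegion(region_id=f"shuf_{region.region_id}",
                               reference_species=region.reference_species,
                               sequences=seqs))
    return out


def discriminate(motif: MotifDefinition, positives: list[OrthoRegion],
                 negatives: list[OrthoRegion], params: DiscoveryParams) -> DiscriminationResult:
    """Per-region conserved presence/absence of the motif in each set."""
    if not positives or not negatives:
        raise ValueError("positive and negative sets must be non-empty")

    def present(region: OrthoRegion) -> bool:
        return bool(assess_conservation(region, motif, shift_window=params.shift_window,
                                        min_species=params.min_species))

    n_pos_hit = sum(present(r) for r in positives)
    n_neg_hit = sum(present(r) for r in negatives)
    return DiscriminationResult(
        motif=motif,
        sensitivity=n_pos_hit / len(positives),
        fpr=n_neg_hit / len(negatives),
        n_pos_hit=n_pos_hit,
        n_pos=len(positives),
        n_neg_hit=n_neg_hit,
        n_neg=len(negatives),
    )


def pareto_rank(results: list[DiscriminationResult]) -> list[DiscriminationResult]:
    """Assign Pareto layers in the (sensitivity, fpr) plane and sort.

    A dominates B iff sensitivity_A >= sensitivity_B and fpr_A <= fpr_B with
    at least one strict. Layer 1 is the non-dominated front; peeling it off
    yields subsequent layers. Within a layer, sort by over-representation
    p-value ascending, ties by motif name.
    """
    if not results:
        return []
    remaining = list(results)
    layer = 1
    out: list[DiscriminationResult] = []
    while remaining:
        front = []
        rest = []
        for a in remaining:
            dominated = any(
                (b.sensitivity >= a.sensitivity and b.fpr <= a.fpr)
                and (b.sensitivity > a.sensitivity or b.fpr < a.fpr)
                for b in remaining
            )
            (rest if dominated else front).append(a)
        for r in front:
            r.pareto_layer = layer
        front.sort(key=lambda r: (r.overrep_p, r.motif.name))
        out.extend(front)
        remaining = rest
        layer += 1
    return out


def discover(positives: list[OrthoRegion], negatives: list[OrthoRegion],
             background_pool: list[OrthoRegion] | None = None,
             params: DiscoveryParams | None = None) -> list[DiscriminationResult]:
    """Full discovery chain; deterministic given inputs and parameters."""
    params = params or DiscoveryParams()
    if not positives or not negatives:
        raise ValueError("positive and negative sets must be non-empty")
    if background_pool is None:
        background_pool = list(negatives) + shuffled_background(positives, params)
    seeds = enumerate_seeds(positives, params.word_length, params.min_positive_regions)
    log.info("discovery: %d seeds (w=%d, >= %d regions) from %d positives",
             len(seeds), params.word_length, params.min_positive_regions, len(positives))
    # cheap conserved-instance prefilter, then greedy IUPAC generalization;
    # seeds converging to the same (canonical) consensus are refined once
    consensi: dict[str, str] = {}
    for seed in seeds:
        _, n_inst = _consensus_conserved_regions(seed, positives, params)
        if n_inst < 2:
            continue
        gen = generalize_seed(seed, positives, negatives, params)
        rc = reverse_complement_iupac(gen)
        consensi.setdefault(min(gen, rc), seed)
    log.info("discovery: %d seeds with conserved instances -> %d consensi",
             len(consensi), len(set(consensi)))
    results: list[DiscriminationResult] = []
    for consensus in sorted(consensi):
        motif = seed_to_motif(consensus, positives, params)
        if motif is None:
            continue
        k, n = _conserved_hit_count(motif, positives, params)
        k_bg, n_bg = _conserved_hit_count(motif, background_pool, params)
        bg_rate = k_bg / n_bg if n_bg else 0.0
        p = overrepresentation(k, n, bg_rate)
        if p > params.p_threshold:
            continue
        res = discriminate(motif, positives, negatives, params)
        res.overrep_p = p
        results.append(res)
    if not results:
        log.warning("discovery: no motif survived the over-representation filter")
        return []
    # collapse duplicate motifs (different seeds converging to one instance set)
    results = _dedupe_motifs(results)
    return pareto_rank(results)


def _dedupe_motifs(results: list[DiscriminationResult]) -> list[DiscriminationResult]:
    seen: dict[bytes, DiscriminationResult] = {}
    for r in sorted(results, key=lambda r: r.motif.name):
        key = np.round(r.motif.pwm, 6).tobytes()
        rc_key = np.round(r.motif.pwm[::-1, ::-1], 6).tobytes()
        if key not in seen and rc_key not in seen:
            seen[key] = r
    return list(seen.values())
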