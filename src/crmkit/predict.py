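"""Combinatorial enhancer prediction and per-species architecture reports.

A candidate cis-regulatory module is a ChIP peak region that (i) is assigned
to a regulated gene and (ii) contains at least one evolutionarily conserved
binding-site motif of the factor (svbF7) — the hard gate reflecting that the
factor's site is necessary (though not sufficient) for enhancer activity.
Accessory motifs (blue, yellow) are annotated and define the composition
class; the per-species architecture report redraws each candidate across the
ortholog set with conserved hits drawn filled and reference-only hits open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import GenomicInterval, OrthoRegion
from .motifs import ConservedHit, MotifDefinition, assess_conservation, dedupe_by_offset, scan

log = logging.getLogger("crmkit")

COMPOSITION_CLASSES = ("svb_only", "svb_blue", "svb_yellow", "all_three", "none")


@dataclass
class PredictRules:
    """Gating and scoring knobs for candidate prediction.

    The factor's motif (``anchor``) is a hard requirement; each additional
    distinct motif class present adds ``extra_class_weight`` to the score on
    top of the best anchor bit score. ``padding`` widens the candidate
    interval beyond the peak on both sides.
    """

    anchor: str = "svbF7"
    extra_class_weight: float = 0.5
    shift_window: int = 20
    min_species: int | None = None
    padding: int = 0


@dataclass
class EnhancerCandidate:
    interval: GenomicInterval
    gene_id: str
    peak_ref: int
    motif_hits: dict[str, list[ConservedHit]] = field(default_factory=dict)
    composition_class: str = "none"
    score: float = 0.0


def classify_architecture(candidate: EnhancerCandidate, anchor: str = "svbF7") -> str:
    """Composition class from presence of conserved anchor/blue/yellow hits."""
    has = {name for name, hits in candidate.motif_hits.items() if hits}
    if anchor not in has:
        return "none"
    blue = "blue" in has
    yellow = "yellow" in has
    if blue and yellow:
        return "all_three"
    if blue:
        return "svb_blue"
    if yellow:
        return "svb_yellow"
    return "svb_only"


def predict(
    peak_gene_map: dict[int, str],
    target_genes: set[str],
    ortho_regions_for_peaks: dict[int, OrthoRegion],
    motifs: dict[str, MotifDefinition],
    rules: PredictRules | None = None,
) -> list[EnhancerCandidate]:
    """Rank peak regions of regulated genes that carry the anchor motif.

    Candidates are sorted by score descending, ties by gene id then peak
    index. Every candidate is guaranteed to contain at least one conserved
    anchor hit.
    """
    rules = rules or PredictRules()
    if rules.anchor not in motifs:
        raise ValueError(f"anchor motif {rules.anchor!r} not among supplied motifs")
    candidates: list[EnhancerCandidate] = []
    for peak_idx, gene in sorted(peak_gene_map.items()):
        if gene not in target_genes:
            continue
        region = ortho_regions_for_peaks.get(peak_idx)
        if region is None:
            continue
        hits_by_motif = {
            name: assess_conservation(region, m, shift_window=rules.shift_window,
                                      min_species=rules.min_species)
            for name, m in motifs.items()
        }
        anchor_hits = hits_by_motif.get(rules.anchor, [])
        if not anchor_hits:
            continue
        best_bits = max(ch.hit.score for ch in anchor_hits)
        extra = sum(1 for name, hs in hits_by_motif.items() if hs and name != rules.anchor)
        iv = region.interval or GenomicInterval(region.region_id, 0,
                                                len(region.reference_sequence))
        if rules.padding:
            iv = GenomicInterval(iv.chrom, max(0, iv.start - rules.padding),
                                 iv.end + rules.padding, iv.strand, iv.id)
        cand = EnhancerCandidate(
            interval=iv,
            gene_id=gene,
            peak_ref=peak_idx,
            motif_hits=hits_by_motif,
            score=best_bits + rules.extra_class_weight * extra,
        )
        cand.composition_class = classify_architecture(cand, rules.anchor)
        candidates.append(cand)
    if not candidates:
        log.warning("predict: no candidate passed the anchor-motif gate")
    candidates.sort(key=lambda c: (-c.score, c.gene_id, c.peak_ref))
    return candidates


@dataclass
class ArchitectureMap:
    """Per-species ordered motif layout of one candidate region.

    Each entry is (motif name, offset, orientation, conserved flag); on the
    reference species the flag marks hits traceable across species (drawn
    filled) versus reference-only hits (drawn open).
    """

    region_id: str
    entries: dict[str, list[tuple[str, int, str, bool]]]


def architecture_report(
    ortho_region: OrthoRegion,
    motifs: dict[str, MotifDefinition],
    shift_window: int = 20,
    min_species: int | None = None,
) -> ArchitectureMap:
    """Independent per-species scans at the shared per-motif thresholds.

    A hit is flagged conserved when it lies within the shift window of a
    conserved reference hit's length-rescaled offset.
    """
    ref = ortho_region.reference_species
    ref_len = len(ortho_region.sequences[ref])
    conserved_offsets: dict[str, list[int]] = {}
    for name, m in motifs.items():
        kept = assess_conservation(ortho_region, m, shift_window=shift_window,
                                   min_species=min_species)
        conserved_offsets[name] = [ch.hit.offset for ch in kept]
    entries: dict[str, list[tuple[str, int, str, bool]]] = {}
    for sp in ortho_region.species:
        seq = ortho_region.sequences[sp]
        ratio = len(seq) / ref_len
        rows: list[tuple[str, int, str, bool]] = []
        for name, m in motifs.items():
            for h in dedupe_by_offset(scan(seq, m, region_id=ortho_region.region_id)):
                flag = any(abs(h.offset - o * ratio) <= shift_window
                           for o in conserved_offsets[name])
                rows.append((name, h.offset, h.strand, flag))
        rows.sort(key=lambda r: (r[1], r[0]))
        entries[sp] = rows
    return ArchitectureMap(region_id=ortho_region.region_id, entries=entries)


def render_architecture(arch: ArchitectureMap, width: int = 72,
                        region_length: int | None = None) -> str:
    """Text schematic: one line per species, motif glyphs at scaled offsets.

    Glyphs: s/b/y for conserved svbF7/blue/yellow, uppercased when the hit is
    not traceable across species (open box).
    """
    glyphs = {"svbF7": "s", "blue": "b", "yellow": "y"}
    max_off = max((off for rows in arch.entries.values() for _, off, _, _ in rows),
                  default=0)
    span = region_length or (max_off + 1)
    lines = [f"# {arch.region_id}"]
    for sp, rows in arch.entries.items():
        line = ["-"] * width
        for name, off, _strand, conserved in rows:
            pos = min(int(off / span * width), width - 1)
            g = glyphs.get(name, name[0].lower())
            line[pos] = g if conserved else g.upper()
        lines.append(f"{sp:>12} {''.join(line)}")
    return "\n".join(lines)
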