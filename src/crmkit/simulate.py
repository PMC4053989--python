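"""Synthetic benchmark generator with ground truth.

Emulates, at desk scale, the data layout of a TF-target mapping study:

* orthologous sequence sets across ~10 Drosophilid-like species under a star
  phylogeny, with planted binding-site instances mutating at a reduced rate
  (phylogenetic footprints) and an optional small offset jitter standing in
  for indel drift;
* a positive/negative enhancer training set — positives carry svbF7
  instances (single-copy biased) plus optional blue/yellow motifs, negatives
  carry core-only decoys (the in-vitro CnGTTa core with flanks resampled so
  the refined consensus never matches);
* a gene universe on one synthetic chromosome, each gene with a TSS and one
  regulatory region; target genes' regions are true enhancers with planted
  conserved svbF7;
* ChIP-like peaks centered on planted sites with Gaussian jitter, plus
  background peaks near non-target genes;
* a replicated log2 expression matrix in which target genes are down in the
  TF mutant and at least a further two-fold down in the cofactor mutant;
* a JSON-serializable truth manifest recording every planted instance,
  region label, effect size and peak-enhancer link.

All randomness flows from one seed; identical configs give byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io import (
    GenomicInterval,
    OrthoRegion,
    TSSTable,
    write_bed,
    write_expression,
    write_ortho_dir,
    write_tss,
)
from .motifs import BASES, IUPAC, MotifDefinition, reverse_complement, scan
from .peaks import PeakSet

log = logging.getLogger("crmkit")

SPECIES = ["dmel", "dsim", "dsec", "dyak", "dere", "dana", "dpse", "dper", "dwil", "dvir"]
REFERENCE = "dmel"

SVBF7 = "ACHGTTAK"
BLUE = "WAGAAAGCSR"
YELLOW = "TTATGCAA"
CORE = "CNGTTA"  # in-vitro Ovo/Svb core, inside svbF7 at offset 1


@dataclass
class PlantSpec:
    """How one motif is planted: presence probability per region and the
    distribution of copy numbers given presence (single-copy biased for the
    factor's own site, as most real enhancers carry one)."""

    name: str
    consensus: str
    prob_region: float = 1.0
    copy_probs: tuple[float, ...] = (1.0,)  # P(1 copy), P(2), ...


@dataclass
class SimConfig:
    n_species: int = 10
    divergence: float = 0.25
    conservation_factor: float = 0.1
    n_positive: int = 14
    n_negative: int = 25
    region_length: int = 1500
    gc: float = 0.42
    offset_jitter: int = 5
    svb_prob_positive: float = 0.9
    svb_copy_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    blue_prob: float = 0.5
    yellow_prob: float = 0.5
    decoy_prob_negative: float = 0.6
    decoy_copy_probs: tuple[float, ...] = (0.7, 0.3)
    n_genes: int = 1000
    n_target_genes: int = 150
    svb_effect_mu: float = -0.8
    svb_effect_sd: float = 0.3
    pri_extra_mu: float = -1.5
    pri_extra_sd: float = 0.4
    noise_sd: float = 0.2
    baseline_mu: float = 8.0
    baseline_sd: float = 1.0
    replicates: int = 5
    peak_jitter_sd: float = 150.0
    peak_width: int = 600
    n_background_peaks: int = 100
    gene_slot: int = 6000
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.divergence, self.conservation_factor, self.gc,
                  self.svb_prob_positive, self.blue_prob, self.yellow_prob,
                  self.decoy_prob_negative):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes exceeds n_genes")
        if not 2 <= self.n_species <= len(SPECIES):
            raise ValueError(f"n_species must be in [2,{len(SPECIES)}]")

    @property
    def species(self) -> list[str]:
        return SPECIES[: self.n_species]


@dataclass
class PlantedInstance:
    motif: str
    offset: int
    strand: str
    word: str
    species_offsets: dict[str, int] = field(default_factory=dict)
    species_mutated: dict[str, bool] = field(default_factory=dict)


@dataclass
class Benchmark:
    """In-memory bundle plus the ground-truth manifest."""

    config: SimConfig
    positives: list[OrthoRegion]
    negatives: list[OrthoRegion]
    gene_regions: dict[str, list[OrthoRegion]]
    tss: TSSTable
    peaks: PeakSet
    expression: ExpressionMatrix
    manifest: dict


# ---------------------------------------------------------------------------
# primitive generators

def background_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """IID background with P(G) = P(C) = gc/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def sample_consensus_word(consensus: str, rng: np.random.Generator) -> str:
    """A uniform word matching an IUPAC consensus."""
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in consensus.upper())


def plant(sequence: str, motif_word: str, offset: int, strand: str) -> str:
    """Replace the substring at ``offset`` by the word (reverse complement on −)."""
    word = motif_word if strand == "+" else reverse_complement(motif_word)
    if offset < 0 or offset + len(word) > len(sequence):
        raise ValueError(f"plant at {offset} outside sequence of length {len(sequence)}")
    return sequence[:offset] + word + sequence[offset + len(word):]


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at ``rate`` to a uniformly random different base."""
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = {ord(b): i for i, b in enumerate(BASES)}
    arr = np.array([lut.get(c, -1) for c in codes], dtype=np.int64)
    hit = (rng.random(len(arr)) < rate) & (arr >= 0)
    arr[hit] = (arr[hit] + 1 + rng.integers(0, 3, size=int(hit.sum()))) % 4
    out = np.array(list(seq))
    out[hit] = np.array(list(BASES))[arr[hit]]
    return "".join(out)


def evolve_ortholog(
    ref_sequence: str,
    planted_sites: list[PlantedInstance],
    divergence: float,
    conservation_factor: float,
    rng: np.random.Generator,
    offset_jitter: int = 0,
    species: str = "",
) -> str:
    """One species' sequence under a star phylogeny (no indels).

    The whole sequence mutates at ``divergence`` per base; each planted word
    is then re-planted from a copy mutated at ``divergence x
    conservation_factor`` and shifted by a uniform jitter of up to
    ``offset_jitter`` bp, overwriting the fully diverged copy. Realized
    per-species offsets and whether the word changed are recorded on the
    planted instances.
    """
    seq = mutate(ref_sequence, divergence, rng)
    for site in planted_sites:
        word = mutate(site.word, divergence * conservation_factor, rng)
        j = int(rng.integers(-offset_jitter, offset_jitter + 1)) if offset_jitter else 0
        off = min(max(site.offset + j, 0), len(seq) - len(word))
        seq = plant(seq, word, off, site.strand)
        if species:
            site.species_offsets[species] = off
            site.species_mutated[species] = word != site.word
    return seq


def _sample_copies(copy_probs: tuple[float, ...], rng: np.random.Generator) -> int:
    p = np.asarray(copy_probs, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum())) + 1


def _place_offsets(n: int, length: int, word_len: int, rng: np.random.Generator,
                   occupied: list[tuple[int, int]], min_gap: int = 25) -> list[int]:
    """Non-overlapping plant offsets, uniform over the region interior."""
    offsets = []
    for _ in range(n):
        for _attempt in range(200):
            off = int(rng.integers(10, length - word_len - 10))
            if all(off + word_len + min_gap <= s or e + min_gap <= off
                   for s, e in occupied):
                occupied.append((off, off + word_len))
                offsets.append(off)
                break
    return offsets


def _decoy_word(rng: np.random.Generator) -> str:
    """An 8-mer with the CnGTTa core but flanks spoiling the refined consensus."""
    svb = MotifDefinition(name="svbF7", consensus=SVBF7)
    while True:
        core = sample_consensus_word(CORE, rng)
        x1 = BASES[rng.integers(4)]
        x2 = BASES[rng.integers(4)]
        word = x1 + core + x2
        if not scan(word, svb):
            return word


# ---------------------------------------------------------------------------
# region construction

def _build_region(
    region_id: str,
    config: SimConfig,
    plants: list[tuple[str, str]],  # (motif name, consensus or literal word)
    rng: np.random.Generator,
    interval: GenomicInterval | None = None,
    forbid: MotifDefinition | None = None,
) -> tuple[OrthoRegion, list[PlantedInstance]]:
    """One ortholog set with the requested motifs planted and evolved.

    With ``forbid`` set, the reference sequence is redrawn until the
    forbidden motif has no match on either strand (used to guarantee
    negatives never contain a full svbF7 by chance).
    """
    length = config.region_length
    for _attempt in range(100):
        ref = background_sequence(length, config.gc, rng)
        occupied: list[tuple[int, int]] = []
        instances: list[PlantedInstance] = []
        for name, pattern in plants:
            word = (_decoy_word(rng) if name == "decoy"
                    else sample_consensus_word(pattern, rng))
            offs = _place_offsets(1, length, len(word), rng, occupied)
            if not offs:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            ref = plant(ref, word, offs[0], strand)
            instances.append(PlantedInstance(motif=name, offset=offs[0],
                                             strand=strand, word=word))
        if forbid is None or not scan(ref, forbid):
            break
    else:  # pragma: no cover - forbidden motif kept reappearing
        raise RuntimeError(f"{region_id}: could not exclude forbidden motif")
    for inst in instances:
        inst.species_offsets[REFERENCE] = inst.offset
        inst.species_mutated[REFERENCE] = False
    seqs = {REFERENCE: ref}
    for sp in config.species:
        if sp == REFERENCE:
            continue
        seqs[sp] = evolve_ortholog(ref, instances, config.divergence,
                                   config.conservation_factor, rng,
                                   offset_jitter=config.offset_jitter, species=sp)
    region = OrthoRegion(region_id=region_id, reference_species=REFERENCE,
                         sequences=seqs, interval=interval)
    return region, instances


def _plant_list(config: SimConfig, rng: np.random.Generator,
                positive: bool) -> list[tuple[str, str]]:
    plants: list[tuple[str, str]] = []
    if positive:
        if rng.random() < config.svb_prob_positive:
            for _ in range(_sample_copies(config.svb_copy_probs, rng)):
                plants.append(("svbF7", SVBF7))
        if rng.random() < config.blue_prob:
            plants.append(("blue", BLUE))
        if rng.random() < config.yellow_prob:
            plants.append(("yellow", YELLOW))
    else:
        if rng.random() < config.decoy_prob_negative:
            for _ in range(_sample_copies(config.decoy_copy_probs, rng)):
                plants.append(("decoy", CORE))
    return plants


# ---------------------------------------------------------------------------
# full benchmark

def simulate_benchmark(config: SimConfig | None = None) -> Benchmark:
    """Generate the complete in-memory benchmark with its truth manifest."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    svb_motif = MotifDefinition(name="svbF7", consensus=SVBF7)
    manifest: dict = {"config": asdict(config), "regions": {}, "genes": {}, "peaks": []}

    # --- enhancer training fragments (positives / negatives)
    positives: list[OrthoRegion] = []
    negatives: list[OrthoRegion] = []
    for i in range(config.n_positive):
        rid = f"pos_{i:02d}"
        region, inst = _build_region(rid, config, _plant_list(config, rng, True), rng)
        positives.append(region)
        manifest["regions"][rid] = {"label": "positive", "planted": _inst_dicts(inst)}
    for i in range(config.n_negative):
        rid = f"neg_{i:02d}"
        region, inst = _build_region(rid, config, _plant_list(config, rng, False), rng,
                                     forbid=svb_motif)
        negatives.append(region)
        manifest["regions"][rid] = {"label": "negative", "planted": _inst_dicts(inst)}

    # --- gene universe on one synthetic chromosome
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    target_idx = sorted(rng.choice(config.n_genes, size=config.n_target_genes,
                                   replace=False).tolist())
    target_set = {gene_ids[i] for i in target_idx}
    gene_regions: dict[str, list[OrthoRegion]] = {}
    tss_records: list[tuple[str, GenomicInterval]] = []
    peaks: list[GenomicInterval] = []
    peak_links: list[dict] = []
    slot = config.gene_slot
    for i, gene in enumerate(gene_ids):
        start = i * slot
        region_iv = GenomicInterval(config.chrom, start + 1000, start + 1000 + config.region_length)
        tss_pos = start + 4000
        tss_records.append((gene, GenomicInterval(config.chrom, tss_pos, tss_pos + 1,
                                                  "+" if rng.random() < 0.5 else "-")))
        is_target = gene in target_set
        plants = _plant_list(config, rng, positive=True) if is_target else []
        if is_target and not any(n == "svbF7" for n, _ in plants):
            plants.insert(0, ("svbF7", SVBF7))  # a true enhancer always has the site
        region, inst = _build_region(f"{gene}_reg", config, plants, rng,
                                     interval=region_iv)
        gene_regions[gene] = [region]
        manifest["genes"][gene] = {
            "target": bool(is_target),
            "region_id": region.region_id,
            "planted": _inst_dicts(inst),
        }
        if is_target:
            svb_sites = [s for s in inst if s.motif == "svbF7"]
            site = svb_sites[0]
            center = region_iv.start + site.offset + len(site.word) // 2
            center += int(round(rng.normal(0.0, config.peak_jitter_sd)))
            half = config.peak_width // 2
            pk = GenomicInterval(config.chrom, max(0, center - half), center + half,
                                 id=f"peak_{len(peaks):04d}")
            peak_links.append({"peak": len(peaks), "gene": gene,
                               "region_id": region.region_id, "true_enhancer": True})
            peaks.append(pk)

    # background peaks over non-target genes
    null_idx = [i for i in range(config.n_genes) if gene_ids[i] not in target_set]
    bg_pick = rng.choice(len(null_idx), size=min(config.n_background_peaks, len(null_idx)),
                         replace=False)
    for k in sorted(bg_pick.tolist()):
        i = null_idx[k]
        start = i * slot
        center = start + 1000 + int(rng.integers(0, config.region_length))
        half = config.peak_width // 2
        pk = GenomicInterval(config.chrom, max(0, center - half), center + half,
                             id=f"peak_{len(peaks):04d}")
        peak_links.append({"peak": len(peaks), "gene": gene_ids[i],
                           "region_id": f"{gene_ids[i]}_reg", "true_enhancer": False})
        peaks.append(pk)
    manifest["peaks"] = peak_links

    # --- expression matrix
    expression = simulate_expression(config, gene_ids, target_set, rng, manifest)

    tss = TSSTable(tss_records)
    peak_set = PeakSet(peaks=peaks, provenance="synthetic benchmark peaks")
    log.info("benchmark seed=%d: %d positives, %d negatives, %d genes (%d targets), %d peaks",
             config.seed, len(positives), len(negatives), config.n_genes,
             config.n_target_genes, len(peaks))
    return Benchmark(config=config, positives=positives, negatives=negatives,
                     gene_regions=gene_regions, tss=tss, peaks=peak_set,
                     expression=expression, manifest=manifest)


def _inst_dicts(instances: list[PlantedInstance]) -> list[dict]:
    return [asdict(i) for i in instances]


def simulate_expression(config: SimConfig, gene_ids: list[str], target_set: set[str],
                        rng: np.random.Generator, manifest: dict | None = None) -> ExpressionMatrix:
    """Replicated log2 intensities; target effects are rejection-sampled so
    every target truly satisfies the defining property (down in svb, at
    least a further two-fold down in pri)."""
    n = len(gene_ids)
    baseline = rng.normal(config.baseline_mu, config.baseline_sd, size=n)
    fc_svb = np.zeros(n)
    extra_pri = np.zeros(n)
    for i, gene in enumerate(gene_ids):
        if gene in target_set:
            v = rng.normal(config.svb_effect_mu, config.svb_effect_sd)
            while v >= 0.0:
                v = rng.normal(config.svb_effect_mu, config.svb_effect_sd)
            fc_svb[i] = v
            e = rng.normal(config.pri_extra_mu, config.pri_extra_sd)
            while e > -1.0:  # defining property: a further >= 2-fold drop
                e = rng.normal(config.pri_extra_mu, config.pri_extra_sd)
            extra_pri[i] = e
            if manifest is not None:
                manifest["genes"][gene]["log2fc_svb"] = float(v)
                manifest["genes"][gene]["log2fc_pri"] = float(v + e)
    cols = {}
    conditions = {}
    for cond, effect in (("wt", np.zeros(n)), ("svb", fc_svb), ("pri", fc_svb + extra_pri)):
        for r in range(config.replicates):
            s = f"{cond}_{r + 1}"
            cols[s] = baseline + effect + rng.normal(0.0, config.noise_sd, size=n)
            conditions[s] = cond
    values = pd.DataFrame(cols, index=gene_ids)
    return ExpressionMatrix(values=values, conditions=conditions)


# ---------------------------------------------------------------------------
# file bundle

def generate_benchmark(config: SimConfig, out_dir: str | Path) -> Benchmark:
    """Generate and write the full file bundle plus ``manifest.json``."""
    bench = simulate_benchmark(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ortho_dir(out / "positives", bench.positives, REFERENCE, config.species)
    write_ortho_dir(out / "negatives", bench.negatives, REFERENCE, config.species)
    write_ortho_dir(out / "gene_regions",
                    [r for regs in bench.gene_regions.values() for r in regs],
                    REFERENCE, config.species)
    write_bed(out / "peaks.bed", bench.peaks.peaks)
    write_tss(out / "tss.tsv", bench.tss)
    write_expression(out / "expression.tsv", out / "conditions.tsv", bench.expression)
    (out / "manifest.json").write_text(json.dumps(bench.manifest, indent=1, sort_keys=True))
    return bench
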