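# Methods

## Scope and data model

`crmkit` re-creates, at desk scale, the computational chain used to map a
transcription factor's direct-target enhancers: conserved-motif scanning
and clustering, discriminative de-novo motif discovery between validated
enhancers and inactive regions, motif–ChIP-peak cross-correlation, a
two-mutant expression filter defining the regulated gene set, and
combinatorial enhancer prediction with per-species architecture reports.
Wet-lab stages (transgenesis, in-situ validation, mutagenesis), peak
calling, and microarray normalization are out of scope: peaks arrive as
BED, expression as a pre-normalized log2 matrix, and ortholog sets as
multi-FASTA files. All interval arithmetic is 0-based half-open
(BED-style); GFF's 1-based closed convention is deliberately unsupported
so a single convention holds everywhere.

## Motif model and scanning

A motif is an IUPAC consensus, an L×4 position probability matrix, or
both, with a 4-vector background (uniform by default) and a bit-score
threshold. Consensus motifs are concretized by giving the allowed bases of
each position `1 − soft` of the probability mass equally and the
disallowed bases `soft` equally (default `soft = 0.04`). The default
threshold is the minimum log-odds score over the words the consensus
matches; by construction, PWM scanning at that threshold is then exactly
equivalent to IUPAC string matching (verified by brute force over all 4^8
words for `ACHGTTAK`), while lowering the threshold relaxes matching
smoothly. `N` in a sequence scores −∞ and never matches; scanning reports
both strands, minus-strand hits at the forward offset of their window. A
plus/minus double hit at one offset (palindromic case) is deduplicated to
the better-scoring strand before clustering or presence counting.

## Conservation

Conservation is alignment-free: each orthologous sequence is scanned
independently at the same threshold, and a species supports a reference
hit when it has a hit whose offset, rescaled by the sequence-length ratio,
lies within ±δ (default δ = 20 bp — generous against the generator's ±5 bp
placement jitter while far smaller than the distance between planted
sites). A hit is conserved when supported by at least `c` species
(reference included), default `c = ceil(0.6 × n_species)`, i.e. 6 of 10.
The species-support requirement is a free parameter because there is no
canonical value; relaxing the conservation penalty maps to lowering `c`
(exposed as `--min-species`), and sensitivity is monotone non-decreasing
under that relaxation (a tested invariant). Alignment-column conservation
is intentionally not implemented — regions are scanned "taken
independently" — so orthology quality only enters through the offset
window.

## Discriminative discovery

The discovery chain is deterministic given inputs and parameters:

1. **Seeds.** All w-mers (default w = 10; the benchmark uses w = 8, the
   length of the planted consensus) occurring in the positive regions,
   collapsed with reverse complements to a canonical key; seeds present in
   fewer than 3 positive regions are skipped.
2. **Generalization.** Each seed is greedily generalized into an IUPAC
   consensus: every single-base code expansion is scored by conserved
   per-region presence (fraction of positives minus fraction of negatives
   with ≥ 1 conserved match, computed by fast string matching that is
   exactly equivalent to default-threshold PWM scanning), and the best
   strictly-improving candidate is taken until none improves. This is the
   move discriminative word-based discoverers (e.g. DREME) make; it is
   what lets instances that sample different words of a degenerate
   consensus in different regions merge into one motif, which no
   fixed-point refinement of an exact word can do. Ties are broken on the
   strand-canonical form so mirrored inputs walk mirrored paths.
3. **Refinement.** Conserved instances of the consensus are collected;
   the PWM is built from the instance columns — the reference word plus
   the supporting species' words, which is where phylogenetic softening
   of the columns comes from — with a 0.5 pseudocount; the threshold is
   the minimum score of the current instances under the new PWM; rescan
   and rebuild until the reference instance set is stable (cap 20
   iterations). Motifs whose instance set collapses (< 2) or explodes
   (> 200, a threshold collapse) are discarded as non-discriminative.
4. **Statistics.** Conserved-hit counts in positives are tested against a
   binomial upper tail with the per-position conserved-hit rate estimated
   from a background pool: the negative regions plus the positive
   ortholog sets with every species independently dinucleotide-shuffled
   (Altschul–Erikson), which preserves composition but destroys both
   motifs and cross-species correspondence. Motifs with p > 1e-3 are
   dropped. When the pool yields no conserved hit at all the p-value is a
   0-sentinel with a warning.
5. **Ranking.** Sensitivity and false-positive rate are per-region
   presence fractions; Pareto layer 1 is the non-dominated front, peeled
   iteratively; within a layer motifs sort by over-representation
   p-value, then name.

## Gene ranking and recovery curves

Genes are scored by the count of conserved hits across their regulatory
regions (ties: best hit bit score, then gene id). The recovery curve is
the cumulative fraction of a signature set along the ranking; AUC is its
trapezoid integral over normalized rank. The randomized reference is
`n_random = 1000` uniform same-size gene sets drawn without replacement,
summarized per rank as mean ± σ·sd (σ = 2); repeated draws rather than a
single randomized set, because a sigma interval requires replication. The
x-axis is rank fraction of the universe.

## Peak integration

Cross-correlation collects signed distances (motif − peak center) for
every hit/peak pair on one chromosome with |distance| < 10 kb, binned at
500 bp (40 bins), and tests the histogram against a uniform expectation
with a chi-square goodness-of-fit test (dof = 39). Counting is pair-based
— a motif near two peaks counts once per peak — because the window is
defined around each peak. Peak centers are summits when available, else
interval midpoints. Nearest-TSS assignment minimizes the unsigned
distance |TSS − center| on the same chromosome; exact ties go to the
lexicographically smallest gene id; peaks on chromosomes without a TSS
are reported unassigned. Peak provenance strings (caller, thresholds,
reproducibility filters) are carried verbatim as metadata, never
interpreted.

## Expression filter

Per-gene differential statistics are Welch two-sample tests on log2
intensities with Benjamini–Hochberg adjustment (any exchangeable
two-sample test could stand behind the same contract). Genes with zero
variance in both groups fall back to a flagged equal-means rule (p = 0
if means differ, else 1). The regulated set keeps genes with
`log2FC(svb) < 0` (sign only; a significance gate on this arm is
optional) and `log2FC(pri) ≤ log2FC(svb) − log2(fold)` (default fold 2 —
the "further more-than-two-fold reduction" is measured between the mutant
genotypes; a flag switches to plain pri-vs-wt) at `FDR(pri) ≤ 0.01`,
ranked by pri fold change, truncated to the top 150. Controls are genes
with `min(p) > 0.8` and `min(FDR) > 0.99` across both contrasts, sampled
to 100 with a seed. Under BH adjustment that joint control gate is very
conservative — adjusted values dip below 0.99 across most of the
distribution's tail — so the eligible pool is small on realistic
matrices; the selection returns all eligible genes when fewer than 100
exist.

## Enhancer prediction

Candidates are peak regions assigned to regulated genes that contain at
least one conserved anchor (svbF7) hit — a hard gate encoding that the
factor's site is necessary for these enhancers (though not sufficient:
adding sites to an inactive region does not make an enhancer, which is
why precision relies on the expression and conservation gates, not the
anchor alone). Blue and yellow motifs are annotated, the composition
class is one of svb_only / svb_blue / svb_yellow / all_three / none, and
the score is the best anchor bit score plus 0.5 per additional distinct
motif class present (weights configurable; the ranking is plumbing — the
underlying study ranks nothing numerically here). The candidate interval
is the peak interval; optional padding is exposed because real tested
fragments are hand-delimited. Architecture reports re-scan every species
independently at the shared thresholds and draw hits filled when
traceable across species (within the shift window of a conserved
reference hit) and open when reference-only.

## Synthetic benchmark

The generator emulates the study's data layout with one seed driving all
randomness (identical config + seed ⇒ byte-identical bundle):

- **Sequences.** IID background at GC 0.42; ten Drosophilid-like species
  under a star phylogeny with per-base substitution probability 0.25 to a
  uniformly random different base; inside planted motifs the rate is
  multiplied by a conservation factor of 0.1; indels are not modeled, but
  planted words shift by a uniform ±5 bp per species so the offset-window
  logic is genuinely exercised.
- **Training fragments.** 14 positives (svbF7 planted in 90%, copy
  number single-biased 1–3, strand uniform; blue and yellow each present
  in half) and 25 negatives carrying core-only decoys: 8-mers with the
  in-vitro `CnGTTa` core whose flanks are resampled until the refined
  consensus does not match, the generator's rendering of the finding that
  flanking-nucleotide mutations inactivate enhancers without disrupting
  the core. Negative reference sequences are redrawn until no full svbF7
  match exists on either strand.
- **Gene universe.** 1,000 genes on one synthetic chromosome in 6 kb
  slots, each with a TSS and one 1.5 kb regulatory region; 150 target
  genes' regions are true enhancers (always ≥ 1 svbF7). ChIP-like peaks
  (600 bp) are centered on a planted site with Gaussian jitter (sd
  150 bp); 100 background peaks sit near non-target genes.
- **Expression.** Five replicates per genotype; log2 baselines
  N(8, 1), replicate noise sd 0.2. Target effects are drawn from
  N(−0.8, 0.3) for the svb contrast and N(−1.5, 0.4) for the extra pri
  drop, rejection-sampled to the defining property of the set (svb effect
  < 0, extra drop ≤ −1): a "target" whose true effect violates the very
  rule that defines targets would be a labeling error, not noise. The
  exact-recovery test of the filter uses a strong-effect configuration
  (svb −1.5, extra −2.5) so recovery is limited by the rule, not by
  boundary draws against replicate noise; at the default effect sizes the
  filter recovers ~95% of planted targets with no false selections,
  which is itself a reported benchmark quantity.
- **Manifest.** Every planted instance (word, offsets and mutation flags
  per species), region label, per-gene target status and true effect
  sizes, and peak→enhancer links.

What the generator does not emulate: indels and alignment ambiguity, a
real phylogeny (only per-species presence is ever used downstream),
chromatin context, probe-level microarray artifacts, and correlated
effects between neighboring genes. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
generative model, not performance on real genomes.

## Numerical and design choices

- Uniform motif background even though sequences are 42% GC: conservative
  for AT-rich motifs, and it keeps consensus/PWM equivalence exact.
- Over-representation is a binomial upper tail computed via the survival
  function; `bg_rate = 0` with hits yields a 0-sentinel plus warning.
- Chi-square is applied only where expected counts are healthy (the
  calibration test uses 300 pairs over 40 bins); an empty histogram
  returns NaN with a warning rather than a fabricated p-value.
- Ties are broken lexicographically everywhere (gene ids, motif names,
  strand-canonical consensi) for byte-identical reruns.
- Benchmark problem sizes (10 discovery replicates of 14 + 25 fragments,
  a 1,000-gene universe, 200 calibration replicates) are chosen so the
  entire suite and the acceptance script each run in minutes on one CPU.

## Known limitations

- The seed-generalization search is greedy and single-base; motifs whose
  degeneracy cannot be reached by strictly improving steps may stay
  split across seeds (the Pareto ranking still surfaces the best
  variant).
- Conservation support treats species independently (star phylogeny
  assumption); shared-branch correlations in a real clade would make the
  support count optimistic.
- The two-mutant filter assumes the cofactor mutant strictly deepens
  target down-regulation; genes regulated in the opposite direction are
  out of scope.
- The negative-control gate inherits BH's conservativeness (see above);
  on matrices like the benchmark's the eligible pool can be much smaller
  than 100.
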