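"""Motif–peak cross-correlation and peak-to-gene assignment.

The cross-correlation analysis asks whether conserved motif instances pile
up around ChIP peak centers: signed motif-to-center distances within a
window around every peak are binned and the histogram tested against a
uniform expectation with a chi-square goodness-of-fit test. Peaks are
linked to genes by nearest transcription start site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenomicInterval, TSSTable

log = logging.getLogger("crmkit")


@dataclass
class PeakSet:
    """ChIP peaks with optional summit offsets (relative to start) and scores.

    ``provenance`` carries free-text metadata about how the peaks were
    produced (caller, thresholds, reproducibility filtering); it is recorded
    verbatim in outputs and never interpreted.
    """

    peaks: list[GenomicInterval]
    summits: dict[int, int] = field(default_factory=dict)  # peak index -> offset
    scores: dict[int, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for i, off in self.summits.items():
            pk = self.peaks[i]
            if not 0 <= off < pk.width:
                raise ValueError(f"peak {i}: summit offset {off} outside interval")

    def center(self, i: int) -> int:
        return peak_center(self.peaks[i], self.summits.get(i))


def peak_center(peak: GenomicInterval, summit_offset: int | None = None) -> int:
    """Summit position if known, else the midpoint (floor)."""
    if summit_offset is not None:
        return peak.start + summit_offset
    return (peak.start + peak.end) // 2


@dataclass
class CrossCorrParams:
    half_window: int = 10_000
    bin: int = 500

    def __post_init__(self) -> None:
        if self.half_window % self.bin:
            raise ValueError("half_window must be divisible by bin")

    @property
    def n_bins(self) -> int:
        return 2 * self.half_window // self.bin


@dataclass
class CrossCorrResult:
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    dof: int
    p: float
    total_hits: int


def cross_correlate(
    hit_positions: dict[str, np.ndarray] | list[tuple[str, int]],
    peak_set: PeakSet,
    params: CrossCorrParams | None = None,
) -> CrossCorrResult:
    """Histogram of signed motif-to-peak-center distances vs uniform.

    ``hit_positions`` gives genomic motif positions per chromosome. Every
    (hit, peak) pair on the same chromosome with |distance| < half_window
    contributes once — a motif near two peaks is counted once per peak, as
    the window is centered on each peak. Distances are signed
    (motif − center) so left/right asymmetries stay visible.
    """
    params = params or CrossCorrParams()
    if isinstance(hit_positions, list):
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in hit_positions:
            by_chrom.setdefault(chrom, []).append(pos)
        hit_positions = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}
    else:
        hit_positions = {c: np.sort(np.asarray(p)) for c, p in hit_positions.items()}
    hw, b = params.half_window, params.bin
    edges = np.arange(-hw, hw + b, b)
    observed = np.zeros(params.n_bins, dtype=int)
    for i, pk in enumerate(peak_set.peaks):
        pos = hit_positions.get(pk.chrom)
        if pos is None or pos.size == 0:
            continue
        c = peak_set.center(i)
        lo = np.searchsorted(pos, c - hw, side="right")   # distance > -hw
        hi = np.searchsorted(pos, c + hw, side="left")    # distance <  hw
        d = pos[lo:hi] - c
        observed += np.histogram(d, bins=edges)[0]
    total = int(observed.sum())
    expected = np.full(params.n_bins, total / params.n_bins)
    if total == 0:
        log.warning("cross-correlation: no hit/peak pairs within the window")
        return CrossCorrResult(edges, observed, expected, float("nan"),
                               params.n_bins - 1, float("nan"), 0)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = params.n_bins - 1
    p = float(stats.chi2.sf(chi2, dof))
    return CrossCorrResult(edges, observed, expected, chi2, dof, p, total)


def nearest_tss(peak_set: PeakSet, tss_table: TSSTable) -> tuple[dict[int, str], list[int]]:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Distance is |TSS − peak center| (unsigned); exact ties go to the
    lexicographically smallest gene id. Returns (peak index -> gene id,
    indices of unassignable peaks on chromosomes with no TSS).
    """
    if not tss_table.records:
        raise ValueError("empty TSS table")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, iv in tss_table.records:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, gene))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    assignment: dict[int, str] = {}
    unassigned: list[int] = []
    for i, pk in enumerate(peak_set.peaks):
        entries = by_chrom.get(pk.chrom)
        if not entries:
            unassigned.append(i)
            continue
        c = peak_set.center(i)
        positions = [p for p, _ in entries]
        j = np.searchsorted(positions, c)
        candidates = entries[max(0, j - 1) : j + 1]
        best_d = min(abs(p - c) for p, _ in candidates)
        winners = sorted(g for p, g in entries if abs(p - c) == best_d)
        assignment[i] = winners[0]
    return assignment, unassigned


def peaks_for_geneset(
    peak_gene_map: dict[int, str], gene_set: set[str]
) -> tuple[list[int], set[str]]:
    """Peaks assigned to genes of interest, and the genes covered by >= 1 peak."""
    peaks = sorted(i for i, g in peak_gene_map.items() if g in gene_set)
    genes = {peak_gene_map[i] for i in peaks}
    return peaks, genes
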