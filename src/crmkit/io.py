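"""Readers and writers for the formats the pipeline touches.

All interval arithmetic in this package uses 0-based half-open (BED-style)
coordinates; GFF-style 1-based closed intervals are deliberately not
supported so a single convention holds everywhere.
"""

from __future__ import annotations

import io as _io
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")

log = logging.getLogger("crmkit")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr; results go to files only."""
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level)


class ParseError(ValueError):
    """Malformed input file; message names the file and offending location."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class OrthoRegion:
    """One reference region together with its orthologous sequences.

    ``sequences`` maps species name to an uppercase nucleotide string over
    {A,C,G,T,N}; the reference species is always one of the keys.
    """

    region_id: str
    reference_species: str
    sequences: dict[str, str]
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.reference_species not in self.sequences:
            raise ValueError(
                f"region {self.region_id}: reference species "
                f"{self.reference_species!r} not among sequences"
            )
        for sp, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"region {self.region_id}: empty sequence for {sp}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"region {self.region_id}/{sp}: invalid characters {sorted(bad)}"
                )

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.reference_species]

    @property
    def species(self) -> list[str]:
        return list(self.sequences)


@dataclass
class TSSTable:
    """One transcription start site per gene (width-1 intervals)."""

    records: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in TSS table")
        for g, iv in self.records:
            if iv.width != 1:
                raise ValueError(f"TSS for {g} is not a single position")

    def as_dict(self) -> dict[str, GenomicInterval]:
        return dict(self.records)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence map.

    Characters outside {A,C,G,T,N} (after uppercasing) are rejected with the
    line number where they occur.
    """
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            lineno = _find_bad_line(text, bad)
            raise ParseError(
                f"{path}: line {lineno}: invalid sequence characters {sorted(bad)}"
            )
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    return records


def _find_bad_line(text: str, bad: set[str]) -> int:
    badset = {c for b in bad for c in (b.upper(), b.lower())}
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            continue
        if set(line) & badset:
            return i
    return 0


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (4th column -> id, 6th -> strand)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: row {i}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise ParseError(f"{path}: row {i}: non-integer coordinate") from e
            name = cols[3] if len(cols) >= 4 and cols[3] != "." else None
            strand = cols[5] if len(cols) >= 6 else "."
            try:
                out.append(GenomicInterval(cols[0], start, end, strand, name))
            except ValueError as e:
                raise ParseError(f"{path}: row {i}: {e}") from e
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval],
              scores: Iterable[float] | None = None) -> None:
    """Write BED6; score column is the supplied value (0 if absent)."""
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Ortholog directories

def read_ortho_dir(path: str | Path) -> list[OrthoRegion]:
    """Read a directory of per-region multi-FASTA files.

    Record ids are species names; ``manifest.json`` in the directory names the
    reference species (key ``reference_species``). The region id is the file
    stem.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ParseError(f"{path}: missing manifest.json naming the reference species")
    manifest = json.loads(manifest_path.read_text())
    ref = manifest["reference_species"]
    regions: list[OrthoRegion] = []
    for fa in sorted(path.glob("*.fa")) + sorted(path.glob("*.fasta")):
        seqs = read_fasta(fa)
        if ref not in seqs:
            raise ParseError(f"{fa}: missing reference species record {ref!r}")
        regions.append(OrthoRegion(region_id=fa.stem, reference_species=ref, sequences=seqs))
    return regions


def write_ortho_dir(path: str | Path, regions: Iterable[OrthoRegion],
                    reference_species: str, species: list[str] | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"reference_species": reference_species}
    if species is not None:
        manifest["species"] = species
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for reg in regions:
        write_fasta(path / f"{reg.region_id}.fa", reg.sequences)


# ---------------------------------------------------------------------------
# TSS tables (TSV: gene_id, chrom, pos, strand)

def read_tss(path: str | Path) -> TSSTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "pos", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TSS table must have columns {sorted(required)}")
    records = [
        (row.gene_id, GenomicInterval(row.chrom, int(row.pos), int(row.pos) + 1, row.strand))
        for row in df.itertuples()
    ]
    return TSSTable(records)


def write_tss(path: str | Path, table: TSSTable) -> None:
    rows = [
        {"gene_id": g, "chrom": iv.chrom, "pos": iv.start, "strand": iv.strand}
        for g, iv in table.records
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Motif files (minimal MEME-like text dialect)
#
#   MOTIF <name>
#   CONSENSUS <iupac>        (optional)
#   BACKGROUND a c g t       (optional, defaults uniform)
#   THRESHOLD <bits>         (optional)
#   MATRIX <L>               (optional; followed by L rows of 4 probabilities)

def read_motifs(path: str | Path):
    """Parse motif definitions; see :mod:`crmkit.motifs` for the type."""
    from .motifs import MotifDefinition  # local import to avoid a cycle

    path = Path(path)
    motifs = []
    cur: dict | None = None
    rows_left = 0
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if rows_left > 0:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ParseError(f"{path}: line {i}: expected 4 probabilities")
                if any(v < 0 or v > 1 for v in vals):
                    raise ParseError(f"{path}: line {i}: probability outside [0,1]")
                if sum(vals) == 0:
                    raise ParseError(f"{path}: line {i}: zero-sum matrix row")
                cur["pwm"].append(vals)
                rows_left -= 1
                continue
            key, _, rest = line.partition(" ")
            key = key.upper()
            if key == "MOTIF":
                if cur is not None:
                    motifs.append(_finish_motif(cur, path))
                cur = {"name": rest.strip(), "pwm": []}
            elif cur is None:
                raise ParseError(f"{path}: line {i}: {key} before any MOTIF")
            elif key == "CONSENSUS":
                cur["consensus"] = rest.strip()
            elif key == "BACKGROUND":
                cur["background"] = [float(x) for x in rest.split()]
            elif key == "THRESHOLD":
                cur["score_threshold"] = float(rest)
            elif key == "MATRIX":
                rows_left = int(rest)
            elif key == "ALPHABET":
                if rest.strip().upper() != "ACGT":
                    raise ParseError(f"{path}: line {i}: only the ACGT alphabet is supported")
            else:
                raise ParseError(f"{path}: line {i}: unknown directive {key!r}")
    if rows_left > 0:
        raise ParseError(f"{path}: truncated matrix block")
    if cur is not None:
        motifs.append(_finish_motif(cur, path))
    return motifs


def _finish_motif(cur: dict, path: Path):
    from .motifs import MotifDefinition

    pwm = cur.pop("pwm")
    kwargs = dict(cur)
    if pwm:
        import numpy as np

        mat = np.asarray(pwm, dtype=float)
        mat = mat / mat.sum(axis=1, keepdims=True)  # renormalize rows
        kwargs["pwm"] = mat
    try:
        return MotifDefinition(**kwargs)
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: motif {cur.get('name')!r}: {e}") from e


def write_motifs(path: str | Path, motifs) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            if m.consensus:
                fh.write(f"CONSENSUS {m.consensus}\n")
            fh.write("BACKGROUND " + " ".join(f"{b:.6f}" for b in m.background) + "\n")
            if m.score_threshold is not None:
                fh.write(f"THRESHOLD {m.score_threshold:.6f}\n")
            if m.pwm is not None:
                fh.write(f"MATRIX {len(m.pwm)}\n")
                for row in m.pwm:
                    fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression matrices (TSV genes x samples, with a condition-map sidecar)

def read_expression(matrix_path: str | Path, conditions_path: str | Path):
    """Read a log2 expression matrix and its sample -> condition map."""
    from .expression import ExpressionMatrix

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", dtype=str)
    if not {"sample", "condition"}.issubset(cond.columns):
        raise ParseError(f"{conditions_path}: need columns sample, condition")
    cmap = dict(zip(cond["sample"], cond["condition"]))
    return ExpressionMatrix(values=mat, conditions=cmap)


def write_expression(matrix_path: str | Path, conditions_path: str | Path, em) -> None:
    em.values.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": list(em.conditions), "condition": list(em.conditions.values())}
    ).to_csv(conditions_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flat key=value configuration files

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text file; CLI flags override these."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {i}: expected key = value")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
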