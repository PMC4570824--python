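"""Readers/writers for the formats the pipeline touches, read collapsing,
and the configuration/logging backbone.

Conventions
-----------
* Internal coordinates are 0-based half-open; every emitted report uses
  1-based inclusive coordinates.
* Sequences are stored uppercase. DNA on disk; folding/duplex code converts
  to RNA (``T`` -> ``U``) at the boundary.
* A :class:`Library` is a collapsed read set: unique sequence -> read count.
  Reads containing ``N`` are retained through parsing and handled by the
  downstream quality filter, so the accounting sees every read.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

from Bio import SeqIO

logger = logging.getLogger("mirdeg")

#: Fixed vocabulary for annotation feature classes.
FEATURE_CLASSES = frozenset({
    "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron",
    "known_miRNA_precursor",
})

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def setup_logging(level: str = "INFO") -> None:
    """Configure pipeline logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


class ParseError(ValueError):
    """A record violated its file format; message names the offending line."""


def _open_text(path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRead:
    """One sequencing read; ``quality`` is per-base Phred scores (absent for FASTA)."""

    identifier: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.identifier!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}")

    @property
    def mean_quality(self) -> Optional[float]:
        if self.quality is None:
            return None
        return sum(self.quality) / len(self.quality)


@dataclass
class Library:
    """A collapsed set of (sequence, count) pairs for one sequencing library.

    ``quality_means`` optionally keeps the per-copy mean Phred score for each
    unique sequence (one entry per read copy) so the quality filter can act
    after collapsing.
    """

    name: str = ""
    records: dict[str, int] = field(default_factory=dict)
    quality_means: Optional[dict[str, list[float]]] = None

    @property
    def total_reads(self) -> int:
        return sum(self.records.values())

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def add(self, sequence: str, count: int = 1, mean_quality: Optional[float] = None) -> None:
        sequence = sequence.upper()
        self.records[sequence] = self.records.get(sequence, 0) + count
        if mean_quality is not None:
            if self.quality_means is None:
                self.quality_means = {}
            self.quality_means.setdefault(sequence, []).extend([mean_quality] * count)

    def sequences(self) -> Iterable[str]:
        return self.records.keys()


@dataclass(frozen=True)
class Feature:
    """Genomic annotation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    cls: str
    label: str = "."


@dataclass
class AnnotationDB:
    """Reference genome plus structural-RNA / repeat / gene-structure features.

    Stands in for live Rfam/GenBank/miRBase lookups with user-supplied
    local files, keeping runs reproducible and offline.
    """

    genome: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Feature]] = {}
        for i, feat in enumerate(self.features):
            if feat.cls not in FEATURE_CLASSES:
                raise ValueError(f"feature line {i + 1}: unknown class {feat.cls!r}")
            if feat.chrom not in self.genome:
                raise ValueError(f"feature line {i + 1}: unknown sequence {feat.chrom!r}")
            if not (0 <= feat.start < feat.end <= len(self.genome[feat.chrom])):
                raise ValueError(
                    f"feature line {i + 1}: interval [{feat.start}, {feat.end}) out of "
                    f"bounds for {feat.chrom} (length {len(self.genome[feat.chrom])})")
            self._by_chrom.setdefault(feat.chrom, []).append(feat)
        for feats in self._by_chrom.values():
            feats.sort(key=lambda f: (f.start, f.end))

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: Optional[str] = None) -> list[Feature]:
        """All features overlapping [start, end) on ``chrom``.

        ``strand=None`` ignores strand; otherwise features on the given
        strand or with strand '.' match.
        """
        out = []
        for feat in self._by_chrom.get(chrom, []):
            if feat.start >= end:
                break
            if feat.end > start:
                if strand is None or feat.strand == "." or feat.strand == strand:
                    out.append(feat)
        return out


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def iter_fastq(path) -> Iterator[RawRead]:
    """Yield reads from a 4-line-record FASTQ file (Phred+33).

    Malformed records (bad separators, length mismatches, truncated tails)
    raise :class:`ParseError` naming the line number rather than being
    silently skipped.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}")
            if not seq:
                raise ParseError(f"{path}: line {lineno - 2}: empty sequence")
            yield RawRead(header[1:].split()[0], seq.upper(),
                          [ord(c) - 33 for c in qual])


def read_fastq(path, name: str = "") -> Library:
    """Read a FASTQ file into a collapsed :class:`Library` with exact counts.

    Collapsing is order-independent; per-copy mean qualities are retained for
    the downstream quality filter.
    """
    lib = Library(name=name or str(path), quality_means={})
    for read in iter_fastq(path):
        lib.add(read.sequence, 1, read.mean_quality)
    return lib


def write_fastq(lib: Library, path, default_quality: int = 40) -> None:
    """Expand a collapsed library back to a 4-line FASTQ file.

    Copies of a sequence reuse its recorded mean qualities where available
    (as a flat per-base score); otherwise ``default_quality`` is used.
    """
    with _open_text(path, "wt") as fh:
        i = 0
        for seq in sorted(lib.records):
            quals = (lib.quality_means or {}).get(seq, [])
            for copy in range(lib.records[seq]):
                q = quals[copy] if copy < len(quals) else default_quality
                qchar = chr(int(round(q)) + 33)
                fh.write(f"@read{i}\n{seq}\n+\n{qchar * len(seq)}\n")
                i += 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {header-first-token: uppercase sequence}.

    Duplicate headers and empty sequences are format violations.
    """
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ParseError(f"{path}: duplicate header {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r}: empty sequence")
            seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fasta_library(path, name: str = "") -> Library:
    """Read a FASTA of (possibly duplicated) reads into a Library (no qualities)."""
    lib = Library(name=name or str(path))
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r}: empty sequence")
            # collapsed-FASTA convention: trailing "_xN" or "xN" token = count
            count = 1
            if "_x" in rec.id:
                tail = rec.id.rsplit("_x", 1)[1]
                if tail.isdigit():
                    count = int(tail)
            lib.add(seq, count)
    return lib


def write_library_fasta(lib: Library, path) -> None:
    """Write a collapsed library as FASTA with counts in headers (seq0_x12)."""
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(sorted(lib.records)):
            fh.write(f">seq{i}_x{lib.records[seq]}\n{seq}\n")


# ---------------------------------------------------------------------------
# Annotation features (6-column TSV, BED-like 0-based half-open)
# ---------------------------------------------------------------------------

def load_annotation(genome_path, features_path) -> AnnotationDB:
    """Load a genome FASTA plus a 6-column feature TSV into an AnnotationDB.

    Columns: name, start, end, strand, class, label — BED-like, 0-based
    half-open. Out-of-bounds intervals raise an error naming the line.
    """
    genome = read_fasta(genome_path)
    features = read_features(features_path, genome)
    return AnnotationDB(genome=genome, features=features)


def read_features(path, genome: Optional[dict[str, str]] = None) -> list[Feature]:
    features = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >= 5 columns")
            chrom, start, end, strand, cls = parts[:5]
            label = parts[5] if len(parts) > 5 else "."
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if cls not in FEATURE_CLASSES:
                raise ParseError(f"{path}: line {lineno}: unknown class {cls!r}")
            if genome is not None:
                if chrom not in genome:
                    raise ParseError(f"{path}: line {lineno}: unknown sequence {chrom!r}")
                if not (0 <= s < e <= len(genome[chrom])):
                    raise ParseError(
                        f"{path}: line {lineno}: interval [{s}, {e}) out of bounds "
                        f"for {chrom}")
            features.append(Feature(chrom, s, e, strand, cls, label))
    return features


def write_features(features: Iterable[Feature], path) -> None:
    with _open_text(path, "wt") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.cls}\t{f.label}\n")
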