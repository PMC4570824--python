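"""Exact genome mapping and annotation-category partitioning of clean reads,
plus length-distribution and first-nucleotide-bias statistics.

Mapping is exact (no mismatches) on both strands. Minus-strand hits store
the genomic locus at which the *reverse complement* of the read occurs on
the plus strand. Annotation classes are collapsed into eight mutually
exclusive read categories with the conventional small-RNA precedence
miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon_intron > unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .io_core import AnnotationDB, Library, revcomp

#: Read-category precedence (highest first); unannotated is the fallback.
CATEGORY_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon_intron")
ALL_CATEGORIES = CATEGORY_PRECEDENCE + ("unannotated",)

#: Feature class -> read category.
_CLASS_TO_CATEGORY = {
    "known_miRNA_precursor": "miRNA",
    "rRNA": "rRNA", "tRNA": "tRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
    "repeat": "repeat", "exon": "exon_intron", "intron": "exon_intron",
}

STRUCTURAL_CATEGORIES = ("rRNA", "repeat", "snRNA", "snoRNA", "tRNA")


class Hit(NamedTuple):
    chrom: str
    start: int  # 0-based genomic start of the occupied locus
    strand: str


class GenomeIndex:
    """Seed-and-verify exact matcher over a set of named sequences.

    A k-mer (default 18, the minimum insert length) dictionary of the plus
    strand finds candidate loci in O(1); candidates are verified by direct
    string comparison, so reported hits are exact occurrences. Queries
    shorter than the seed fall back to a full scan.
    """

    def __init__(self, genome: dict[str, str], seed_len: int = 18):
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(0, len(seq) - seed_len + 1):
                self._index.setdefault(seq[i:i + seed_len], []).append((name, i))

    def _scan(self, query: str) -> list[tuple[str, int]]:
        out = []
        for name, seq in self.genome.items():
            i = seq.find(query)
            while i != -1:
                out.append((name, i))
                i = seq.find(query, i + 1)
        return out

    def find_plus(self, query: str) -> list[tuple[str, int]]:
        """All exact plus-strand occurrences of ``query``."""
        n = len(query)
        if n < self.seed_len:
            return self._scan(query)
        hits = []
        for name, i in self._index.get(query[:self.seed_len], ()):
            if self.genome[name][i:i + n] == query:
                hits.append((name, i))
        return hits

    def find(self, query: str) -> list[Hit]:
        """Exact occurrences on both strands (minus = revcomp occurs on plus)."""
        query = query.upper()
        hits = [Hit(c, s, "+") for c, s in self.find_plus(query)]
        hits += [Hit(c, s, "-") for c, s in self.find_plus(revcomp(query))]
        hits.sort()
        return hits


def map_exact(clean: Library, genome: dict[str, str],
              index: Optional[GenomeIndex] = None, seed_len: int = 18) -> dict[str, list[Hit]]:
    """Exact hit lists (position, strand) for every unique clean sequence.

    Unmapped sequences get empty hit lists.
    """
    if index is None:
        index = GenomeIndex(genome, seed_len=seed_len)
    return {seq: index.find(seq) for seq in clean.sequences()}


@dataclass
class MappingSummary:
    """Matched/total bookkeeping in both the unique-tag and total-read views."""

    unique_total: int
    unique_matched: int
    total_reads: int
    total_matched: int

    def __post_init__(self) -> None:
        if self.unique_matched > self.unique_total or self.total_matched > self.total_reads:
            raise ValueError("matched exceeds total")

    @property
    def unique_pct(self) -> float:
        return round(self.unique_matched / self.unique_total * 100, 2)

    @property
    def total_pct(self) -> float:
        return round(self.total_matched / self.total_reads * 100, 2)


def mapping_summary(hits: dict[str, list[Hit]], clean: Library) -> MappingSummary:
    if clean.total_reads == 0:
        raise ValueError("cannot summarize an empty library")
    um = tm = 0
    for seq, count in clean.records.items():
        if hits.get(seq):
            um += 1
            tm += count
    return MappingSummary(unique_total=clean.n_unique, unique_matched=um,
                          total_reads=clean.total_reads, total_matched=tm)


@dataclass
class CategoryTable:
    """(unique, total) read counts per annotation category.

    Categories are disjoint and sum to the library totals.
    """

    counts: dict[str, tuple[int, int]]
    unique_total: int
    total_total: int

    def validate(self) -> None:
        su = sum(u for u, _ in self.counts.values())
        st = sum(t for _, t in self.counts.values())
        if su != self.unique_total or st != self.total_total:
            raise ValueError("category counts do not partition the library")

    def unique_pct(self, category: str) -> float:
        return round(self.counts[category][0] / self.unique_total * 100, 2)

    def total_pct(self, category: str) -> float:
        return round(self.counts[category][1] / self.total_total * 100, 2)

    def structural_unique_pct(self) -> float:
        s = sum(self.counts.get(c, (0, 0))[0] for c in STRUCTURAL_CATEGORIES)
        return round(s / self.unique_total * 100, 2)

    def structural_total_pct(self) -> float:
        s = sum(self.counts.get(c, (0, 0))[1] for c in STRUCTURAL_CATEGORIES)
        return round(s / self.total_total * 100, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ALL_CATEGORIES:
            u, t = self.counts.get(cat, (0, 0))
            rows.append((cat, u, self.unique_pct(cat) if cat in self.counts else 0.0,
                         t, self.total_pct(cat) if cat in self.counts else 0.0))
        return pd.DataFrame(rows, columns=["category", "unique", "unique_pct",
                                           "total", "total_pct"])


def classify_per_read(hits: dict[str, list[Hit]], db: AnnotationDB,
                      read_lengths: Optional[dict[str, int]] = None) -> dict[str, str]:
    """Single category per unique sequence: best precedence over all its loci.

    Feature overlap is strand-agnostic (structural-RNA filtering convention).
    Unmapped or feature-free sequences are ``unannotated``.
    """
    out = {}
    for seq, seq_hits in hits.items():
        n = len(seq) if read_lengths is None else read_lengths[seq]
        best = None
        for hit in seq_hits:
            for feat in db.overlapping(hit.chrom, hit.start, hit.start + n):
                cat = _CLASS_TO_CATEGORY[feat.cls]
                idx = CATEGORY_PRECEDENCE.index(cat)
                if best is None or idx < best:
                    best = idx
        out[seq] = CATEGORY_PRECEDENCE[best] if best is not None else "unannotated"
    return out


def classify_reads(hits: dict[str, list[Hit]], db: AnnotationDB,
                   clean: Library) -> CategoryTable:
    """Partition a clean library into the eight annotation categories."""
    per_read = classify_per_read(hits, db)
    counts = {cat: [0, 0] for cat in ALL_CATEGORIES}
    for seq, count in clean.records.items():
        cat = per_read.get(seq, "unannotated")
        counts[cat][0] += 1
        counts[cat][1] += count
    table = CategoryTable(
        counts={c: (u, t) for c, (u, t) in counts.items()},
        unique_total=clean.n_unique, total_total=clean.total_reads)
    table.validate()
    return table


def length_histogram(lib: Library) -> pd.Series:
    """Read counts per insert length; the histogram total equals the library total."""
    counts: dict[int, int] = {}
    for seq, count in lib.records.items():
        counts[len(seq)] = counts.get(len(seq), 0) + count
    return pd.Series(counts, dtype=int).sort_index()


def first_nt_table(lib: Library, lengths: Iterable[int] = range(18, 27)) -> pd.DataFrame:
    """First-nucleotide counts and percentages per insert length (18-26 nt).

    DNA ``T`` is reported as ``U``. Each row's percentages sum to 100 (up to
    rounding); rows are emitted only for lengths with at least one read.
    """
    lengths = set(lengths)
    counts: dict[int, dict[str, int]] = {}
    for seq, count in lib.records.items():
        n = len(seq)
        if n not in lengths:
            continue
        first = "U" if seq[0] == "T" else seq[0]
        row = counts.setdefault(n, {"A": 0, "U": 0, "C": 0, "G": 0})
        if first in row:
            row[first] += count
    records = []
    for n in sorted(counts):
        row = counts[n]
        total = sum(row.values())
        rec = {"length": n}
        for base in "AUCG":
            rec[base] = row[base]
            rec[f"{base}_pct"] = round(row[base] / total * 100, 2) if total else 0.0
        records.append(rec)
    return pd.DataFrame(records).set_index("length") if records else pd.DataFrame(
        columns=["A", "A_pct", "U", "U_pct", "C", "C_pct", "G", "G_pct"])
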