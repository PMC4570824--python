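"""Raw-read cleaning with six-category removal accounting.

Every high-quality read receives exactly one category, in a fixed
precedence order (mirroring the mutually exclusive accounting of a
standard small-RNA data-set summary table):

1. ``adapter3_null``      — no detectable 3' adapter;
2. ``insert_null``        — adapter dimer, insert length 0;
3. ``adapter5_contaminant`` — insert begins with the 5' adapter;
4. ``shorter_than_min``   — trimmed insert below the minimum length;
5. ``polyA``              — insert is (nearly) all adenine;
6. ``clean``              — everything else; the insert enters the clean library.

The same machinery cleans degradome libraries; only the adapter sequences
(and a typically absent polyA class) differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_core import Library

#: Conventional small-RNA adapter defaults; the source adapters are not part
#: of the data model and both are configurable.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

REMOVAL_CATEGORIES = (
    "adapter3_null", "insert_null", "adapter5_contaminant",
    "shorter_than_min", "polyA",
)


@dataclass
class CleanConfig:
    """Parameters of the cleaning stage.

    min_quality: mean-Phred threshold for "high quality" (0 disables).
    min_insert_len: minimum trimmed insert length in nt.
    polyA_fraction: adenine fraction at/above which an insert is polyA.
    contaminant_seed_len: how many leading bases of the 5' adapter mark a
        5'-adapter contaminant.
    adapter_min_overlap / adapter_max_mismatch: 3'-adapter detection — the
        longest adapter prefix (>= min overlap, <= max mismatches) found in
        the read marks the trimming point.
    """

    min_quality: float = 20.0
    min_insert_len: int = 18
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    polyA_fraction: float = 0.9
    contaminant_seed_len: int = 8
    adapter_min_overlap: int = 6
    adapter_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        if not 0.0 <= self.polyA_fraction <= 1.0:
            raise ValueError("polyA_fraction must lie in [0, 1]")
        if self.adapter_min_overlap < 1 or self.contaminant_seed_len < 1:
            raise ValueError("overlap/seed lengths must be >= 1")


@dataclass
class AccountingReport:
    """Removal accounting for one library; counts are reads, not unique tags.

    Invariant: ``high_quality == clean_reads + sum(removed.values())``.
    Percentages use the high-quality count as the 100% denominator.
    """

    total_reads: int
    high_quality: int
    removed: dict[str, int]
    clean_reads: int
    name: str = ""

    @classmethod
    def from_counts(cls, total_reads: int, high_quality: int,
                    removed: dict[str, int], name: str = "") -> "AccountingReport":
        """Build a report from per-category removal counts (clean derived)."""
        removed = {cat: int(removed.get(cat, 0)) for cat in REMOVAL_CATEGORIES}
        clean = high_quality - sum(removed.values())
        rep = cls(total_reads=total_reads, high_quality=high_quality,
                  removed=removed, clean_reads=clean, name=name)
        rep.validate()
        return rep

    def validate(self) -> None:
        if any(v < 0 for v in self.removed.values()) or self.clean_reads < 0:
            raise ValueError("negative count in accounting report")
        if self.high_quality != self.clean_reads + sum(self.removed.values()):
            raise ValueError("accounting conservation violated: "
                             "high_quality != clean + sum(removed)")

    @property
    def percentages(self) -> dict[str, float]:
        if self.high_quality <= 0:
            raise ValueError("high_quality must be > 0 to form percentages")
        pct = {"high_quality": 100.0}
        for cat in REMOVAL_CATEGORIES:
            pct[cat] = round(self.removed[cat] / self.high_quality * 100, 2)
        pct["clean_reads"] = round(self.clean_reads / self.high_quality * 100, 2)
        return pct


def filter_quality(raw: Library, cfg: CleanConfig) -> tuple[Library, int]:
    """Drop reads with mean Phred below threshold or containing ``N``.

    Returns the surviving (high-quality) library and the removed read count;
    counts are conserved between the two outputs.
    """
    hq = Library(name=raw.name)
    removed = 0
    threshold_active = cfg.min_quality > 0
    for seq, count in raw.records.items():
        if "N" in seq:
            removed += count
            continue
        if threshold_active:
            quals = (raw.quality_means or {}).get(seq)
            if quals is None:
                raise ValueError(
                    f"library {raw.name!r}: quality threshold {cfg.min_quality} active "
                    f"but sequence {seq[:20]!r}... carries no quality information")
            keep = sum(1 for q in quals if q >= cfg.min_quality)
            removed += count - keep
            if keep:
                hq.add(seq, keep)
        else:
            hq.add(seq, count)
    return hq, removed


def _find_with_mismatch(seq: str, pattern: str, max_mm: int) -> int:
    """Leftmost start of ``pattern`` in ``seq`` with <= max_mm mismatches, or -1.

    Pigeonhole on the two pattern halves keeps the scan at C speed for the
    common exact case.
    """
    pos = seq.find(pattern)
    if pos != -1 or max_mm == 0:
        return pos
    half = len(pattern) // 2
    p1, p2 = pattern[:half], pattern[half:]
    candidates = set()
    for part, offset in ((p1, 0), (p2, half)):
        if not part:
            continue
        i = seq.find(part)
        while i != -1:
            candidates.add(i - offset)
            i = seq.find(part, i + 1)
    best = -1
    for cand in sorted(candidates):
        if cand < 0 or cand + len(pattern) > len(seq):
            continue
        mm = sum(a != b for a, b in zip(seq[cand:cand + len(pattern)], pattern))
        if mm <= max_mm:
            return cand
    return best


def find_adapter3(seq: str, cfg: CleanConfig) -> int:
    """Trimming point: leftmost hit of the longest adapter prefix, or -1."""
    adapter = cfg.adapter3
    for plen in range(len(adapter), cfg.adapter_min_overlap - 1, -1):
        if plen > len(seq):
            continue
        pos = _find_with_mismatch(seq, adapter[:plen], cfg.adapter_max_mismatch)
        if pos != -1:
            return pos
    return -1


def classify_and_trim(read, cfg: CleanConfig) -> tuple[str, str]:
    """Assign one removal category (or ``clean``) and return the trimmed insert.

    The insert is nonempty only for category ``clean``.
    """
    seq = read if isinstance(read, str) else read.sequence
    seq = seq.upper()
    pos = find_adapter3(seq, cfg)
    if pos == -1:
        return "adapter3_null", ""
    if pos == 0:
        return "insert_null", ""
    insert = seq[:pos]
    k = cfg.contaminant_seed_len
    if len(insert) >= k and insert[:k] == cfg.adapter5[:k]:
        return "adapter5_contaminant", ""
    if len(insert) < cfg.min_insert_len:
        return "shorter_than_min", ""
    if insert.count("A") / len(insert) >= cfg.polyA_fraction:
        return "polyA", ""
    return "clean", insert


def run_preprocess(raw: Library, cfg: CleanConfig) -> tuple[Library, AccountingReport]:
    """Quality-filter, trim and account for a whole library.

    The clean library holds trimmed inserts with merged counts; the report
    satisfies the conservation invariant
    high_quality = clean + sum(removed).
    """
    hq, _low = filter_quality(raw, cfg)
    removed = {cat: 0 for cat in REMOVAL_CATEGORIES}
    clean = Library(name=raw.name)
    for seq, count in hq.records.items():
        category, insert = classify_and_trim(seq, cfg)
        if category == "clean":
            clean.add(insert, count)
        else:
            removed[category] += count
    report = AccountingReport(
        total_reads=raw.total_reads, high_quality=hq.total_reads,
        removed=removed, clean_reads=clean.total_reads, name=raw.name)
    report.validate()
    return clean, report


def percentage_table(report: AccountingReport) -> pd.DataFrame:
    """Data-set-summary rows: category, count, percent of high quality.

    The high-quality row prints 100%; percentages are rounded to 2 decimals.
    """
    pct = report.percentages  # raises on zero high_quality
    rows = [("total_reads", report.total_reads, float("nan")),
            ("high_quality", report.high_quality, pct["high_quality"])]
    for cat in REMOVAL_CATEGORIES:
        rows.append((cat, report.removed[cat], pct[cat]))
    rows.append(("clean_reads", report.clean_reads, pct["clean_reads"]))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
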