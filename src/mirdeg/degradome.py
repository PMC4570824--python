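"""Degradome (PARE) tag mapping, t-plots, cleavage categories and
miRNA-target pairing.

Tag 5' ends are mapped exactly (first 20 nt, sense strand only) onto
transcripts; a per-position pile-up (the t-plot) ranks cleavage signals
into the conventional categories 0–4. A miRNA-target pair is reported when
a position-weighted duplex penalty score clears a threshold and a tag
pile-up of sufficient depth lies opposite miRNA positions 9–11
(canonically 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Optional

import numpy as np

from .io_core import Library, to_rna


# ---------------------------------------------------------------------------
# t-plots
# ---------------------------------------------------------------------------

@dataclass
class TPlot:
    """Per-position degradome tag 5'-end counts along one transcript."""

    transcript_id: str
    length: int
    counts: dict[int, float] = field(default_factory=dict)  # 0-based position -> count

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    @property
    def max_count(self) -> float:
        return max(self.counts.values()) if self.counts else 0.0

    @property
    def median_positive(self) -> float:
        """Median over positions with count >= 1 only (length independent)."""
        pos = [c for c in self.counts.values() if c >= 1]
        return median(pos) if pos else 0.0


def map_tags(tags: Library, transcripts: dict[str, str],
             trunc: int = 20) -> tuple[dict[str, TPlot], float]:
    """Accumulate tag 5'-end counts on transcripts (sense strand, exact).

    Each tag is truncated to its first ``trunc`` nt before matching
    (degradome tag lengths peak at 20–21 nt). A tag matching several sites
    adds its full count at each. Returns (t-plots keyed by transcript,
    unmapped tag count).
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        seq = seq.upper()
        for i in range(0, len(seq) - trunc + 1):
            index.setdefault(seq[i:i + trunc], []).append((tid, i))
    tplots = {tid: TPlot(tid, len(seq)) for tid, seq in transcripts.items()}
    unmapped = 0.0
    for tag, count in tags.records.items():
        key = tag[:trunc]
        sites = index.get(key)
        if len(key) < trunc:
            sites = [(tid, i) for tid, seq in transcripts.items()
                     for i in _find_all(seq.upper(), key)]
        if not sites:
            unmapped += count
            continue
        for tid, i in sites:
            tplots[tid].counts[i] = tplots[tid].counts.get(i, 0) + count
    return tplots, unmapped


def _find_all(seq: str, query: str) -> list[int]:
    out, i = [], seq.find(query)
    while i != -1:
        out.append(i)
        i = seq.find(query, i + 1)
    return out


def classify_category(tplot: TPlot, position: int) -> int:
    """Cleavage category 0–4 of one t-plot position (0-based).

    0: count equals the transcript maximum, maximum unique, count > 1;
    1: equals a shared maximum, count > 1;
    2: below maximum but above the median of positive positions, count > 1;
    3: at or below that median, count > 1;
    4: count == 1.
    """
    c = tplot.counts.get(position, 0)
    if c < 1:
        raise ValueError(f"position {position} has zero tag count")
    if c == 1:
        return 4
    mx = tplot.max_count
    if c == mx:
        n_at_max = sum(1 for v in tplot.counts.values() if v == mx)
        return 0 if n_at_max == 1 else 1
    return 2 if c > tplot.median_positive else 3


# ---------------------------------------------------------------------------
# Duplex scoring
# ---------------------------------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def pair_class(a: str, b: str) -> str:
    """Classify a miRNA base / target base opposition (symmetric in a, b)."""
    if (a, b) in _WC:
        return "match"
    if (a, b) in _GU:
        return "GU"
    return "mismatch"


@dataclass
class DuplexAlignment:
    """miRNA x target-window alignment with per-column states and penalty score.

    Penalties: mismatch 1.0, G·U 0.5, gap 2.0, all doubled at miRNA
    positions 2–13 from the 5' end. ``states`` columns run 5'->3' along the
    miRNA; the window is the target sense sequence.
    """

    mirna: str
    window: str
    states: list[str]
    score: float
    cleavage_site: Optional[int] = None  # 1-based transcript position opposite miRNA pos 10


_PEN = {"match": 0.0, "GU": 0.5, "mismatch": 1.0}
GAP_PENALTY = 2.0


def score_duplex(mirna: str, window: str, max_gaps: int = 1,
                 double_start: int = 2, double_end: int = 13) -> DuplexAlignment:
    """Minimal-penalty global alignment of a miRNA against a target window.

    The window is target sense sequence 5'->3'; the duplex is antiparallel,
    so window position ``len(window)-1-i`` opposes miRNA position ``i+1``.
    At most ``max_gaps`` gap columns are allowed in total (window length
    must lie within miRNA length ± max_gaps); the gap count is an explicit
    alignment state, so compensating gap pairs cannot undercut the gap-free
    alignment. Ties resolve deterministically (pairing preferred over gaps,
    miRNA-gap over target-gap, fewer gaps first).
    """
    m = to_rna(mirna)
    w = to_rna(window)[::-1]  # align 5'->3' of miRNA against 3'->5' of target
    nm, nw = len(m), len(w)
    if abs(nm - nw) > max_gaps:
        raise ValueError(f"window length {nw} outside miRNA length {nm} ± {max_gaps}")

    def mult(i: int) -> float:  # i = 1-based miRNA position
        return 2.0 if double_start <= i <= double_end else 1.0

    INF = float("inf")
    # D[i, j, g]: best cost aligning m[:i] with w[:j] using g gap columns
    D = np.full((nm + 1, nw + 1, max_gaps + 1), INF)
    D[0, 0, 0] = 0.0
    for i in range(nm + 1):
        for j in range(nw + 1):
            for g in range(max_gaps + 1):
                cur = D[i, j, g]
                if cur == INF:
                    continue
                if i < nm and j < nw:
                    cost = _PEN[pair_class(m[i], w[j])] * mult(i + 1)
                    if cur + cost < D[i + 1, j + 1, g]:
                        D[i + 1, j + 1, g] = cur + cost
                if g < max_gaps:
                    if i < nm:  # miRNA base opposite a gap
                        cost = GAP_PENALTY * mult(i + 1)
                        if cur + cost < D[i + 1, j, g + 1]:
                            D[i + 1, j, g + 1] = cur + cost
                    if j < nw:  # target base opposite a gap
                        cost = GAP_PENALTY * mult(min(i + 1, nm))
                        if cur + cost < D[i, j + 1, g + 1]:
                            D[i, j + 1, g + 1] = cur + cost
    g_best = int(np.argmin(D[nm, nw]))
    score = float(D[nm, nw, g_best])
    # deterministic traceback: diagonal > up > left, fewer gaps preferred
    states: list[str] = []
    i, j, g = nm, nw, g_best
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
                D[i, j, g],
                D[i - 1, j - 1, g] + _PEN[pair_class(m[i - 1], w[j - 1])] * mult(i)):
            states.append(pair_class(m[i - 1], w[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and g > 0 and np.isclose(
                D[i, j, g], D[i - 1, j, g - 1] + GAP_PENALTY * mult(i)):
            states.append("gap")
            i, g = i - 1, g - 1
        else:
            states.append("gap")
            j, g = j - 1, g - 1
    states.reverse()
    return DuplexAlignment(mirna=m, window=to_rna(window), states=states,
                           score=score)


def ungapped_score(mirna: str, window: str,
                   double_start: int = 2, double_end: int = 13) -> float:
    """Fast gap-free penalty (>= the banded optimum when lengths match)."""
    m = to_rna(mirna)
    w = to_rna(window)[::-1]
    n = min(len(m), len(w))
    score = abs(len(m) - len(w)) * GAP_PENALTY
    for i in range(n):
        mul = 2.0 if double_start <= i + 1 <= double_end else 1.0
        score += _PEN[pair_class(m[i], w[i])] * mul
    return score


# ---------------------------------------------------------------------------
# Target calling
# ---------------------------------------------------------------------------

@dataclass
class TargetConfig:
    """Degradome target-calling thresholds.

    max_score: duplex penalty ceiling (position-weighted scheme);
    min_tags: minimum tag count at the cleavage position;
    max_category: deepest acceptable t-plot category;
    offsets: acceptable miRNA positions opposite the tag 5' end
        (canonical 10, ±1 for imprecise processing).
    """

    max_score: float = 4.0
    min_tags: float = 2.0
    max_category: int = 3
    offsets: tuple[int, ...] = (10, 9, 11)
    max_gaps: int = 1


@dataclass
class TargetPair:
    """One miRNA x transcript cleavage call with its degradome evidence."""

    mirna_id: str
    transcript_id: str
    cleavage_pos: int      # 1-based transcript position of the tag 5' end
    tag_count: float
    category: int
    score: float
    alignment: DuplexAlignment
    library: str = ""


def find_targets(mirnas: dict[str, str], tplots: dict[str, TPlot],
                 transcripts: dict[str, str],
                 cfg: Optional[TargetConfig] = None,
                 library: str = "") -> list[TargetPair]:
    """Degradome-evidenced targets for a set of miRNAs.

    A pair is reported when the duplex score is <= ``max_score`` and a tag
    5'-end pile-up with count >= ``min_tags`` (category <= ``max_category``)
    lies opposite miRNA positions 9–11. One call per (miRNA, transcript,
    position): the best-scoring offset, canonical position 10 preferred.
    A miRNA may hit many transcripts and vice versa.
    """
    cfg = cfg or TargetConfig()
    mirnas_rna = {mid: to_rna(seq) for mid, seq in sorted(mirnas.items())}
    out: list[TargetPair] = []
    for tid in sorted(tplots):
        tplot = tplots[tid]
        seq = transcripts[tid].upper()
        sites = [(p, c) for p, c in sorted(tplot.counts.items())
                 if c >= cfg.min_tags and classify_category(tplot, p) <= cfg.max_category]
        for p0, count in sites:
            for mid, mseq in mirnas_rna.items():
                L = len(mseq)
                best: Optional[tuple[float, int, DuplexAlignment]] = None
                for rank, k in enumerate(cfg.offsets):
                    start = p0 - (L - k)
                    end = p0 + k - 1  # inclusive
                    if start < 0 or end >= len(seq):
                        continue
                    window = seq[start:end + 1]
                    # cheap upper-bound screen before the banded DP
                    if ungapped_score(mseq, window) > cfg.max_score + 2 * GAP_PENALTY:
                        continue
                    aln = score_duplex(mseq, window, max_gaps=cfg.max_gaps)
                    if aln.score <= cfg.max_score:
                        key = (aln.score, rank)
                        if best is None or key < (best[0], best[1]):
                            best = (aln.score, rank, aln)
                if best is not None:
                    aln = best[2]
                    aln.cleavage_site = p0 + 1
                    out.append(TargetPair(
                        mirna_id=mid, transcript_id=tid, cleavage_pos=p0 + 1,
                        tag_count=count, category=classify_category(tplot, p0),
                        score=best[0], alignment=aln, library=library))
    return out


def predict_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                    max_score: float = 4.0) -> list[tuple[str, str, int, float]]:
    """Complementarity-only target scan (no degradome evidence required).

    Returns (miRNA id, transcript id, 1-based cleavage position, score) for
    every window whose gap-free duplex penalty is <= ``max_score``.
    """
    out = []
    for mid, mseq in sorted(mirnas.items()):
        m = to_rna(mseq)
        L = len(m)
        for tid in sorted(transcripts):
            seq = transcripts[tid].upper()
            for start in range(0, len(seq) - L + 1):
                score = ungapped_score(m, seq[start:start + L])
                if score <= max_score:
                    out.append((mid, tid, start + L - 10 + 1, score))
    return out
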