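"""Known-miRNA counting and novel plant miRNA prediction.

Novel candidates are called from clusters of unannotated genome-mapped
reads: the dominant 20–22 nt read must account for > 75% of the cluster
(5'-end specificity), and the surrounding genomic window must fold into a
hairpin placing the candidate wholly in one arm with a well-formed
miRNA/miRNA* duplex (few unpaired positions, no large asymmetric bulge).
The folder maximizes nested base pairing (Watson–Crick + G·U wobble) by
dynamic programming; the weighted score (GC=3, AU=2, GU=1) is the
stability proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotate import Hit
from .io_core import Library, revcomp, to_dna, to_rna

# ---------------------------------------------------------------------------
# Known-miRNA counting
# ---------------------------------------------------------------------------

def count_known(clean: Library, mature_db: dict[str, str],
                precursor_db: Optional[dict[str, str]] = None,
                max_mismatch: int = 0, max_len_diff: int = 2,
                ) -> tuple[dict[str, int], dict[str, str]]:
    """Sum read counts per known mature miRNA.

    A read matches a mature sequence when their 5' ends align (anchored),
    the length difference is <= ``max_len_diff`` and the overlap carries
    <= ``max_mismatch`` mismatches (default 0: perfect match, 3' length
    variants allowed). Each read is assigned to at most one miRNA; ties
    break by fewest mismatches, then smallest length difference, then
    miRNA identifier.

    Returns (counts per miRNA id, read -> miRNA assignment).
    """
    if not mature_db:
        raise ValueError("mature miRNA set is empty")
    matures = {mid: to_dna(seq) for mid, seq in mature_db.items()}
    counts = {mid: 0 for mid in matures}
    assigned: dict[str, str] = {}
    for seq, count in clean.records.items():
        best = None
        for mid in sorted(matures):
            m = matures[mid]
            ld = abs(len(seq) - len(m))
            if ld > max_len_diff:
                continue
            k = min(len(seq), len(m))
            mm = sum(a != b for a, b in zip(seq[:k], m[:k]))
            if mm > max_mismatch:
                continue
            key = (mm, ld, mid)
            if best is None or key < best:
                best = key
        if best is not None:
            counts[best[2]] += count
            assigned[seq] = best[2]
    return counts, assigned


# ---------------------------------------------------------------------------
# Read clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterMember:
    seq: str
    start: int   # 0-based genomic start
    end: int
    weight: float  # library count divided equally among the read's loci

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand handled by the cluster)."""
        return self.start


@dataclass
class ReadCluster:
    """Overlapping unannotated reads at one genomic locus (single strand)."""

    chrom: str
    strand: str
    start: int
    end: int
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def total_count(self) -> float:
        return sum(m.weight for m in self.members)

    def _member_5p(self, m: ClusterMember) -> int:
        return m.start if self.strand == "+" else m.end

    @property
    def dominant(self) -> ClusterMember:
        """Highest-weight member; ties break to the lexicographically smallest sequence."""
        return min(self.members, key=lambda m: (-m.weight, m.seq))

    @property
    def specificity(self) -> float:
        """Fraction of the cluster in the dominant 5'-end group.

        Reads sharing the dominant 5' end but differing at the 3' end count
        toward the dominant group.
        """
        dom5 = self._member_5p(self.dominant)
        grp = sum(m.weight for m in self.members if self._member_5p(m) == dom5)
        return grp / self.total_count


def extract_clusters(hits: dict[str, list[Hit]], lib: Library,
                     merge_gap: int = 100) -> list[ReadCluster]:
    """Group unannotated read loci lying within ``merge_gap`` of each other.

    Multi-locus reads contribute their count divided equally among loci so
    that total counts are conserved.
    """
    placed: dict[tuple[str, str], list[ClusterMember]] = {}
    for seq, seq_hits in hits.items():
        if not seq_hits:
            continue
        weight = lib.records.get(seq, 0) / len(seq_hits)
        if weight == 0:
            continue
        for hit in seq_hits:
            placed.setdefault((hit.chrom, hit.strand), []).append(
                ClusterMember(seq, hit.start, hit.start + len(seq), weight))
    clusters: list[ReadCluster] = []
    for (chrom, strand) in sorted(placed):
        members = sorted(placed[(chrom, strand)], key=lambda m: (m.start, m.end, m.seq))
        current: Optional[ReadCluster] = None
        for m in members:
            if current is not None and m.start <= current.end + merge_gap:
                current.members.append(m)
                current.end = max(current.end, m.end)
            else:
                current = ReadCluster(chrom, strand, m.start, m.end, [m])
                clusters.append(current)
    return clusters


# ---------------------------------------------------------------------------
# Hairpin folding (nested max base pairing over WC + GU, min loop 3)
# ---------------------------------------------------------------------------

#: Pair weights: GC=3, AU=2, GU=1 (stability proxy).
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

_WEIGHT_SCALE = 4096  # combined DP score: n_pairs * SCALE + weight (weight < SCALE)


def _pair_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    P = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            w = PAIR_WEIGHT.get((seq[i], seq[j]))
            if w:
                P[i, j] = _WEIGHT_SCALE + w
    return P


def max_pairing(seq: str, min_loop: int = 3) -> tuple[set[tuple[int, int]], int, int]:
    """Maximum nested base-pairing structure of an RNA string.

    Maximizes the number of pairs, breaking ties toward the larger weighted
    score, with a deterministic traceback. Pairs (i, j) require
    ``j - i > min_loop``. Returns (pairs, n_pairs, weighted_score).
    """
    seq = to_rna(seq)
    n = len(seq)
    if n == 0:
        return set(), 0, 0
    P = _pair_matrix(seq)
    # pair bonus by (right-end, left-end); impossible pairs sink to -inf-ish
    PM = np.where(P.T > 0, P.T, np.int64(-1) << 40)
    # E[i, j] = best combined score for seq[i:j] (half-open); ET = E transposed
    # (kept in sync so every slice below is contiguous)
    E = np.zeros((n + 2, n + 1), dtype=np.int64)
    ET = np.zeros((n + 1, n + 2), dtype=np.int64)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = E[i, j - 1]  # j-1 unpaired
            # pair (k, j-1) with i <= k <= j-min_loop-2
            kmax = j - min_loop - 1  # exclusive
            if kmax > i:
                cand = E[i, i:kmax] + PM[j - 1, i:kmax] + ET[j - 1, i + 1:kmax + 1]
                m = cand.max()
                if m > best:
                    best = m
            E[i, j] = best
            ET[j, i] = best
    pairs: set[tuple[int, int]] = set()

    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop + 1:
            continue
        if E[i, j] == E[i, j - 1]:
            stack.append((i, j - 1))
            continue
        kmax = j - min_loop - 1
        cand = E[i, i:kmax] + PM[j - 1, i:kmax] + ET[j - 1, i + 1:kmax + 1]
        k = i + int(np.argmax(cand))  # first k achieving the optimum
        pairs.add((k, j - 1))
        stack.append((i, k))
        stack.append((k + 1, j - 1))
    n_pairs = len(pairs)
    weight = sum(PAIR_WEIGHT[(seq[i], seq[j])] for i, j in pairs)
    return pairs, n_pairs, weight


@dataclass
class HairpinStructure:
    """Nested secondary structure of a candidate precursor.

    ``arms``/``loop`` are half-open intervals derived from the innermost
    (smallest-span) stem pair; for clean hairpins this is the terminal loop.
    """

    sequence: str  # RNA
    pairs: frozenset[tuple[int, int]]
    pairing_score: int
    weighted_score: int
    five_prime_arm: tuple[int, int]
    loop: tuple[int, int]
    three_prime_arm: tuple[int, int]

    @property
    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def fold_hairpin(seq: str, min_loop: int = 3,
                 min_len: int = 40, max_len: int = 400) -> HairpinStructure:
    """Fold a candidate precursor window into its max-pairing structure."""
    rna = to_rna(seq)
    if not (min_len <= len(rna) <= max_len):
        raise ValueError(f"precursor length {len(rna)} outside [{min_len}, {max_len}]")
    pairs, n_pairs, weight = max_pairing(rna, min_loop=min_loop)
    n = len(rna)
    if pairs:
        li, lj = min(pairs, key=lambda p: (p[1] - p[0], p[0]))
        arms = ((0, li + 1), (li + 1, lj), (lj, n))
    else:
        arms = ((0, n), (n, n), (n, n))
    return HairpinStructure(sequence=rna, pairs=frozenset(pairs),
                            pairing_score=n_pairs, weighted_score=weight,
                            five_prime_arm=arms[0], loop=arms[1],
                            three_prime_arm=arms[2])


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryConfig:
    """Plant-miRNA annotation criteria; all thresholds configurable.

    mature length 20–22 nt; locus specificity > 0.75; flank window ±150 nt;
    <= 4 unpaired mature positions in the duplex; no asymmetric bulge
    > 2 nt; weighted stability >= 18; >= 3 supporting reads.
    """

    mature_len_range: tuple[int, int] = (20, 22)
    min_specificity: float = 0.75
    flank: int = 150
    max_unpaired_mature: int = 4
    max_bulge: int = 2
    min_stability: int = 18
    min_loop: int = 3
    min_count: float = 3.0
    merge_gap: int = 100


@dataclass
class MiRNACandidate:
    """An accepted novel miRNA: mature/star/precursor with locus and evidence."""

    mature: str                 # RNA
    star: Optional[str]         # RNA or None
    precursor: str              # RNA (folded genomic window)
    chrom: str
    start: int                  # 0-based window start on the genome
    end: int
    strand: str
    mature_offset: int          # 0-based offset of the mature within the window
    arm: str                    # "5p" | "3p"
    specificity: float
    counts: dict[str, float] = field(default_factory=dict)
    star_observed: bool = False
    known_match: bool = False
    structure: Optional[HairpinStructure] = None

    @property
    def mature_dna(self) -> str:
        return to_dna(self.mature)

    @property
    def mature_genomic_span(self) -> tuple[int, int]:
        """0-based half-open genomic interval of the mature read."""
        L = len(self.mature)
        if self.strand == "+":
            return self.start + self.mature_offset, self.start + self.mature_offset + L
        return self.end - self.mature_offset - L, self.end - self.mature_offset


def assess_duplex(structure: HairpinStructure, m_start: int, m_end: int,
                  cfg: DiscoveryConfig) -> tuple[Optional[str], Optional[str]]:
    """Check the mature's duplex geometry inside a folded window.

    Returns (arm, None) on success or (None, rejection reason). The mature
    must sit wholly in one arm: its partners lie outside the mature, on a
    single side, in antiparallel (strictly decreasing) order; at most
    ``max_unpaired_mature`` positions unpaired; adjacent duplex pairs may
    differ by at most ``max_bulge`` nt of asymmetry.
    """
    partner = structure.partner
    paired = [(i, partner[i]) for i in range(m_start, m_end) if i in partner]
    unpaired = (m_end - m_start) - len(paired)
    if unpaired > cfg.max_unpaired_mature:
        return None, f"too many unpaired mature positions ({unpaired})"
    if not paired:
        return None, "mature entirely unpaired"
    sides = {p >= m_end for _, p in paired}
    if any(m_start <= p < m_end for _, p in paired):
        return None, "mature pairs with itself"
    if len(sides) > 1:
        return None, "mature spans the loop"
    for (i1, p1), (i2, p2) in zip(paired, paired[1:]):
        if p2 >= p1:
            return None, "mature duplex is not antiparallel"
        bulge = abs((i2 - i1 - 1) - (p1 - p2 - 1))
        if bulge > cfg.max_bulge:
            return None, f"asymmetric bulge of {bulge} nt in duplex"
    if structure.weighted_score < cfg.min_stability:
        return None, f"weighted stability {structure.weighted_score} < {cfg.min_stability}"
    arm = "5p" if sides == {True} else "3p"
    return arm, None


def evaluate_precursor(cluster: ReadCluster, genome: dict[str, str],
                       cfg: Optional[DiscoveryConfig] = None,
                       ) -> tuple[Optional[MiRNACandidate], Optional[str]]:
    """Accept or reject a read cluster as a novel miRNA locus.

    Returns (candidate, None) or (None, rejection reason). Acceptance
    requires, in order: cluster support >= min_count, dominant read length
    20–22 nt, 5'-end specificity > 0.75, and a hairpin fold of the flanked
    window passing :func:`assess_duplex`.
    """
    cfg = cfg or DiscoveryConfig()
    if cluster.total_count < cfg.min_count:
        return None, f"cluster support {cluster.total_count:.1f} < {cfg.min_count}"
    dom = cluster.dominant
    lo, hi = cfg.mature_len_range
    if not (lo <= len(dom.seq) <= hi):
        return None, f"dominant read length {len(dom.seq)} outside [{lo}, {hi}]"
    spec = cluster.specificity
    if not spec > cfg.min_specificity:
        return None, f"specificity {spec:.2f} <= {cfg.min_specificity}"
    chrom_seq = genome[cluster.chrom]
    wstart = max(0, dom.start - cfg.flank)
    wend = min(len(chrom_seq), dom.end + cfg.flank)
    window = chrom_seq[wstart:wend]
    if cluster.strand == "-":
        window = revcomp(window)
        m_start = wend - dom.end
    else:
        m_start = dom.start - wstart
    m_end = m_start + len(dom.seq)
    if len(window) < 40:
        return None, "fold window too short"
    structure = fold_hairpin(window, min_loop=cfg.min_loop)
    arm, reason = assess_duplex(structure, m_start, m_end, cfg)
    if arm is None:
        return None, reason
    mature_rna = to_rna(dom.seq)
    cand = MiRNACandidate(
        mature=mature_rna, star=None, precursor=structure.sequence,
        chrom=cluster.chrom, start=wstart, end=wend, strand=cluster.strand,
        mature_offset=m_start, arm=arm, specificity=spec, structure=structure)
    star, _, _ = find_star(cand, structure)
    cand.star = star
    return cand, None


def find_star(candidate: MiRNACandidate, structure: HairpinStructure,
              tolerance: int = 2) -> tuple[Optional[str], Optional[tuple[int, int]],
                                           Optional[str]]:
    """miRNA* segment pairing the mature with 2-nt 3' overhangs on both ends.

    With partner map ``p`` and mature [a, b] (0-based inclusive), the star
    spans [p(b-2), p(a)+2]; if those positions are unpaired, the nearest
    paired position within ``tolerance`` is extrapolated from. Returns
    (star RNA, (start, end) half-open in the window, reason-if-absent).
    """
    partner = structure.partner
    a = candidate.mature_offset
    b = candidate.mature_offset + len(candidate.mature) - 1
    m_set = range(a, b + 1)
    paired = [(i, partner[i]) for i in m_set if i in partner]
    if not paired:
        return None, None, "mature unpaired"
    sides = {p > b for _, p in paired}
    if len(sides) > 1 or any(a <= p <= b for _, p in paired):
        return None, None, "mature spans the loop"

    def anchored(target: int, direction: int) -> Optional[tuple[int, int]]:
        for off in range(tolerance + 1):
            i = target + direction * off
            if a <= i <= b and i in partner:
                return i, partner[i]
        return None

    anchor_hi = anchored(b - 2, -1)   # pairs the star 5' end
    anchor_lo = anchored(a, +1)       # pairs (2 nt short of) the star 3' end
    if anchor_hi is None or anchor_lo is None:
        return None, None, "mature ends unpaired beyond tolerance"
    i2, p2 = anchor_hi
    i1, p1 = anchor_lo
    c = p2 - ((b - 2) - i2)
    d = p1 + (i1 - a) + 2
    if c > d:
        c, d = d, c
    n = len(structure.sequence)
    c = max(0, c)
    d = min(n - 1, d)
    star = structure.sequence[c:d + 1]
    return star, (c, d + 1), None


def star_observed(star_rna: Optional[str], lib: Library) -> bool:
    """Whether the star sequence itself was sequenced in the library."""
    return star_rna is not None and to_dna(star_rna) in lib.records
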