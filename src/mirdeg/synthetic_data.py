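"""Fully specified synthetic two-condition study with ground truth.

Generates a compact genome carrying planted miRNA hairpin precursors
(validated against the discovery module's own folder), structural-RNA and
repeat annotation, transcripts with embedded miRNA target sites, known and
novel mature miRNA sets with planted expression differences, and raw
small-RNA / degradome FASTQ libraries with adapter-contamination classes —
plus a machine-readable truth manifest so every pipeline stage is testable
offline.

All randomness flows from the single supplied seed; the same (cfg, seed)
always produces identical manifests and identical read sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .io_core import Feature, Library, revcomp, to_dna
from .mirna_discovery import (DiscoveryConfig, MiRNACandidate, assess_duplex,
                              fold_hairpin, find_star)
from .preprocess import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, CleanConfig, classify_and_trim

CONDITIONS = ("wild", "mutant")

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Sizes are desk-scale stand-ins for the study's two unreplicated
    libraries; contamination fractions follow the magnitudes of a typical
    small-RNA data-set summary (per-category fractions of high-quality
    reads). ``signal_to_noise`` scales the degradome cleavage pile-up depth
    against the per-position background rate.
    """

    n_precursors: int = 20          # novel (unannotated) hairpin loci
    n_known: int = 30               # annotated known-miRNA loci
    n_transcripts: int = 50
    n_chroms: int = 4
    intergenic_len: int = 5000      # unannotated spacer per chromosome
    mature_len_choices: tuple[int, ...] = (20, 21, 21, 21, 22)  # 21 nt dominant
    loop_len: int = 8
    flank_len: int = 160            # per-precursor neutral flank (> fold flank)
    max_planted_mismatches: int = 2
    transcript_len: int = 300
    n_targets_known: int = 20
    n_targets_novel: int = 12

    # expression truth
    expr_mean_range: tuple[float, float] = (80.0, 800.0)  # log-uniform
    frac_up: float = 0.2            # higher in mutant (log2 wild/mutant = -effect)
    frac_down: float = 0.2
    frac_specific: float = 0.1      # split evenly between conditions
    log2fc_effect: float = 2.0

    # small-RNA library composition (fractions of expected clean reads)
    frac_mirna: float = 0.45
    frac_structural: float = 0.20
    frac_degradation: float = 0.15
    frac_unmappable: float = 0.20
    star_fraction: float = 0.08     # star reads per mature read
    isomir_fraction: float = 0.12   # same 5' end, 3' +/- 1 nt
    offstart_fraction: float = 0.05 # shifted 5' end (counts against specificity)
    n_hotspots: int = 150           # degradation pile-up loci
    read_len: int = 36
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    base_quality: int = 35
    low_quality: int = 10

    #: per-category contamination fractions (of high-quality reads), plus a
    #: low-quality fraction of total reads.
    contamination: dict = field(default_factory=lambda: {
        "low_quality": 0.003,
        "adapter3_null": 0.0004,
        "insert_null": 0.0007,
        "adapter5_contaminant": 0.009,
        "shorter_than_min": 0.05,
        "polyA": 0.0002,
    })
    deg_contamination: dict = field(default_factory=lambda: {
        "low_quality": 0.002,
        "adapter3_null": 0.0004,
        "insert_null": 0.0002,
        "adapter5_contaminant": 0.004,
        "shorter_than_min": 0.0002,
        "polyA": 0.0,
    })

    # degradome
    background_per_position: float = 0.5
    signal_to_noise: float = 20.0
    deg_tag_lens: tuple[int, ...] = (20, 21)
    deg_frac_unmappable: float = 0.25

    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)

    def clean_config(self) -> CleanConfig:
        return CleanConfig(adapter3=self.adapter3, adapter5=self.adapter5)


@dataclass
class PlantedPrecursor:
    mirna_id: str
    mature: str          # DNA
    star: str            # DNA (2-nt-overhang segment, from the folder itself)
    arm: str
    chrom: str
    hairpin_start: int   # 0-based genomic
    hairpin_end: int
    mature_start: int
    strand: str = "+"
    known: bool = False


@dataclass
class PlantedTarget:
    mirna_id: str
    mature: str
    transcript_id: str
    site_start: int      # 0-based start of the reverse-complement site
    cleavage_pos: int    # 0-based transcript position opposite miRNA pos 10


@dataclass
class TruthManifest:
    """Ground truth that fully determines both FASTQ outputs given the seed."""

    cfg: SimConfig
    seed: int
    genome: dict[str, str]
    features: list[Feature]
    transcripts: dict[str, str]
    precursors: list[PlantedPrecursor]       # novel loci
    known_loci: list[PlantedPrecursor]       # annotated known-miRNA loci
    targets: list[PlantedTarget]
    #: miRNA id -> {mean_wild, mean_mutant, log2fc (wild/mutant), call}
    expression: dict[str, dict]
    hotspots: list[tuple[str, int]]
    mappable_fraction: dict[str, float]      # expected, per condition
    deg_mappable_fraction: float

    def mature_of(self, mirna_id: str) -> str:
        for p in self.precursors + self.known_loci:
            if p.mirna_id == mirna_id:
                return p.mature
        raise KeyError(mirna_id)

    def known_mature_db(self) -> dict[str, str]:
        return {p.mirna_id: p.mature for p in self.known_loci}

    def known_precursor_db(self) -> dict[str, str]:
        return {p.mirna_id: self.genome[p.chrom][p.hairpin_start:p.hairpin_end]
                for p in self.known_loci}

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["features"] = [[f.chrom, f.start, f.end, f.strand, f.cls, f.label]
                               for f in self.features]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        payload["cfg"]["discovery"] = DiscoveryConfig(**payload["cfg"]["discovery"])
        for key in ("mature_len_choices", "deg_tag_lens", "expr_mean_range"):
            payload["cfg"][key] = tuple(payload["cfg"][key])
        payload["cfg"] = SimConfig(**payload["cfg"])
        payload["features"] = [Feature(*f) for f in payload["features"]]
        payload["precursors"] = [PlantedPrecursor(**p) for p in payload["precursors"]]
        payload["known_loci"] = [PlantedPrecursor(**p) for p in payload["known_loci"]]
        payload["targets"] = [PlantedTarget(**t) for t in payload["targets"]]
        payload["hotspots"] = [tuple(h) for h in payload["hotspots"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_mature(rng: np.random.Generator, length: int) -> str:
    seq = _random_seq(rng, length)
    if rng.random() < 0.7:  # 5'-U bias, the plant miRNA signature
        seq = "T" + seq[1:]
    return seq


def _build_hairpin(rng: np.random.Generator, mature: str, arm: str,
                   loop_len: int, max_mm: int) -> str:
    """mature + loop + mutated complement arm (or the 3p mirror)."""
    comp = revcomp(mature)
    # at least one planted mismatch so the mature cannot multimap to its own
    # star arm (perfect inverted repeats are also biologically rare)
    n_mut = int(rng.integers(1, max(2, max_mm + 1)))
    comp_list = list(comp)
    if n_mut and len(comp) > 8:
        sites = rng.choice(np.arange(3, len(comp) - 4), size=n_mut, replace=False)
        for s in sites:
            choices = [b for b in "ACGT" if b != comp_list[s]]
            comp_list[int(s)] = choices[int(rng.integers(0, 3))]
    comp = "".join(comp_list)
    loop = _random_seq(rng, loop_len)
    return mature + loop + comp if arm == "5p" else comp + loop + mature


def _validate_precursor(block: str, m_start: int, m_len: int,
                        cfg: DiscoveryConfig) -> Optional[tuple[str, str]]:
    """Fold the mature's discovery window inside ``block``; return
    (arm, star DNA) when the hairpin passes the duplex criteria."""
    wstart = max(0, m_start - cfg.flank)
    wend = min(len(block), m_start + m_len + cfg.flank)
    window = block[wstart:wend]
    if len(window) < 40:
        return None
    structure = fold_hairpin(window, min_loop=cfg.min_loop)
    a = m_start - wstart
    arm, reason = assess_duplex(structure, a, a + m_len, cfg)
    if arm is None:
        return None
    cand = MiRNACandidate(
        mature=structure.sequence[a:a + m_len], star=None,
        precursor=structure.sequence, chrom="", start=0, end=len(window),
        strand="+", mature_offset=a, arm=arm, specificity=1.0)
    star, _span, _reason = find_star(cand, structure)
    if star is None:
        return None
    return arm, to_dna(star)


def _insert_survives(insert: str, cfg: SimConfig, clean_cfg: CleanConfig) -> bool:
    """True when the adapter-wrapped read cleans back to exactly ``insert``."""
    if not insert:
        return False
    category, trimmed = classify_and_trim(_wrap_read(insert, cfg), clean_cfg)
    return category == "clean" and trimmed == insert


_STRUCTURAL_BLOCKS = (  # (class, length, copies per genome)
    ("rRNA", 800, 2), ("tRNA", 80, 4), ("snRNA", 150, 2),
    ("snoRNA", 120, 2), ("repeat", 400, 3), ("exon", 400, 3), ("intron", 300, 2),
)


def build_truth(cfg: SimConfig, seed: int) -> TruthManifest:
    """Construct the deterministic ground truth for one synthetic study.

    Precursors are rejection-sampled until their genomic discovery window
    folds into a hairpin passing the discovery module's own duplex
    criteria, so every planted mature is recoverable in principle.
    """
    rng = np.random.default_rng([int(seed), 0])
    clean_cfg = cfg.clean_config()

    def planted_locus(mirna_id: str, known: bool) -> tuple[str, PlantedPrecursor]:
        for _attempt in range(200):
            length = int(rng.choice(cfg.mature_len_choices))
            mature = _random_mature(rng, length)
            if not _insert_survives(mature, cfg, clean_cfg):
                continue
            arm = "5p" if rng.random() < 0.5 else "3p"
            hairpin = _build_hairpin(rng, mature, arm, cfg.loop_len,
                                     cfg.max_planted_mismatches)
            flank_l = _random_seq(rng, cfg.flank_len)
            flank_r = _random_seq(rng, cfg.flank_len)
            block = flank_l + hairpin + flank_r
            m_start = len(flank_l) + (0 if arm == "5p" else len(hairpin) - length)
            res = _validate_precursor(block, m_start, length, cfg.discovery)
            if res is None:
                continue
            arm_found, star = res
            rec = PlantedPrecursor(
                mirna_id=mirna_id, mature=mature, star=star, arm=arm_found,
                chrom="", hairpin_start=len(flank_l),
                hairpin_end=len(flank_l) + len(hairpin),
                mature_start=m_start, known=known)
            return block, rec
        raise RuntimeError("could not plant a valid precursor in 200 attempts")

    # --- assemble chromosomes from precursor + structural blocks
    chroms = {f"chr{i + 1}": "" for i in range(cfg.n_chroms)}
    features: list[Feature] = []
    precursors: list[PlantedPrecursor] = []
    known_loci: list[PlantedPrecursor] = []
    blocks: list[tuple[str, object]] = []
    for i in range(cfg.n_precursors):
        blocks.append(planted_locus(f"novel_mir_{i + 1:03d}", known=False))
    for i in range(cfg.n_known):
        blocks.append(planted_locus(f"known_mir_{i + 1:03d}", known=True))
    for cls, length, copies in _STRUCTURAL_BLOCKS:
        for _c in range(copies):
            blocks.append((_random_seq(rng, length), cls))
    for _c in range(cfg.n_chroms):  # unannotated intergenic space (hotspot room)
        blocks.append((_random_seq(rng, cfg.intergenic_len), None))

    chrom_names = sorted(chroms)
    for i, (block, info) in enumerate(blocks):
        name = chrom_names[i % cfg.n_chroms]
        offset = len(chroms[name])
        chroms[name] += block
        if isinstance(info, PlantedPrecursor):
            info.chrom = name
            info.hairpin_start += offset
            info.hairpin_end += offset
            info.mature_start += offset
            (known_loci if info.known else precursors).append(info)
            if info.known:
                features.append(Feature(name, info.hairpin_start, info.hairpin_end,
                                        "+", "known_miRNA_precursor", info.mirna_id))
        elif info is not None:
            features.append(Feature(name, offset, offset + len(block), "+",
                                    str(info), f"{info}_{i}"))

    # guard: every planted mature must map uniquely in the genome
    for p in precursors + known_loci:
        occurrences = sum(chroms[c].count(p.mature) + chroms[c].count(revcomp(p.mature))
                          for c in chroms)
        if occurrences != 1:
            return build_truth(cfg, seed + 90001)  # vanishingly rare; reseed

    # --- expression truth
    ids = [p.mirna_id for p in known_loci] + [p.mirna_id for p in precursors]
    lo, hi = cfg.expr_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), len(ids)))
    classes = []
    for pool in (range(len(known_loci)), range(len(known_loci), len(ids))):
        pool = list(pool)
        n = len(pool)
        shuffled = list(rng.permutation(pool))
        n_up = int(round(cfg.frac_up * n))
        n_down = int(round(cfg.frac_down * n))
        n_spec = int(round(cfg.frac_specific * n))
        assign = {}
        k = 0
        for _ in range(n_up):
            assign[shuffled[k]] = "up_in_mutant"; k += 1
        for _ in range(n_down):
            assign[shuffled[k]] = "down_in_mutant"; k += 1
        for j in range(n_spec):
            assign[shuffled[k]] = "specific_wild" if j % 2 == 0 else "specific_mutant"
            k += 1
        for idx in shuffled[k:]:
            assign[idx] = "unchanged"
        classes.append(assign)
    assign = {**classes[0], **classes[1]}
    expression: dict[str, dict] = {}
    eff = cfg.log2fc_effect
    for i, mid in enumerate(ids):
        call = assign[i]
        base = float(means[i])
        if call == "up_in_mutant":
            fc = -eff
        elif call == "down_in_mutant":
            fc = eff
        else:
            fc = 0.0
        mw = base * 2 ** (fc / 2)
        mm = base * 2 ** (-fc / 2)
        if call == "specific_wild":
            mm = 0.0
        elif call == "specific_mutant":
            mw = 0.0
        expression[mid] = {"mean_wild": mw, "mean_mutant": mm,
                           "log2fc": fc, "call": call}

    # --- transcripts and target sites
    n_targets = cfg.n_targets_known + cfg.n_targets_novel
    if n_targets > cfg.n_transcripts:
        raise ValueError("more targets than transcripts can host (one site each)")
    transcripts = {f"t_{i + 1:03d}": _random_seq(rng, cfg.transcript_len)
                   for i in range(cfg.n_transcripts)}
    tids = sorted(transcripts)
    host_ids = list(rng.permutation(tids)[:n_targets])
    target_mirnas = (
        [p.mirna_id for p in rng.permutation(known_loci)[:cfg.n_targets_known]]
        + [p.mirna_id for p in rng.permutation(precursors)[:cfg.n_targets_novel]])
    targets: list[PlantedTarget] = []
    mature_by_id = {p.mirna_id: p.mature for p in known_loci + precursors}
    for tid, mid in zip(host_ids, target_mirnas):
        mature = mature_by_id[mid]
        L = len(mature)
        max_tag = max(cfg.deg_tag_lens)
        site_start = int(rng.integers(40, cfg.transcript_len - L - max_tag - 15))
        site = revcomp(mature)
        seq = transcripts[tid]
        transcripts[tid] = seq[:site_start] + site + seq[site_start + L:]
        targets.append(PlantedTarget(
            mirna_id=mid, mature=mature, transcript_id=tid,
            site_start=site_start, cleavage_pos=site_start + L - 10))

    # --- degradation hotspots (away from planted matures)
    mature_zones = {(p.chrom, p.mature_start) for p in precursors + known_loci}
    hotspots: list[tuple[str, int]] = []
    guard = 0
    while len(hotspots) < cfg.n_hotspots and guard < 100 * cfg.n_hotspots:
        guard += 1
        chrom = chrom_names[int(rng.integers(0, cfg.n_chroms))]
        pos = int(rng.integers(0, max(1, len(chroms[chrom]) - 40)))
        if any(c == chrom and abs(pos - ms) < 300 for c, ms in mature_zones):
            continue
        hotspots.append((chrom, pos))

    # --- expected mappable fraction per condition
    mappable_fraction = {}
    for cond in CONDITIONS:
        mirna = sum(e[f"mean_{cond}"] for e in expression.values())
        mirna *= (1 + cfg.star_fraction)
        total = mirna / cfg.frac_mirna
        mappable = mirna + (cfg.frac_structural + cfg.frac_degradation) * total
        mappable_fraction[cond] = mappable / total

    return TruthManifest(
        cfg=cfg, seed=int(seed), genome=chroms, features=features,
        transcripts=transcripts, precursors=precursors, known_loci=known_loci,
        targets=targets, expression=expression, hotspots=hotspots,
        mappable_fraction=mappable_fraction,
        deg_mappable_fraction=1.0 - cfg.deg_frac_unmappable)


# ---------------------------------------------------------------------------
# Small-RNA library simulation
# ---------------------------------------------------------------------------

@dataclass
class SrnaRealization:
    """Exact realized composition of one simulated library."""

    condition: str
    mirna_counts: dict[str, int]          # reads countable toward each miRNA
    category_counts: dict[str, int]       # contamination classes + low_quality
    clean_reads: int
    mappable_reads: int
    length_counts: dict[int, int]


def _deg_length(rng: np.random.Generator) -> int:
    """Bimodal insert-length profile with modes at 21 and 24 nt."""
    r = rng.random()
    if r < 0.35:
        return 21
    if r < 0.70:
        return 24
    return int(rng.integers(18, 27))


def _wrap_read(insert: str, cfg: SimConfig) -> str:
    read = insert + cfg.adapter3
    while len(read) < cfg.read_len:
        read += cfg.adapter3
    return read[:cfg.read_len]


def simulate_srna(truth: TruthManifest, condition: str, seed: int,
                  path=None) -> tuple[Library, SrnaRealization]:
    """Emit one condition's raw small-RNA library (optionally as FASTQ).

    miRNA read counts are Poisson around the manifest means; structural and
    degradation reads are sampled from the annotated genome; adapter
    contamination classes are appended at the configured fractions. Every
    intended-clean insert is verified to survive the cleaning rules, so the
    manifest's category accounting is exact.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.cfg
    rng = np.random.default_rng([int(seed), 1 + CONDITIONS.index(condition)])
    clean_cfg = cfg.clean_config()
    lib = Library(name=f"srna_{condition}", quality_means={})
    q = float(cfg.base_quality)
    realization = SrnaRealization(condition, {}, {}, 0, 0, {})

    def emit(insert: str, count: int, quality: float = q) -> None:
        if count <= 0:
            return
        lib.add(_wrap_read(insert, cfg), count, quality)

    def tally_len(insert: str, count: int) -> None:
        realization.length_counts[len(insert)] = (
            realization.length_counts.get(len(insert), 0) + count)

    def clean_insert_ok(insert: str) -> bool:
        return _insert_survives(insert, cfg, clean_cfg)

    genome_index = None  # built lazily for the unmappable guard

    # --- miRNA reads (mature, isomiR, shifted-5', star)
    all_loci = truth.known_loci + truth.precursors
    hairpins = {p.mirna_id: truth.genome[p.chrom][p.hairpin_start - 2:
                                                  p.hairpin_end + 2]
                for p in all_loci}
    clean_total = 0
    mappable = 0
    for p in all_loci:
        mean = truth.expression[p.mirna_id][f"mean_{condition}"]
        if mean <= 0:
            realization.mirna_counts[p.mirna_id] = 0
            continue
        n_mature = int(rng.poisson(mean))
        n_iso = int(rng.binomial(n_mature, cfg.isomir_fraction)) if n_mature else 0
        n_off = int(rng.poisson(mean * cfg.offstart_fraction))
        n_star = int(rng.poisson(mean * cfg.star_fraction))
        mstart_local = p.mature_start - p.hairpin_start + 2
        hp = hairpins[p.mirna_id]
        trimmed = p.mature[:-1]
        extended = hp[mstart_local:mstart_local + len(p.mature) + 1]
        shifted = hp[mstart_local + 1:mstart_local + 1 + len(p.mature)]
        n_iso_valid = n_iso if (clean_insert_ok(trimmed) and clean_insert_ok(extended)) else 0
        n_core = n_mature - n_iso_valid
        emit(p.mature, n_core)
        tally_len(p.mature, n_core)
        countable = n_mature
        if n_iso_valid:
            emit(trimmed, n_iso_valid // 2)
            emit(extended, n_iso_valid - n_iso_valid // 2)
            tally_len(trimmed, n_iso_valid // 2)
            tally_len(extended, n_iso_valid - n_iso_valid // 2)
        if not clean_insert_ok(shifted):
            n_off = 0
        emit(shifted, n_off)
        tally_len(shifted, n_off)
        star = p.star
        if not clean_insert_ok(star):
            n_star = 0
        emit(star, n_star)
        tally_len(star, n_star)
        realization.mirna_counts[p.mirna_id] = countable
        clean_total += n_mature + n_off + n_star
        mappable += n_mature + n_off + n_star
    mirna_total = clean_total

    # --- structural-RNA fragments
    expected_total = max(1.0, mirna_total / cfg.frac_mirna)
    structural_feats = [f for f in truth.features
                        if f.cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat",
                                     "exon", "intron")]
    weights = np.array([f.end - f.start for f in structural_feats], dtype=float)
    weights /= weights.sum()
    n_struct = int(rng.poisson(cfg.frac_structural * expected_total))
    for _ in range(n_struct):
        for _try in range(20):
            f = structural_feats[int(rng.choice(len(structural_feats), p=weights))]
            length = _deg_length(rng)
            if f.end - f.start <= length:
                continue
            start = int(rng.integers(f.start, f.end - length))
            insert = truth.genome[f.chrom][start:start + length]
            if clean_insert_ok(insert):
                emit(insert, 1)
                tally_len(insert, 1)
                clean_total += 1
                mappable += 1
                break

    # --- degradation fragments at hotspot loci
    n_deg = int(rng.poisson(cfg.frac_degradation * expected_total))
    for _ in range(n_deg):
        for _try in range(20):
            chrom, pos = truth.hotspots[int(rng.integers(0, len(truth.hotspots)))]
            jitter = int(rng.integers(-5, 6))
            length = _deg_length(rng)
            start = max(0, pos + jitter)
            insert = truth.genome[chrom][start:start + length]
            if len(insert) == length and clean_insert_ok(insert):
                emit(insert, 1)
                tally_len(insert, 1)
                clean_total += 1
                mappable += 1
                break

    # --- unmappable clean reads
    from .annotate import GenomeIndex  # local import to avoid a cycle at module load
    n_unmap = int(rng.poisson(cfg.frac_unmappable * expected_total))
    if genome_index is None:
        genome_index = GenomeIndex(truth.genome)
    for _ in range(n_unmap):
        for _try in range(20):
            insert = _random_seq(rng, _deg_length(rng))
            if clean_insert_ok(insert) and not genome_index.find(insert):
                emit(insert, 1)
                tally_len(insert, 1)
                clean_total += 1
                break

    realization.clean_reads = clean_total
    realization.mappable_reads = mappable

    # --- contamination classes (fractions of high-quality reads)
    contam = cfg.contamination
    hq_expected = clean_total / max(1e-9, 1.0 - sum(
        v for k, v in contam.items() if k != "low_quality"))

    def contaminated(category: str, maker) -> None:
        n = int(rng.poisson(contam.get(category, 0.0) * hq_expected))
        made = 0
        guard = 0
        while made < n and guard < 50 * n + 50:
            guard += 1
            read = maker()
            if classify_and_trim(read, clean_cfg)[0] == category:
                lib.add(read, 1, q)
                made += 1
        realization.category_counts[category] = made

    contaminated("adapter3_null", lambda: _random_seq(rng, cfg.read_len))
    contaminated("insert_null", lambda: _wrap_read("", cfg))
    contaminated("adapter5_contaminant", lambda: _wrap_read(
        cfg.adapter5[:int(rng.integers(cfg.clean_config().contaminant_seed_len, 13))]
        + _random_seq(rng, 12), cfg))
    contaminated("shorter_than_min", lambda: _wrap_read(
        _random_seq(rng, int(rng.integers(10, cfg.clean_config().min_insert_len))), cfg))
    contaminated("polyA", lambda: _wrap_read("A" * int(rng.integers(18, 25)), cfg))

    # --- low-quality reads (mean Phred below the filter)
    n_low = int(rng.poisson(contam.get("low_quality", 0.0) * hq_expected))
    for _ in range(n_low):
        lib.add(_wrap_read(_random_seq(rng, 21), cfg), 1, float(cfg.low_quality))
    realization.category_counts["low_quality"] = n_low

    if path is not None:
        from .io_core import write_fastq
        write_fastq(lib, path)
    return lib, realization


# ---------------------------------------------------------------------------
# Degradome simulation
# ---------------------------------------------------------------------------

@dataclass
class DegradomeRealization:
    condition: str
    site_counts: dict[tuple[str, str, int], int]  # (mirna, transcript, pos0) -> tags
    background_tags: int
    unmappable_tags: int
    category_counts: dict[str, int]


def simulate_degradome(truth: TruthManifest, condition: str, seed: int,
                       path=None) -> tuple[Library, DegradomeRealization]:
    """Emit one condition's raw degradome library (optionally as FASTQ).

    For each active target (miRNA expressed in the condition) a tag pile-up
    of depth round(signal_to_noise x background rate) starts exactly at the
    cleavage site; background tag 5' ends are Poisson-uniform over
    transcript positions. Tag lengths are 20–21 nt.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.cfg
    rng = np.random.default_rng([int(seed), 11 + CONDITIONS.index(condition)])
    clean_cfg = cfg.clean_config()
    lib = Library(name=f"degradome_{condition}", quality_means={})
    q = float(cfg.base_quality)
    real = DegradomeRealization(condition, {}, 0, 0, {})

    def emit_tag(transcript: str, pos: int) -> bool:
        length = int(rng.choice(cfg.deg_tag_lens))
        tag = transcript[pos:pos + length]
        if len(tag) < min(cfg.deg_tag_lens):
            return False
        if not _insert_survives(tag, cfg, clean_cfg):
            return False
        lib.add(_wrap_read(tag, cfg), 1, q)
        return True

    # --- signal pile-ups
    site_depth = int(round(cfg.signal_to_noise * cfg.background_per_position))
    for t in truth.targets:
        if truth.expression[t.mirna_id][f"mean_{condition}"] <= 0:
            continue
        made = 0
        for _ in range(site_depth):
            if emit_tag(truth.transcripts[t.transcript_id], t.cleavage_pos):
                made += 1
        if made:
            real.site_counts[(t.mirna_id, t.transcript_id, t.cleavage_pos)] = made

    # --- background
    max_tag = max(cfg.deg_tag_lens)
    signal_total = sum(real.site_counts.values())
    for tid in sorted(truth.transcripts):
        seq = truth.transcripts[tid]
        n_pos = len(seq) - max_tag
        counts = rng.poisson(cfg.background_per_position, n_pos)
        for pos in np.nonzero(counts)[0]:
            for _ in range(int(counts[pos])):
                if emit_tag(seq, int(pos)):
                    real.background_tags += 1

    # --- unmappable tags
    mapped_total = signal_total + real.background_tags
    n_unmap = int(rng.poisson(cfg.deg_frac_unmappable / (1 - cfg.deg_frac_unmappable)
                              * mapped_total))
    transcript_blob = " ".join(truth.transcripts.values())
    made = 0
    guard = 0
    while made < n_unmap and guard < 50 * n_unmap + 50:
        guard += 1
        tag = _random_seq(rng, int(rng.choice(cfg.deg_tag_lens)))
        if tag[:20] in transcript_blob:
            continue
        if not _insert_survives(tag, cfg, clean_cfg):
            continue
        lib.add(_wrap_read(tag, cfg), 1, q)
        made += 1
    real.unmappable_tags = made

    # --- contamination (degradome block: same classes, polyA typically absent)
    contam = cfg.deg_contamination
    hq_expected = (mapped_total + made) / max(1e-9, 1.0 - sum(
        v for k, v in contam.items() if k != "low_quality"))

    def contaminated(category: str, maker) -> None:
        n = int(rng.poisson(contam.get(category, 0.0) * hq_expected))
        done = 0
        guard = 0
        while done < n and guard < 50 * n + 50:
            guard += 1
            read = maker()
            if classify_and_trim(read, clean_cfg)[0] == category:
                lib.add(read, 1, q)
                done += 1
        real.category_counts[category] = done

    contaminated("adapter3_null", lambda: _random_seq(rng, cfg.read_len))
    contaminated("insert_null", lambda: _wrap_read("", cfg))
    contaminated("adapter5_contaminant", lambda: _wrap_read(
        cfg.adapter5[:10] + _random_seq(rng, 12), cfg))
    contaminated("shorter_than_min", lambda: _wrap_read(_random_seq(rng, 12), cfg))
    n_low = int(rng.poisson(contam.get("low_quality", 0.0) * hq_expected))
    for _ in range(n_low):
        lib.add(_wrap_read(_random_seq(rng, 20), cfg), 1, float(cfg.low_quality))
    real.category_counts["low_quality"] = n_low

    if path is not None:
        from .io_core import write_fastq
        write_fastq(lib, path)
    return lib, real
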