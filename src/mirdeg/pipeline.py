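"""End-to-end orchestration from one configuration, report emission, and
small phenotype arithmetic.

``run_all`` executes simulate -> preprocess -> annotate -> discover ->
targets -> diffexpr for both conditions and writes the report tables
(accounting, mapping, classification, first-nucleotide bias, targets,
expression calls and the selection summary) as TSVs. Reruns with the same
seed produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotate as ann
from . import degradome as deg
from . import expression as expr
from . import mirna_discovery as disc
from . import synthetic_data as synth
from .io_core import (AnnotationDB, Library, logger, to_dna, write_fasta,
                      write_features)
from .preprocess import CleanConfig, percentage_table, run_preprocess

CONDITIONS = synth.CONDITIONS


def flag_leaf_area(length_cm: float, width_cm: float) -> float:
    """Flag leaf area (cm^2) = leaf length x maximum leaf width x 0.75,
    reported to one decimal."""
    if length_cm < 0 or width_cm < 0:
        raise ValueError("leaf dimensions must be nonnegative")
    return round(length_cm * width_cm * 0.75, 1)


def summarize_selection(rows: pd.DataFrame) -> pd.DataFrame:
    """Selection-summary totals for specifically/differentially expressed
    miRNAs.

    ``rows`` columns: profile (specific/up_regulated/down_regulated),
    strain, category (known/new), srna_count, degradome_count. Appends a
    Total row with per-column sums; the degradome-evidenced grand total is
    the headline selection count.
    """
    required = {"profile", "category", "srna_count", "degradome_count"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = rows.copy()
    total = {
        "profile": "total", "category": "",
        "srna_count": int(out["srna_count"].sum()),
        "degradome_count": int(out["degradome_count"].sum()),
    }
    if "strain" in out.columns:
        total["strain"] = ""
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


@dataclass
class RunConfig:
    """One-stop configuration for a full synthetic-study run."""

    out_dir: str
    seed: int = 1
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    de: expr.DEConfig = field(default_factory=expr.DEConfig)
    target: deg.TargetConfig = field(default_factory=deg.TargetConfig)
    log_level: str = "INFO"

    def clean_config(self) -> CleanConfig:
        return self.sim.clean_config()


@dataclass
class PipelineResult:
    truth: synth.TruthManifest
    clean: dict[str, Library]
    reports: dict[str, object]
    category_tables: dict[str, ann.CategoryTable]
    mapping: dict[str, ann.MappingSummary]
    candidates: list[disc.MiRNACandidate]
    targets: dict[str, list[deg.TargetPair]]
    expression: pd.DataFrame
    selection: pd.DataFrame
    out_dir: str


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def discover_candidates(clean_by_cond: dict[str, Library],
                        db: AnnotationDB, cfg: synth.SimConfig,
                        ) -> tuple[list[disc.MiRNACandidate], dict[str, str]]:
    """Novel-miRNA discovery on the union of both clean libraries.

    Returns accepted candidates (with per-condition counts filled from the
    exact mature sequence) and the per-read category map of the union
    library.
    """
    union = Library(name="union")
    for lib in clean_by_cond.values():
        for seq, count in lib.records.items():
            union.add(seq, count)
    hits = ann.map_exact(union, db.genome)
    per_read = ann.classify_per_read(hits, db)
    unann_hits = {seq: h for seq, h in hits.items()
                  if h and per_read.get(seq) == "unannotated"}
    clusters = disc.extract_clusters(unann_hits, union,
                                     merge_gap=cfg.discovery.merge_gap)
    candidates = []
    for cluster in clusters:
        cand, _reason = disc.evaluate_precursor(cluster, db.genome, cfg.discovery)
        if cand is None:
            continue
        # accepted candidates must not overlap annotated structural RNA
        g0, g1 = cand.mature_genomic_span
        if db.overlapping(cand.chrom, g0, g1):
            continue
        for cond, lib in clean_by_cond.items():
            cand.counts[cond] = lib.records.get(cand.mature_dna, 0)
        cand.star_observed = disc.star_observed(cand.star, union)
        candidates.append(cand)
    candidates.sort(key=lambda c: (c.chrom, c.start, c.strand))
    for i, cand in enumerate(candidates):
        cand.counts["id"] = f"candidate_{i + 1:03d}"
    return candidates, per_read


def candidate_frame(candidates: list[disc.MiRNACandidate]) -> pd.DataFrame:
    rows = []
    for cand in candidates:
        rows.append({
            "id": cand.counts.get("id", ""),
            "chrom": cand.chrom, "start": cand.start + 1, "end": cand.end,
            "strand": cand.strand, "arm": cand.arm,
            "mature": cand.mature, "star": cand.star or "",
            "specificity": round(cand.specificity, 4),
            "count_wild": cand.counts.get("wild", 0),
            "count_mutant": cand.counts.get("mutant", 0),
            "star_observed": cand.star_observed,
            "known_match": cand.known_match,
        })
    return pd.DataFrame(rows)


def target_frame(pairs: list[deg.TargetPair]) -> pd.DataFrame:
    rows = [{
        "mirna": p.mirna_id, "transcript": p.transcript_id,
        "cleavage_pos": p.cleavage_pos, "tags": p.tag_count,
        "category": p.category, "score": p.score, "library": p.library,
        "alignment": "".join({"match": "|", "GU": "o",
                              "mismatch": ".", "gap": "-"}[s]
                             for s in p.alignment.states),
    } for p in pairs]
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> PipelineResult:
    """Execute every stage on a synthetic study and write the report bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = config.out_dir
    clean_cfg = config.clean_config()

    logger.info("stage simulate: building ground truth (seed %d)", config.seed)
    truth = synth.build_truth(config.sim, config.seed)
    write_fasta(truth.genome, os.path.join(out, "genome.fa"))
    write_fasta(truth.transcripts, os.path.join(out, "transcripts.fa"))
    write_fasta(truth.known_mature_db(), os.path.join(out, "mature_known.fa"))
    write_fasta(truth.known_precursor_db(), os.path.join(out, "precursors_known.fa"))
    write_features(truth.features, os.path.join(out, "features.tsv"))
    truth.to_json(os.path.join(out, "truth.json"))
    db = AnnotationDB(genome=truth.genome, features=truth.features)

    clean: dict[str, Library] = {}
    reports: dict[str, object] = {}
    mapping: dict[str, ann.MappingSummary] = {}
    category_tables: dict[str, ann.CategoryTable] = {}
    deg_clean: dict[str, Library] = {}

    for cond in CONDITIONS:
        logger.info("stage preprocess: %s small-RNA library", cond)
        raw, _real = synth.simulate_srna(
            truth, cond, config.seed, path=os.path.join(out, f"srna_{cond}.fastq"))
        lib, report = run_preprocess(raw, clean_cfg)
        clean[cond] = lib
        reports[f"srna_{cond}"] = report
        _write_tsv(percentage_table(report), os.path.join(out, f"table2_srna_{cond}.tsv"))

        raw_deg, _dreal = synth.simulate_degradome(
            truth, cond, config.seed, path=os.path.join(out, f"degradome_{cond}.fastq"))
        dlib, dreport = run_preprocess(raw_deg, clean_cfg)
        deg_clean[cond] = dlib
        reports[f"degradome_{cond}"] = dreport
        _write_tsv(percentage_table(dreport),
                   os.path.join(out, f"table2_degradome_{cond}.tsv"))

    index = ann.GenomeIndex(truth.genome)
    for cond in CONDITIONS:
        logger.info("stage annotate: %s", cond)
        hits = ann.map_exact(clean[cond], truth.genome, index=index)
        mapping[f"srna_{cond}"] = ann.mapping_summary(hits, clean[cond])
        table = ann.classify_reads(hits, db, clean[cond])
        category_tables[cond] = table
        _write_tsv(table.to_frame(), os.path.join(out, f"table4_{cond}.tsv"))
        hist = ann.length_histogram(clean[cond])
        hist.rename("count").to_frame().reset_index(names="length").to_csv(
            os.path.join(out, f"length_hist_{cond}.tsv"), sep="\t", index=False)
        bias = ann.first_nt_table(clean[cond])
        bias.reset_index().to_csv(os.path.join(out, f"first_nt_{cond}.tsv"),
                                  sep="\t", index=False)
        # degradome mapping summary is computed against the transcript space
        tindex = ann.GenomeIndex(truth.transcripts, seed_len=18)
        dhits = ann.map_exact(deg_clean[cond], truth.transcripts, index=tindex)
        mapping[f"degradome_{cond}"] = ann.mapping_summary(dhits, deg_clean[cond])

    map_rows = [{"library": name, "unique_total": m.unique_total,
                 "unique_matched": m.unique_matched, "unique_pct": m.unique_pct,
                 "total_reads": m.total_reads, "total_matched": m.total_matched,
                 "total_pct": m.total_pct} for name, m in sorted(mapping.items())]
    _write_tsv(pd.DataFrame(map_rows), os.path.join(out, "table3.tsv"))

    logger.info("stage discover: novel miRNA candidates")
    candidates, _per_read = discover_candidates(clean, db, config.sim)
    known_db = truth.known_mature_db()
    for cand in candidates:
        counts, _assigned = disc.count_known(
            Library(records={cand.mature_dna: 1}), known_db)
        cand.known_match = any(v for v in counts.values())
    _write_tsv(candidate_frame(candidates), os.path.join(out, "candidates.tsv"))
    cand_lib = {cond: Library(name=cond) for cond in CONDITIONS}
    for cand in candidates:
        for cond in CONDITIONS:
            if cand.counts.get(cond, 0):
                cand_lib[cond].add(cand.mature_dna, cand.counts[cond])
    for cond in CONDITIONS:
        bias = ann.first_nt_table(cand_lib[cond])
        bias.reset_index().to_csv(os.path.join(out, f"table6_{cond}.tsv"),
                                  sep="\t", index=False)

    logger.info("stage targets: degradome pairing")
    mirnas = dict(known_db)
    for cand in candidates:
        mirnas[cand.counts["id"]] = cand.mature_dna
    targets: dict[str, list[deg.TargetPair]] = {}
    all_pairs: list[deg.TargetPair] = []
    for cond in CONDITIONS:
        tplots, _unmapped = deg.map_tags(deg_clean[cond], truth.transcripts)
        pairs = deg.find_targets(mirnas, tplots, truth.transcripts,
                                 config.target, library=cond)
        targets[cond] = pairs
        all_pairs.extend(pairs)
        _write_tsv(target_frame(pairs), os.path.join(out, f"targets_{cond}.tsv"))
    t7 = [{"sample": cond,
           "mirnas": len({p.mirna_id for p in targets[cond]}),
           "targets": len({(p.mirna_id, p.transcript_id) for p in targets[cond]})}
          for cond in CONDITIONS]
    _write_tsv(pd.DataFrame(t7), os.path.join(out, "table7.tsv"))

    logger.info("stage diffexpr")
    counts = {cond: dict(disc.count_known(clean[cond], known_db)[0])
              for cond in CONDITIONS}
    for cand in candidates:
        for cond in CONDITIONS:
            counts[cond][cand.counts["id"]] = cand.counts.get(cond, 0)
    table = expr.build_expression_table(
        counts["wild"], counts["mutant"],
        clean["wild"].total_reads, clean["mutant"].total_reads, config.de)
    evidenced = {p.mirna_id for p in all_pairs}
    table["degradome_evidenced"] = table["mirna_id"].isin(evidenced)
    _write_tsv(table, os.path.join(out, "expression.tsv"))

    selection = _selection_rows(table)
    selection = summarize_selection(selection)
    _write_tsv(selection, os.path.join(out, "table8.tsv"))

    return PipelineResult(
        truth=truth, clean=clean, reports=reports,
        category_tables=category_tables, mapping=mapping,
        candidates=candidates, targets=targets, expression=table,
        selection=selection, out_dir=out)


def _selection_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Selection-summary rows (known vs new, by sRNA and degradome evidence)."""
    is_new = table["mirna_id"].str.startswith("candidate")
    rows = []
    for profile, mask in (
            ("specific_mutant", table["call"] == "specific_mutant"),
            ("specific_wild", table["call"] == "specific_wild"),
            ("up_regulated", table["call"] == "up_in_mutant"),
            ("down_regulated", table["call"] == "down_in_mutant")):
        strain = profile.split("_", 1)[1] if profile.startswith("specific") else ""
        for category, cmask in (("known", ~is_new), ("new", is_new)):
            sub = table[mask & cmask]
            rows.append({"profile": profile, "strain": strain, "category": category,
                         "srna_count": int(len(sub)),
                         "degradome_count": int(sub["degradome_evidenced"].sum())})
    return pd.DataFrame(rows)
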