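"""End-to-end orchestration: stage functions and the full pipeline.

The in-memory core functions (``compute_distances`` ... ``consolidate``)
carry the science; the disk-facing stage functions wrap them with artifact
reading/writing so each CLI subcommand can resume from the previous
stage's outputs. A master seed derives per-run seeds as seed + run_id, so
adding runs never reshuffles earlier ones; identical seed and inputs give
byte-identical TSV/BED artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import (
    PositionHistogram,
    Peak,
    accumulate_histogram,
    call_peaks,
    peaks_to_bed,
    project_run,
)
from .distances import (
    DistanceMatrix,
    StratificationConfig,
    Subgroups,
    matrix_from_sequences,
    matrix_from_tree,
    stratify,
)
from .iodata import (
    DatabaseMotif,
    MotifDatabase,
    PromoterRecord,
    find_target,
    read_fasta,
    read_meme_motifs,
    read_newick,
    write_bedgraph,
    write_bigwig,
    write_meme_motifs,
)
from .motifcompare import (
    MatchScore,
    aggregate_peak_stats,
    build_consolidated_alignment,
    compare_pwms,
    motifs_overlapping_peak,
    peak_stats_to_frame,
    presence_map,
    score_consolidated,
)
from .motifdiscovery import (
    ConsensusConfig,
    GibbsConfig,
    Instance,
    Motif,
    build_motif,
    consensus_finder,
    gibbs_finder,
    vote_combine,
)
from .subsampler import SamplerConfig, SubsetPlan, generate_subsets

logger = logging.getLogger(__name__)

STAGES = ["distances", "subsets", "discover", "aggregate", "compare", "consolidate"]


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths and the master seed."""

    fasta: str = ""
    target_id: str = ""
    tree: str | None = None
    motif_db: str | None = None
    outdir: str = "phylofoot_out"
    seed: int = 0

    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    widths: tuple[int, ...] = (8, 10, 12, 14, 16)
    gibbs_max_iters: int = 500
    gibbs_patience: int = 50
    gibbs_restarts: int = 5
    consensus_max_mismatch: int = 1
    quorum: int = 2
    overlap_frac: float = 0.5
    pseudocount: float = 0.5

    min_ortholog_support: int = 6
    min_support_frac: float = 0.25
    min_peak_width: int = 6
    merge_gap: int = 5

    compare_min_overlap: int = 5
    compare_shuffles: int = 1000
    alpha: float = 0.05

    chrom: str = "promoter"
    chrom_offset: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        strat = StratificationConfig(**raw.pop("stratification", {}))
        sampler_raw = raw.pop("sampler", {})
        if "quota" in sampler_raw:
            sampler_raw["quota"] = tuple(sampler_raw["quota"])
        cfg = cls(stratification=strat, sampler=SamplerConfig(**sampler_raw), **raw)
        cfg.widths = tuple(cfg.widths)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["widths"] = list(self.widths)
        d["sampler"]["quota"] = list(self.sampler.quota)
        return d


# ---------------------------------------------------------------------------
# In-memory core


def compute_distances(
    records: Sequence[PromoterRecord], tree=None
) -> DistanceMatrix:
    """Patristic distances when a tree is supplied, else alignment fallback."""
    if tree is not None:
        return matrix_from_tree(tree, [r.id for r in records])
    return matrix_from_sequences(records)


def plan_subsets(
    dm: DistanceMatrix,
    target_id: str,
    strat_cfg: StratificationConfig,
    sampler_cfg: SamplerConfig,
) -> tuple[Subgroups, SubsetPlan]:
    groups = stratify(dm, target_id, strat_cfg)
    plan = generate_subsets(groups, dm, sampler_cfg)
    return groups, plan


def discover_run(
    records: Sequence[PromoterRecord],
    run_seed: int,
    cfg: PipelineConfig,
) -> list[Motif]:
    """Run every finder at every width on one subset and vote-combine."""
    sequences = {r.id: r.sequence for r in records}
    results = []
    for width in cfg.widths:
        gcfg = GibbsConfig(
            max_iters=cfg.gibbs_max_iters,
            patience=cfg.gibbs_patience,
            restarts=cfg.gibbs_restarts,
            pseudocount=cfg.pseudocount,
            seed=(run_seed * 131 + width) % (2**31),
        )
        results.append(gibbs_finder(records, width, gcfg))
        if width <= 12:  # enumeration guard of the consensus finder
            results.append(
                consensus_finder(
                    records,
                    width,
                    max_mismatch=cfg.consensus_max_mismatch,
                    cfg=ConsensusConfig(pseudocount=cfg.pseudocount),
                )
            )
    return vote_combine(
        results,
        sequences,
        quorum=cfg.quorum,
        overlap_frac=cfg.overlap_frac,
        pseudocount=cfg.pseudocount,
    )


def discover_all(
    records: Sequence[PromoterRecord],
    plan: SubsetPlan,
    cfg: PipelineConfig,
) -> list[list[Motif]]:
    by_id = {r.id: r for r in records}
    per_run: list[list[Motif]] = []
    for spec in plan.subsets:
        subset = [by_id[i] for i in spec.all_ids]
        motifs = discover_run(subset, cfg.seed + spec.run_id, cfg)
        logger.info("run %d: %d combined motifs", spec.run_id, len(motifs))
        per_run.append(motifs)
    return per_run


def aggregate(
    per_run_motifs: Sequence[Sequence[Motif]],
    target: PromoterRecord,
    cfg: PipelineConfig,
) -> tuple[PositionHistogram, list[Peak]]:
    per_run_intervals = [
        project_run(motifs, target.id, cfg.min_ortholog_support)
        for motifs in per_run_motifs
    ]
    hist = accumulate_histogram(
        per_run_intervals, target.id, len(target.sequence), len(per_run_motifs)
    )
    peaks = call_peaks(
        hist, cfg.min_support_frac, cfg.min_peak_width, cfg.merge_gap
    )
    logger.info("histogram over %d runs; %d peaks called", hist.n_runs, len(peaks))
    return hist, peaks


def compare_runs(
    per_run_motifs: Sequence[Sequence[Motif]],
    peaks: Sequence[Peak],
    db: MotifDatabase,
    target_id: str,
    cfg: PipelineConfig,
):
    """Per run and peak, score the peak-overlapping motifs against the db."""
    per_run_peak_matches: list[dict[int, list[MatchScore]]] = []
    for run_id, motifs in enumerate(per_run_motifs):
        run_map: dict[int, list[MatchScore]] = {}
        for peak in peaks:
            hits = motifs_overlapping_peak(motifs, peak, target_id)
            matches: list[MatchScore] = []
            for qi, (motif, _t) in enumerate(hits):
                matches.extend(
                    compare_pwms(
                        motif,
                        db,
                        min_overlap=cfg.compare_min_overlap,
                        n_shuffles=cfg.compare_shuffles,
                        seed=(cfg.seed + run_id) % (2**31),
                        query_name=f"run{run_id}_peak{peak.peak_id}_m{qi}",
                    )
                )
            if matches:
                run_map[peak.peak_id] = matches
        per_run_peak_matches.append(run_map)
    stats = aggregate_peak_stats(per_run_peak_matches, peaks, alpha=cfg.alpha)
    return per_run_peak_matches, stats


def consolidate(
    peaks: Sequence[Peak],
    per_run_motifs: Sequence[Sequence[Motif]],
    records: Sequence[PromoterRecord],
    db: MotifDatabase | None,
    cfg: PipelineConfig,
    sampled_ids: set[str] | None = None,
):
    alignments, scores, presences = [], {}, []
    for peak in peaks:
        try:
            aln = build_consolidated_alignment(
                peak, per_run_motifs, records, pseudocount=cfg.pseudocount
            )
        except ValueError:
            continue
        alignments.append(aln)
        if db is not None and len(aln.rows) >= 2:
            scores[peak.peak_id] = score_consolidated(
                aln,
                db,
                min_overlap=cfg.compare_min_overlap,
                n_shuffles=cfg.compare_shuffles,
                seed=cfg.seed,
            )
        presences.append(presence_map(peak, per_run_motifs, records, sampled_ids))
    return alignments, scores, presences


# ---------------------------------------------------------------------------
# Disk-facing stages


def _load_records(cfg: PipelineConfig) -> list[PromoterRecord]:
    records = read_fasta(cfg.fasta)
    if not cfg.target_id:
        raise ValueError("config must name the target promoter (target_id)")
    found = False
    for r in records:
        r.is_target = r.id == cfg.target_id
        found = found or r.is_target
    if not found:
        raise ValueError(f"target '{cfg.target_id}' not present in {cfg.fasta}")
    return records


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_distances(cfg: PipelineConfig) -> DistanceMatrix:
    records = _load_records(cfg)
    tree = read_newick(cfg.tree) if cfg.tree else None
    dm = compute_distances(records, tree)
    dm.to_tsv(_outdir(cfg) / "distances.tsv")
    return dm


def stage_subsets(cfg: PipelineConfig) -> SubsetPlan:
    out = _outdir(cfg)
    dm = DistanceMatrix.from_tsv(out / "distances.tsv")
    sampler = dataclasses.replace(cfg.sampler, seed=cfg.seed)
    groups, plan = plan_subsets(dm, cfg.target_id, cfg.stratification, sampler)
    plan.to_tsv(out / "subsets.tsv", groups)
    return plan


def _instances_frame(per_run_motifs: Sequence[Sequence[Motif]]) -> pd.DataFrame:
    rows = []
    for run_id, motifs in enumerate(per_run_motifs):
        for mi, motif in enumerate(motifs):
            for inst in motif.instances:
                rows.append(
                    {
                        "run_id": run_id,
                        "motif_idx": mi,
                        "finder": "vote",
                        "promoter_id": inst.promoter_id,
                        "start": inst.start,
                        "strand": inst.strand,
                        "width": motif.width,
                    }
                )
    columns = ["run_id", "motif_idx", "finder", "promoter_id", "start", "strand", "width"]
    return pd.DataFrame(rows, columns=columns)


def _rebuild_motifs(
    instances: pd.DataFrame, records: Sequence[PromoterRecord], n_runs: int,
    pseudocount: float,
) -> list[list[Motif]]:
    sequences = {r.id: r.sequence for r in records}
    per_run: list[list[Motif]] = [[] for _ in range(n_runs)]
    for (run_id, _mi), grp in instances.groupby(["run_id", "motif_idx"], sort=True):
        width = int(grp["width"].iloc[0])
        insts = [
            Instance(str(row.promoter_id), int(row.start), str(row.strand))
            for row in grp.itertuples()
        ]
        per_run[int(run_id)].append(
            build_motif(insts, sequences, width, pseudocount)
        )
    return per_run


def stage_discover(cfg: PipelineConfig) -> list[list[Motif]]:
    out = _outdir(cfg)
    records = _load_records(cfg)
    plan = SubsetPlan.from_tsv(out / "subsets.tsv")
    per_run = discover_all(records, plan, cfg)
    _instances_frame(per_run).to_csv(out / "instances.tsv", sep="\t", index=False)
    runs_dir = out / "runs"
    runs_dir.mkdir(exist_ok=True)
    for run_id, motifs in enumerate(per_run):
        db = MotifDatabase(
            motifs=[
                DatabaseMotif(
                    name=f"run{run_id}_motif{mi}", pwm=m.pwm,
                    nsites=len(m.instances),
                )
                for mi, m in enumerate(motifs)
            ]
        )
        write_meme_motifs(db, runs_dir / f"run_{run_id:03d}.meme")
    return per_run


def _load_per_run_motifs(cfg: PipelineConfig, records) -> list[list[Motif]]:
    out = Path(cfg.outdir)
    plan = SubsetPlan.from_tsv(out / "subsets.tsv")
    instances = pd.read_csv(
        out / "instances.tsv", sep="\t", dtype={"promoter_id": str}
    )
    return _rebuild_motifs(instances, records, plan.N, cfg.pseudocount)


def stage_aggregate(cfg: PipelineConfig) -> tuple[PositionHistogram, list[Peak]]:
    out = _outdir(cfg)
    records = _load_records(cfg)
    per_run = _load_per_run_motifs(cfg, records)
    hist, peaks = aggregate(per_run, find_target(records), cfg)
    write_bedgraph(hist, out / "histogram.bedgraph", cfg.chrom, cfg.chrom_offset)
    write_bigwig(hist, out / "histogram.bw", cfg.chrom, cfg.chrom_offset)
    peaks_to_bed(peaks, out / "peaks.bed", cfg.chrom, cfg.chrom_offset)
    return hist, peaks


def _load_peaks(cfg: PipelineConfig) -> list[Peak]:
    peaks = []
    for line in (Path(cfg.outdir) / "peaks.bed").read_text().splitlines():
        chrom, start, end, name, score, _strand = line.split("\t")
        peaks.append(
            Peak(
                peak_id=int(name.split("_")[1]),
                start=int(start) - cfg.chrom_offset,
                end=int(end) - cfg.chrom_offset,
                height=0,
                support_frac=int(score) / 1000,
            )
        )
    return peaks


def stage_compare(cfg: PipelineConfig):
    out = _outdir(cfg)
    if not cfg.motif_db:
        raise ValueError("comparison requested but no motif database configured")
    db = read_meme_motifs(cfg.motif_db)
    records = _load_records(cfg)
    per_run = _load_per_run_motifs(cfg, records)
    peaks = _load_peaks(cfg)
    per_run_matches, stats = compare_runs(per_run, peaks, db, cfg.target_id, cfg)
    match_rows = []
    for run_id, run_map in enumerate(per_run_matches):
        for peak_id, matches in sorted(run_map.items()):
            for m in matches:
                match_rows.append(
                    {
                        "run_id": run_id,
                        "peak_id": peak_id,
                        "query": m.query_name,
                        "tf": m.db_motif_name,
                        "offset": m.offset,
                        "orientation": m.orientation,
                        "score": m.score,
                        "p_value": m.p_value,
                        "e_value": m.e_value,
                    }
                )
    columns = ["run_id", "peak_id", "query", "tf", "offset", "orientation",
               "score", "p_value", "e_value"]
    pd.DataFrame(match_rows, columns=columns).to_csv(
        out / "matches.tsv", sep="\t", index=False, float_format="%.6g"
    )
    peak_stats_to_frame(stats).to_csv(
        out / "peak_stats.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return per_run_matches, stats


def stage_consolidate(cfg: PipelineConfig):
    out = _outdir(cfg)
    records = _load_records(cfg)
    per_run = _load_per_run_motifs(cfg, records)
    peaks = _load_peaks(cfg)
    db = read_meme_motifs(cfg.motif_db) if cfg.motif_db else None
    plan = SubsetPlan.from_tsv(out / "subsets.tsv")
    sampled = {pid for spec in plan.subsets for pid in spec.member_ids}
    alignments, scores, presences = consolidate(
        peaks, per_run, records, db, cfg, sampled_ids=sampled
    )
    for aln in alignments:
        aln.to_fasta(out / f"consolidated_peak_{aln.peak_id}.fasta")
        write_meme_motifs(
            MotifDatabase(
                motifs=[
                    DatabaseMotif(
                        name=f"peak_{aln.peak_id}_consolidated",
                        pwm=aln.pwm,
                        nsites=len(aln.rows),
                    )
                ]
            ),
            out / f"consolidated_peak_{aln.peak_id}.meme",
        )
    rows = []
    for peak_id, matches in sorted(scores.items()):
        for m in matches:
            rows.append(
                {
                    "peak_id": peak_id,
                    "tf": m.db_motif_name,
                    "offset": m.offset,
                    "orientation": m.orientation,
                    "score": m.score,
                    "p_value": m.p_value,
                    "e_value": m.e_value,
                }
            )
    columns = ["peak_id", "tf", "offset", "orientation", "score", "p_value", "e_value"]
    pd.DataFrame(rows, columns=columns).to_csv(
        out / "consolidated_matches.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if presences:
        pd.concat([p.to_frame() for p in presences]).to_csv(
            out / "presence.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["taxon", "peak_id", "present", "sampled"]).to_csv(
            out / "presence.tsv", sep="\t", index=False
        )
    return alignments, scores, presences


def run_pipeline(cfg: PipelineConfig, stop_after: str | None = None) -> Path:
    """Run all stages in order, writing artifacts and a run manifest.

    Fails fast when comparison is configured but the database is missing,
    before any discovery work starts.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage '{stop_after}'; stages are {STAGES}")
    if cfg.motif_db and not Path(cfg.motif_db).exists():
        raise FileNotFoundError(
            f"motif database '{cfg.motif_db}' not found (checked before discovery)"
        )
    out = _outdir(cfg)
    manifest = {"config": cfg.to_dict(), "seed": cfg.seed, "version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage_funcs = {
        "distances": stage_distances,
        "subsets": stage_subsets,
        "discover": stage_discover,
        "aggregate": stage_aggregate,
        "compare": stage_compare,
        "consolidate": stage_consolidate,
    }
    for stage in STAGES:
        if stage == "compare" and not cfg.motif_db:
            logger.info("no motif database configured; skipping comparison")
            continue
        logger.info("stage: %s", stage)
        try:
            stage_funcs[stage](cfg)
        except Exception:
            logger.error("pipeline failed in stage '%s'", stage)
            raise
        if stage == stop_after:
            break
    return out
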