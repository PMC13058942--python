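"""Motif-to-database comparison and multi-run match statistics.

Discovered PWMs are compared to a known-TFBS database by ungapped
alignment of columns: column similarity is the Pearson correlation of the
two 4-vectors, an alignment's score is the summed similarity over the
overlap normalized by query width (query columns left unaligned count as
zero similarity, so short overlaps cannot outscore full-width agreement),
and the best offset/orientation wins. Significance is empirical:
the same scan is repeated against column-shuffled versions of the database
motif and the p-value is the (add-one corrected) fraction of shuffles
scoring at least as well; the E-value is the p-value times the database
size, the expected number of equally good matches by chance.

Across pipeline runs the per-peak match lists are reduced to E-value
summaries (median, quartiles, significant fraction at the 5% threshold)
and the top-candidate frequency: the fraction of runs in which a factor
was the best match for a peak. Per-peak consolidated alignments stack, at
peak width, the conserved segment from every promoter in which a similar
motif was ever detected; the presence map projects that onto taxa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import Peak
from .iodata import (
    DatabaseMotif,
    MotifDatabase,
    PromoterRecord,
    find_target,
    reverse_complement,
)
from .motifdiscovery import Motif, build_motif, Instance


@dataclass
class MatchScore:
    query_name: str
    db_motif_name: str
    offset: int  # db start relative to query start, in query coordinates
    orientation: str  # "+" or "-"
    score: float  # summed column Pearson correlation over overlap / query width
    p_value: float
    e_value: float


def _standardize_columns(pwm: np.ndarray) -> np.ndarray:
    """Center/normalize each 4-vector column; zero-variance columns -> 0.

    Zero columns make the Pearson correlation with anything 0, which keeps
    uniform (e.g. all-N padded) columns well-defined.
    """
    x = np.asarray(pwm, float) - np.asarray(pwm, float).mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x, norms, out=out, where=norms > 1e-12)
    return out


def _offsets(wq: int, wd: int, min_overlap: int):
    """Yield (offset, query_idx, db_idx) for every overlap >= min_overlap."""
    for off in range(-(wd - min_overlap), wq - min_overlap + 1):
        lo = max(0, off)
        hi = min(wq, off + wd)
        if hi - lo < min_overlap:
            continue
        qi = np.arange(lo, hi)
        yield off, qi, qi - off


def compare_pwms(
    query: Motif | np.ndarray,
    db: MotifDatabase,
    min_overlap: int = 5,
    n_shuffles: int = 1000,
    seed: int = 0,
    query_name: str = "query",
) -> list[MatchScore]:
    """Best ungapped alignment of the query against each database motif.

    Scans every offset with overlap >= ``min_overlap`` in both orientations;
    the empirical null rescans the query against ``n_shuffles``
    column-shuffled copies of each database motif, so p-values carry the
    +1/(K+1) correction and E-values are p times the database size.
    """
    if len(db) == 0:
        raise ValueError("empty motif database")
    qpwm = query.pwm if isinstance(query, Motif) else np.asarray(query, float)
    wq = qpwm.shape[0]
    if wq < min_overlap:
        raise ValueError(f"query width {wq} below min_overlap {min_overlap}")
    rng = np.random.default_rng(seed)
    qn = _standardize_columns(qpwm)

    matches: list[MatchScore] = []
    for dbm in db:
        wd = dbm.width
        dn = _standardize_columns(dbm.pwm)
        # corr of query col q with db col d, and with the complement of db
        # col d (complementing a 4-vector over ACGT reverses its entries)
        c_plus = qn @ dn.T
        c_comp = qn @ dn[:, ::-1].T

        offsets = list(_offsets(wq, wd, min_overlap))
        if not offsets:
            continue
        best = (-np.inf, 0, "+")
        for off, qi, di in offsets:
            s_plus = float(c_plus[qi, di].sum()) / wq
            # '-' orientation aligns the query to the reverse complement of
            # the db motif: its column j is the complement of db column wd-1-j
            s_minus = float(c_comp[qi, wd - 1 - di].sum()) / wq
            if s_plus > best[0]:
                best = (s_plus, off, "+")
            if s_minus > best[0]:
                best = (s_minus, off, "-")
        obs_score, obs_off, obs_orient = best

        perms = np.argsort(rng.random((n_shuffles, wd)), axis=1)
        null_best = np.full(n_shuffles, -np.inf)
        for off, qi, di in offsets:
            plus_vals = c_plus[qi[:, None], perms[:, di].T].sum(axis=0) / wq
            minus_vals = c_comp[qi[:, None], perms[:, wd - 1 - di].T].sum(axis=0) / wq
            np.maximum(null_best, plus_vals, out=null_best)
            np.maximum(null_best, minus_vals, out=null_best)
        p = (1 + int((null_best >= obs_score - 1e-12).sum())) / (n_shuffles + 1)
        matches.append(
            MatchScore(
                query_name=query_name,
                db_motif_name=dbm.name,
                offset=obs_off,
                orientation=obs_orient,
                score=obs_score,
                p_value=p,
                e_value=p * len(db),
            )
        )
    return matches


# ---------------------------------------------------------------------------
# Per-peak aggregation across runs


@dataclass
class TFStats:
    e_values: list[float]
    median: float
    q1: float
    q3: float
    frac_significant: float
    top_candidate_freq: float


@dataclass
class PeakMatchStats:
    peak_id: int
    n_matched_runs: int
    per_tf: dict[str, TFStats] = field(default_factory=dict)


def aggregate_peak_stats(
    per_run_peak_matches: Sequence[Mapping[int, Sequence[MatchScore]]],
    peaks: Sequence[Peak],
    alpha: float = 0.05,
) -> list[PeakMatchStats]:
    """Reduce per-run match lists into per-peak, per-factor E-value summaries.

    One E-value per factor per run (the run's best) enters the statistics.
    ``top_candidate_freq`` divides by the total number of runs, so runs
    without any match for a peak contribute to no factor and the
    frequencies sum to at most 1.
    """
    n_runs = len(per_run_peak_matches)
    out = []
    for peak in peaks:
        evals: dict[str, list[float]] = {}
        top_counts: Counter[str] = Counter()
        matched_runs = 0
        for run_matches in per_run_peak_matches:
            matches = run_matches.get(peak.peak_id, [])
            if not matches:
                continue
            matched_runs += 1
            best_per_tf: dict[str, tuple[float, float]] = {}
            for m in matches:
                key = (m.e_value, -m.score)
                prev = best_per_tf.get(m.db_motif_name)
                if prev is None or key < prev:
                    best_per_tf[m.db_motif_name] = key
            for tf, (e, _ns) in best_per_tf.items():
                evals.setdefault(tf, []).append(e)
            # ties at the empirical p-value floor break on alignment score
            top_counts[min(best_per_tf, key=lambda tf: best_per_tf[tf])] += 1
        stats = PeakMatchStats(peak_id=peak.peak_id, n_matched_runs=matched_runs)
        for tf, es in evals.items():
            arr = np.array(es)
            stats.per_tf[tf] = TFStats(
                e_values=es,
                median=float(np.median(arr)),
                q1=float(np.percentile(arr, 25)),
                q3=float(np.percentile(arr, 75)),
                frac_significant=float((arr < alpha).mean()),
                top_candidate_freq=top_counts[tf] / n_runs if n_runs else 0.0,
            )
        out.append(stats)
    return out


def peak_stats_to_frame(stats: Sequence[PeakMatchStats]) -> pd.DataFrame:
    rows = []
    for ps in stats:
        for tf, s in sorted(ps.per_tf.items()):
            rows.append(
                {
                    "peak_id": ps.peak_id,
                    "tf": tf,
                    "n_runs_matched": len(s.e_values),
                    "e_median": s.median,
                    "e_q1": s.q1,
                    "e_q3": s.q3,
                    "frac_significant": s.frac_significant,
                    "top_candidate_freq": s.top_candidate_freq,
                }
            )
    columns = [
        "peak_id", "tf", "n_runs_matched", "e_median", "e_q1", "e_q3",
        "frac_significant", "top_candidate_freq",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Consolidated per-peak alignments


@dataclass
class AlignmentRow:
    promoter_id: str
    segment: str  # peak-width sequence, '-' rows already reverse-complemented
    start: int  # 0-based start on the promoter's forward strand
    strand: str
    padded: bool = False  # True when N-padding crossed a promoter boundary


@dataclass
class ConsolidatedAlignment:
    peak_id: int
    width: int
    rows: list[AlignmentRow]
    pwm: np.ndarray

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(
                    f">{row.promoter_id} start={row.start} strand={row.strand}"
                    f"{' padded' if row.padded else ''}\n{row.segment}\n"
                )


def motifs_overlapping_peak(
    run_motifs: Sequence[Motif], peak: Peak, target_id: str
) -> list[tuple[Motif, Instance]]:
    """A run's motifs whose target instance overlaps the peak by >= 1 bp."""
    hits = []
    for motif in run_motifs:
        for inst in motif.instances:
            if inst.promoter_id != target_id:
                continue
            if inst.start < peak.end and inst.start + motif.width > peak.start:
                hits.append((motif, inst))
                break
    return hits


def build_consolidated_alignment(
    peak: Peak,
    per_run_motifs: Sequence[Sequence[Motif]],
    records: Sequence[PromoterRecord],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> ConsolidatedAlignment:
    """Stack, at peak width, the conserved segment from every detected promoter.

    Each motif instance on a non-target promoter is re-anchored so the
    instance start aligns with its run's peak-overlapping target instance,
    then trimmed/extended to peak width. When runs disagree on a promoter's
    position, the most frequently detected (then leftmost) position wins;
    '-' strand rows are reverse-complemented before stacking; rows crossing
    a promoter boundary are N-padded and flagged.
    """
    target = find_target(records)
    sequences = {r.id: r.sequence for r in records}
    votes: dict[str, Counter] = {}
    supporting = 0
    for run_motifs in per_run_motifs:
        hits = motifs_overlapping_peak(run_motifs, peak, target.id)
        if hits:
            supporting += 1
        for motif, t_inst in hits:
            left_ext = t_inst.start - peak.start
            right_ext = peak.end - (t_inst.start + motif.width)
            for inst in motif.instances:
                if inst.promoter_id == target.id:
                    continue
                if inst.strand == "+":
                    row_start = inst.start - left_ext
                else:
                    row_start = inst.start - right_ext
                votes.setdefault(inst.promoter_id, Counter())[
                    (row_start, inst.strand)
                ] += 1
    if supporting == 0:
        raise ValueError(f"peak {peak.peak_id} has no supporting run")

    width = peak.width
    rows = [
        AlignmentRow(
            promoter_id=target.id,
            segment=target.sequence[peak.start : peak.end],
            start=peak.start,
            strand="+",
        )
    ]
    for pid in sorted(votes):
        counter = votes[pid]
        top = max(counter.values())
        row_start, strand = min(
            (pos for pos, c in counter.items() if c == top),
            key=lambda x: (x[0], x[1] != "+"),
        )
        seq = sequences[pid]
        lo, hi = row_start, row_start + width
        core = seq[max(0, lo) : min(len(seq), hi)]
        pad_left = max(0, -lo)
        pad_right = max(0, hi - len(seq))
        segment = "N" * pad_left + core + "N" * pad_right
        if strand == "-":
            segment = reverse_complement(segment)
        rows.append(
            AlignmentRow(
                promoter_id=pid,
                segment=segment,
                start=row_start,
                strand=strand,
                padded=bool(pad_left or pad_right),
            )
        )

    pwm = _pwm_from_rows([r.segment for r in rows], pseudocount, background)
    return ConsolidatedAlignment(peak_id=peak.peak_id, width=width, rows=rows, pwm=pwm)


def _pwm_from_rows(
    rows: Sequence[str], pseudocount: float, background: np.ndarray | None
) -> np.ndarray:
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    width = len(rows[0])
    code = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((width, 4))
    for row in rows:
        for w, ch in enumerate(row):
            if ch == "N":
                counts[w] += q
            else:
                counts[w, code[ch]] += 1.0
    pwm = counts + pseudocount
    return pwm / pwm.sum(axis=1, keepdims=True)


def score_consolidated(
    alignment: ConsolidatedAlignment,
    db: MotifDatabase,
    min_overlap: int = 5,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[MatchScore]:
    """Compare the consolidated alignment's PWM against the database."""
    if len(alignment.rows) < 2:
        raise ValueError("consolidated alignment needs at least 2 rows")
    return compare_pwms(
        alignment.pwm,
        db,
        min_overlap=min_overlap,
        n_shuffles=n_shuffles,
        seed=seed,
        query_name=f"peak_{alignment.peak_id}_consolidated",
    )


# ---------------------------------------------------------------------------
# Taxonomic presence map


@dataclass
class PresenceMap:
    peak_id: int
    present: dict[str, bool]  # taxon -> similar motif at the aligned position
    sampled: dict[str, bool]  # taxon ever drawn into a subset

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon": taxon,
                "peak_id": self.peak_id,
                "present": int(self.present[taxon]),
                "sampled": int(self.sampled.get(taxon, False)),
            }
            for taxon in sorted(self.present)
        ]
        return pd.DataFrame(rows, columns=["taxon", "peak_id", "present", "sampled"])


def presence_map(
    peak: Peak,
    per_run_motifs: Sequence[Sequence[Motif]],
    records: Sequence[PromoterRecord],
    sampled_ids: set[str] | None = None,
) -> PresenceMap:
    """Which taxa carried a similar motif at the position aligned with the peak.

    ``sampled`` distinguishes absence of evidence (taxon never drawn into any
    subset) from evidence of absence (drawn but no similar motif found).
    """
    target = find_target(records)
    taxon_of = {r.id: r.taxon for r in records}
    present = {r.taxon: False for r in records}
    for run_motifs in per_run_motifs:
        for motif, _t_inst in motifs_overlapping_peak(run_motifs, peak, target.id):
            for inst in motif.instances:
                present[taxon_of[inst.promoter_id]] = True
    if sampled_ids is None:
        sampled = {r.taxon: True for r in records}
    else:
        sampled = {r.taxon: (r.id in sampled_ids or r.is_target) for r in records}
    return PresenceMap(peak_id=peak.peak_id, present=present, sampled=sampled)
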