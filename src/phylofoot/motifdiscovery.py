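"""De novo motif discovery: built-in finders and the voting combiner.

Two finders implement one discovery contract so the pipeline runs fully
offline: a classic Gibbs site sampler (one site per sequence, both strands)
and a word-enumeration consensus finder. Their per-subset outputs are
combined by a voting rule that keeps only motifs supported by a quorum of
finders at overlapping positions. Additional finders (e.g. adapters around
external binaries) can be plugged in as callables returning a
:class:`FinderResult`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .iodata import PromoterRecord, reverse_complement

BASES = "ACGT"
_ENCODE = {b: i for i, b in enumerate("ACGTN")}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in _ENCODE.items():
    _ENCODE_LUT[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int codes A=0 C=1 G=2 T=3 N=4."""
    codes = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


@dataclass(frozen=True, order=True)
class Instance:
    """One motif occurrence: forward-strand interval plus strand.

    ``start`` is 0-based on the promoter's forward strand; a ``-`` strand
    instance means the motif reads as the reverse complement of
    ``sequence[start:start+width]``.
    """

    promoter_id: str
    start: int
    strand: str  # "+" or "-"


@dataclass
class Motif:
    """A PWM with the instance list it was built from.

    ``score`` is the information content in bits,
    IC = sum_w sum_b f_wb log2(f_wb / q_b).
    """

    width: int
    counts: np.ndarray  # W x 4
    pwm: np.ndarray  # W x 4, rows sum to 1
    instances: list[Instance] = field(default_factory=list)
    score: float = 0.0

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))


@dataclass
class FinderResult:
    finder_name: str
    motifs: list[Motif]  # ranked by score descending


def information_content(pwm: np.ndarray, background: np.ndarray | None = None) -> float:
    """IC in bits of a PWM against a background distribution."""
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    p = np.asarray(pwm, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return float(terms.sum())


def build_motif(
    instances: Sequence[Instance],
    sequences: Mapping[str, str],
    width: int,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> Motif:
    """Assemble counts/PWM/IC from instance substrings (strand-aware).

    N bases contribute the background distribution to the counts rather
    than any specific base.
    """
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for inst in instances:
        seq = sequences[inst.promoter_id]
        seg = seq[inst.start : inst.start + width]
        if len(seg) != width:
            raise ValueError(
                f"instance at {inst.promoter_id}:{inst.start} exceeds promoter bounds"
            )
        if inst.strand == "-":
            seg = reverse_complement(seg)
        for w, ch in enumerate(seg):
            code = _ENCODE[ch]
            if code == 4:
                counts[w] += q
            else:
                counts[w, code] += 1.0
    pwm = counts + pseudocount
    pwm = pwm / pwm.sum(axis=1, keepdims=True)
    return Motif(
        width=width,
        counts=counts,
        pwm=pwm,
        instances=list(instances),
        score=information_content(pwm, q),
    )


def _rc_logodds(logodds5: np.ndarray) -> np.ndarray:
    """Log-odds for scoring the reverse strand on forward-encoded sequence."""
    return logodds5[::-1, _COMP_CODE]


# ---------------------------------------------------------------------------
# Gibbs site sampler


@dataclass
class GibbsConfig:
    max_iters: int = 500
    patience: int = 50  # iterations without IC improvement before stopping
    restarts: int = 5
    pseudocount: float = 0.5
    seed: int = 0
    background: np.ndarray | None = None


def gibbs_finder(
    seqs: Sequence[PromoterRecord], width: int, cfg: GibbsConfig | None = None
) -> FinderResult:
    """One-site-per-sequence Gibbs sampler over both strands.

    Holds out one sequence at a time, builds a PWM (pseudocount 0.5) from
    the remaining sites, and resamples the held-out site proportional to the
    PWM/background likelihood ratio over all offsets on both strands. The
    best-IC site configuration across restarts is returned; seeded and
    reproducible.
    """
    cfg = cfg or GibbsConfig()
    if len(seqs) < 3:
        raise ValueError("gibbs_finder needs at least 3 sequences")
    for r in seqs:
        if len(r.sequence) < width:
            raise ValueError(
                f"sequence '{r.id}' (length {len(r.sequence)}) is shorter than "
                f"motif width {width}"
            )
    rng = np.random.default_rng(cfg.seed)
    q = np.full(4, 0.25) if cfg.background is None else np.asarray(cfg.background, float)
    logq = np.log(q)
    enc = [encode(r.sequence) for r in seqs]
    nwins = [e.size - width + 1 for e in enc]
    n = len(seqs)
    wrange = np.arange(width)[:, None]
    # per-sequence (W x nwin) gather indices into the log-odds columns
    idx = [np.lib.stride_tricks.sliding_window_view(e, width).T for e in enc]

    def one_hot_window(i: int, pos: int, strand: int) -> np.ndarray:
        window = enc[i][pos : pos + width]
        if strand == 1:
            window = _COMP_CODE[window][::-1]
        oh = np.zeros((width, 4))
        for w, code in enumerate(window):
            if code == 4:
                oh[w] += q
            else:
                oh[w, code] += 1.0
        return oh

    def config_ic(sites: list[tuple[int, int]]) -> float:
        counts = np.zeros((width, 4))
        for i, (pos, strand) in enumerate(sites):
            counts += one_hot_window(i, pos, strand)
        pwm = counts + cfg.pseudocount
        pwm /= pwm.sum(axis=1, keepdims=True)
        return information_content(pwm, q)

    best_sites: list[tuple[int, int]] | None = None
    best_ic = -np.inf
    for _restart in range(cfg.restarts):
        sites = [(int(rng.integers(nw)), int(rng.integers(2))) for nw in nwins]
        totals = np.zeros((width, 4))
        for i, (pos, strand) in enumerate(sites):
            totals += one_hot_window(i, pos, strand)
        local_best = -np.inf
        stall = 0
        for _it in range(cfg.max_iters):
            for i in range(n):
                totals -= one_hot_window(i, *sites[i])
                pwm = totals + cfg.pseudocount
                pwm = pwm / pwm.sum(axis=1, keepdims=True)
                lo = np.log(pwm) - logq  # W x 4 log likelihood ratios
                lo5 = np.column_stack([lo, np.zeros(width)])  # N scores as background
                fwd = lo5[wrange, idx[i]].sum(axis=0)
                rev = _rc_logodds(lo5)[wrange, idx[i]].sum(axis=0)
                logw = np.concatenate([fwd, rev])
                logw -= logw.max()
                w = np.exp(logw)
                cum = np.cumsum(w)
                choice = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                choice = min(choice, logw.size - 1)
                strand, pos = (
                    (0, choice) if choice < nwins[i] else (1, choice - nwins[i])
                )
                sites[i] = (pos, strand)
                totals += one_hot_window(i, pos, strand)
            ic = config_ic(sites)
            if ic > local_best + 1e-12:
                local_best = ic
                stall = 0
                if ic > best_ic:
                    best_ic = ic
                    best_sites = list(sites)
            else:
                stall += 1
                if stall >= cfg.patience:
                    break

    assert best_sites is not None
    instances = [
        Instance(seqs[i].id, pos, "+" if strand == 0 else "-")
        for i, (pos, strand) in enumerate(best_sites)
    ]
    sequences = {r.id: r.sequence for r in seqs}
    motif = build_motif(instances, sequences, width, cfg.pseudocount, q)
    return FinderResult(finder_name="gibbs", motifs=[motif])


# ---------------------------------------------------------------------------
# Word-enumeration consensus finder


@dataclass
class ConsensusConfig:
    pseudocount: float = 0.5
    background: np.ndarray | None = None
    max_motifs: int = 1  # how many ranked candidate words to report

MAX_CONSENSUS_WIDTH = 12  # enumeration guard


def consensus_finder(
    seqs: Sequence[PromoterRecord],
    width: int,
    max_mismatch: int = 1,
    cfg: ConsensusConfig | None = None,
) -> FinderResult:
    """Enumerate W-mers (both strands) and rank by cross-sequence support.

    A candidate word supports a sequence when that sequence contains an
    occurrence within Hamming distance ``max_mismatch`` on either strand.
    Candidates are ranked by (number of supporting sequences, total
    occurrence count, lexicographic word); the motif is built from the best
    (fewest mismatches, then leftmost, '+' preferred) occurrence per
    supporting sequence. Windows containing N are not candidate sources.
    """
    cfg = cfg or ConsensusConfig()
    if width > MAX_CONSENSUS_WIDTH:
        raise ValueError(
            f"consensus_finder enumeration is limited to width <= "
            f"{MAX_CONSENSUS_WIDTH}, got {width}"
        )
    if len(seqs) < 2:
        raise ValueError("consensus_finder needs at least 2 sequences")

    # Collect all clean windows per sequence on both strands, grouped by
    # sequence so support can be reduced per-sequence with reduceat. At each
    # start the '+' window precedes its '-' partner so index order encodes
    # the (leftmost, '+'-preferred) tie-break.
    window_blocks: list[np.ndarray] = []
    window_meta: list[tuple[int, int, str]] = []  # (seq_idx, start, strand)
    seq_starts: list[int] = []
    for i, rec in enumerate(seqs):
        seq_starts.append(len(window_meta))
        e = encode(rec.sequence)
        if e.size < width:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(e, width)
        clean = ~(sw == 4).any(axis=1)
        starts = np.flatnonzero(clean)
        if starts.size == 0:
            continue
        fwd = sw[starts]
        rev = _COMP_CODE[fwd][:, ::-1]
        both = np.empty((2 * starts.size, width), dtype=np.int8)
        both[0::2] = fwd
        both[1::2] = rev
        window_blocks.append(both)
        for j in starts:
            window_meta.append((i, int(j), "+"))
            window_meta.append((i, int(j), "-"))
    if not window_blocks:
        return FinderResult(finder_name="consensus", motifs=[])
    windows = np.concatenate(window_blocks, axis=0)
    boundaries = np.array(seq_starts)

    packed = windows.astype(np.int64) @ (4 ** np.arange(width - 1, -1, -1, dtype=np.int64))
    uniq_packed, first_idx = np.unique(packed, return_index=True)
    candidates = windows[first_idx]

    n_seq = len(seqs)
    n_cand = candidates.shape[0]
    seq_bounds = list(boundaries) + [len(window_meta)]
    support = np.zeros(n_cand, dtype=np.int64)
    total_occ = np.zeros(n_cand, dtype=np.int64)
    chunk = max(1, 2_000_000 // max(windows.shape[0], 1))
    for c0 in range(0, n_cand, chunk):
        cand = candidates[c0 : c0 + chunk]
        mism = (windows[None, :, :] != cand[:, None, :]).sum(axis=2, dtype=np.int16)
        hit = mism <= max_mismatch
        total_occ[c0 : c0 + chunk] = hit.sum(axis=1)
        per_seq = np.zeros((hit.shape[0], n_seq), dtype=bool)
        for i in range(n_seq):
            lo, hi = seq_bounds[i], seq_bounds[i + 1]
            if lo < hi:
                per_seq[:, i] = hit[:, lo:hi].any(axis=1)
        support[c0 : c0 + chunk] = per_seq.sum(axis=1)

    def word_str(cand: np.ndarray) -> str:
        return "".join(BASES[c] for c in cand)

    order = sorted(
        range(n_cand),
        key=lambda c: (-support[c], -total_occ[c], word_str(candidates[c])),
    )
    sequences = {r.id: r.sequence for r in seqs}
    motifs: list[Motif] = []
    for c in order[: cfg.max_motifs]:
        if support[c] < 2:
            break
        mism = (windows != candidates[c][None, :]).sum(axis=1)
        instances: list[Instance] = []
        for i, rec in enumerate(seqs):
            lo = boundaries[i]
            hi = boundaries[i + 1] if i + 1 < n_seq else len(window_meta)
            if lo == hi:
                continue
            local = mism[lo:hi]
            best = local.min()
            if best > max_mismatch:
                continue
            # fewest mismatches, then leftmost start, then '+' strand
            choices = [
                (local[k], window_meta[lo + k][1], window_meta[lo + k][2] == "-", lo + k)
                for k in np.flatnonzero(local == best)
            ]
            _, start, _, idx = min(choices)
            _, start, strand = window_meta[idx]
            instances.append(Instance(rec.id, start, strand))
        motifs.append(
            build_motif(instances, sequences, width, cfg.pseudocount, cfg.background)
        )
    motifs.sort(key=lambda m: -m.score)
    return FinderResult(finder_name="consensus", motifs=motifs)


FinderFunc = Callable[[Sequence[PromoterRecord], int], FinderResult]


# ---------------------------------------------------------------------------
# Voting combiner


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def vote_combine(
    results: Sequence[FinderResult],
    sequences: Mapping[str, str],
    quorum: int = 2,
    overlap_frac: float = 0.5,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> list[Motif]:
    """Merge finder outputs by positional agreement ("voting").

    Instances from different finders are grouped when, on the same promoter
    and strand, their intervals overlap by at least ``overlap_frac`` of the
    shorter width; instances of one source motif always stay grouped. A
    group is kept when it contains instances from at least ``quorum``
    distinct finders (auto-lowered to 1 when only one finder ran); each kept
    group becomes one merged motif rebuilt from one instance per promoter
    location, re-anchored into the coordinate frame (and width) of the
    group's highest-IC source motif.
    """
    if not results:
        raise ValueError("vote_combine needs at least one finder result")
    if len({r.finder_name for r in results}) == 1:
        quorum = 1

    entries: list[tuple[str, int, Instance, int]] = []  # finder, motif key, inst, width
    for ri, r in enumerate(results):
        for mi, motif in enumerate(r.motifs):
            mkey = ri * 10_000 + mi
            for inst in motif.instances:
                entries.append((r.finder_name, mkey, inst, motif.width))
    if not entries:
        return []

    uf = _UnionFind(len(entries))
    by_motif: dict[int, list[int]] = {}
    by_pos: dict[tuple[str, str], list[int]] = {}
    for idx, (_f, mkey, inst, _w) in enumerate(entries):
        by_motif.setdefault(mkey, []).append(idx)
        by_pos.setdefault((inst.promoter_id, inst.strand), []).append(idx)
    for idxs in by_motif.values():
        for a, b in zip(idxs, idxs[1:]):
            uf.union(a, b)
    for idxs in by_pos.values():
        for a, b in itertools.combinations(idxs, 2):
            fa, _, ia, wa = entries[a]
            fb, _, ib, wb = entries[b]
            ov = _overlap(ia.start, ia.start + wa, ib.start, ib.start + wb)
            if ov >= overlap_frac * min(wa, wb):
                uf.union(a, b)

    groups: dict[int, list[int]] = {}
    for idx in range(len(entries)):
        groups.setdefault(uf.find(idx), []).append(idx)

    motif_rank: dict[int, tuple[float, int]] = {}  # mkey -> (IC, width)
    for ri, r in enumerate(results):
        for mi, motif in enumerate(r.motifs):
            motif_rank[ri * 10_000 + mi] = (motif.score, motif.width)

    merged: list[Motif] = []
    for idxs in groups.values():
        finders = {entries[i][0] for i in idxs}
        if len(finders) < quorum:
            continue
        # Anchor every location in the coordinates of the group's highest-IC
        # source motif and keep its width: each source motif's sites are
        # internally consistent, so correcting the others by their modal
        # shift against the reference keeps columns aligned across promoters
        # instead of smearing them by per-promoter interval arithmetic.
        mkeys = sorted(
            {entries[i][1] for i in idxs}, key=lambda k: -motif_rank[k][0]
        )
        ref_key = mkeys[0]
        ref_w = motif_rank[ref_key][1]
        merged_w = ref_w
        sites: dict[int, dict[tuple[str, str], int]] = {}
        for i in idxs:
            _f, mkey, inst, _w = entries[i]
            loc = sites.setdefault(mkey, {})
            key = (inst.promoter_id, inst.strand)
            if key not in loc or inst.start < loc[key]:
                loc[key] = inst.start
        shift: dict[int, int] = {ref_key: 0}
        for mkey in mkeys[1:]:
            deltas = [
                sites[ref_key][k] - s
                for k, s in sites[mkey].items()
                if k in sites[ref_key]
            ]
            shift[mkey] = Counter(deltas).most_common(1)[0][0] if deltas else 0

        out_instances: list[Instance] = []
        seen: set[tuple[str, str]] = set()
        for mkey in mkeys:  # best-ranked source wins each location
            w_m = motif_rank[mkey][1]
            for (pid, strand), start in sorted(sites[mkey].items()):
                if (pid, strand) in seen:
                    continue
                seen.add((pid, strand))
                ref_start = start + shift[mkey]
                if ref_start + merged_w <= start or ref_start >= start + w_m:
                    # a shift that would detach the site from its source
                    # evidence falls back to the source's own interval
                    ref_start = start + (w_m - merged_w) // 2
                seq_len = len(sequences[pid])
                ref_start = max(0, min(ref_start, seq_len - merged_w))
                out_instances.append(Instance(pid, ref_start, strand))
        motif = build_motif(out_instances, sequences, merged_w, pseudocount, background)
        merged.append(motif)
    merged.sort(key=lambda m: -m.score)
    return merged
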