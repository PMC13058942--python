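"""Synthetic orthologous-promoter sets with implanted conserved motifs.

Generates a pure-birth guide tree whose leaf-to-target distances populate
all three stratification bins, evolves a root promoter down it under
Jukes-Cantor substitutions (no indels), and implants motif instances drawn
from a PWM whose positions mutate at a reduced rate — the conservation
structure phylogenetic footprinting assumes. Ground truth (implant
intervals per leaf, the tree, the root sequence) is returned alongside the
sequences so every downstream stage can be validated against it.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .iodata import GuideTree, MotifDatabase, DatabaseMotif, PromoterRecord, write_fasta, write_newick, write_meme_motifs

BASES = "ACGT"

TARGET_ID = "target"


def default_implant_pwm(dominance: float = 0.85) -> np.ndarray:
    """A 12-column PWM around the consensus TTGATCGATCAA.

    Per-column probability ``dominance`` on the consensus base and the rest
    spread evenly gives ~1.15 bits per column (~13.8 bits total), a
    specificity typical of bacterial TFBS models.
    """
    consensus = "TTGATCGATCAA"
    return pwm_from_consensus(consensus, dominance)


def pwm_from_consensus(consensus: str, dominance: float = 0.85) -> np.ndarray:
    pwm = np.full((len(consensus), 4), (1 - dominance) / 3)
    for i, ch in enumerate(consensus):
        pwm[i, BASES.index(ch)] = dominance
    return pwm


@dataclass
class SimConfig:
    """Conditions of the simulated study.

    30 taxa at distances spanning the three stratification bins, 250 bp
    promoters with one implanted conserved motif, and motif positions
    mutating at ``conservation`` times the background rate.
    """

    n_taxa: int = 30
    promoter_length: int = 250
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    implant_pwm: np.ndarray = field(default_factory=default_implant_pwm)
    implant_positions: list[int] = field(default_factory=lambda: [100])
    conservation: float = 0.1
    tree_depth_range: tuple[float, float] = (0.05, 0.73)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.conservation <= 1:
            raise ValueError("conservation must be in [0, 1]")
        w = self.implant_pwm.shape[0]
        spans = sorted((p, p + w) for p in self.implant_positions)
        for (s, e), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e:
                raise ValueError("implant intervals overlap")
        for s, e in spans:
            if s < 0 or e > self.promoter_length:
                raise ValueError("implant interval outside the promoter")


@dataclass
class GroundTruth:
    intervals: dict[str, list[tuple[int, int, str]]]  # taxon -> (start, end, strand)
    tree: GuideTree
    root_sequence: str

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon in sorted(self.intervals):
                for start, end, strand in self.intervals[taxon]:
                    fh.write(f"{taxon}\t{start}\t{end}\timplant\t0\t{strand}\n")


def jc_substitution_probability(d: float) -> float:
    """Jukes-Cantor per-site substitution probability over a branch of length d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_tree(
    n_taxa: int,
    depth_range: tuple[float, float] = (0.05, 0.73),
    seed: int = 0,
) -> GuideTree:
    """Pure-birth tree with target distances spread over the strata.

    A birth-death (death rate 0) topology is simulated and branch lengths
    rescaled so the designated target leaf's distances to the other leaves
    hit prescribed values: when the depth range spans the default cut points
    (0.31, 0.55) those delimit the bins, else the range is cut into thirds,
    and leaves are assigned to bins cyclically in 1:1:2 proportion (the far
    bin holding twice as many, matching the 3:3:6 draw). Non-target pendant
    edges are adjusted to realize the prescribed distances exactly.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa (one target + one per bin)")
    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    leaves = list(tree.leaf_node_iter())
    for i, leaf in enumerate(leaves):
        label = TARGET_ID if i == 0 else f"ortho_{i:03d}"
        leaf.taxon = tree.taxon_namespace.new_taxon(label) if leaf.taxon is None else leaf.taxon
        leaf.taxon.label = label
    target_leaf = leaves[0]

    lo, hi = depth_range
    n_others = n_taxa - 1
    if hi <= lo:
        desired = np.full(n_others, lo)
    else:
        if lo < 0.31 < 0.55 < hi:
            edges = np.array([lo, 0.31, 0.55, hi])
        else:
            edges = np.linspace(lo, hi, 4)
        margins = 0.02 * (edges[1:] - edges[:-1])
        pattern = [0, 1, 2, 2]  # cyclic bin assignment, far bin twice over
        desired = np.empty(n_others)
        for i in range(n_others):
            b = pattern[i % 4]
            desired[i] = rng.uniform(edges[b] + margins[b], edges[b + 1] - margins[b])

    # Scale the whole tree so every shared path (distance minus the leaf's
    # own pendant edge) sits safely below the smallest prescribed distance,
    # then set each non-target pendant to land exactly on its target.
    pdm = tree.phylogenetic_distance_matrix()
    shared = np.array(
        [
            pdm.patristic_distance(target_leaf.taxon, leaf.taxon)
            - (leaf.edge.length or 0.0)
            for leaf in leaves[1:]
        ]
    )
    max_shared = shared.max() if shared.size else 0.0
    floor = desired.min() if desired.size else lo
    factor = (0.8 * floor / max_shared) if max_shared > 0 and floor > 0 else 1.0
    factor = min(factor, 1.0) if floor > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    for leaf, want, shared_raw in zip(leaves[1:], desired, shared):
        leaf.edge.length = max(float(want) - shared_raw * factor, 0.0)
    return GuideTree(tree=tree)


def evolve_promoters(cfg: SimConfig) -> tuple[list[PromoterRecord], GroundTruth]:
    """Evolve a root promoter down a simulated tree.

    Root background positions are i.i.d. from ``cfg.background``; implant
    positions are sampled column-wise from ``cfg.implant_pwm``. Along each
    branch of length d a background site substitutes with probability
    (3/4)(1 - e^(-4d/3)) (uniform among the three alternatives) and a motif
    site with the same expression at length ``conservation * d``, so motif
    divergence grows with distance but more slowly than neutral sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_taxa, cfg.tree_depth_range, seed=int(rng.integers(2**31)))
    length = cfg.promoter_length
    width = cfg.implant_pwm.shape[0]

    motif_mask = np.zeros(length, dtype=bool)
    root = rng.choice(4, size=length, p=np.asarray(cfg.background, float))
    for pos in cfg.implant_positions:
        motif_mask[pos : pos + width] = True
        for w in range(width):
            root[pos + w] = rng.choice(4, p=cfg.implant_pwm[w])

    seqs: dict[str, np.ndarray] = {}

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            child_seq = seq.copy()
            p_bg = jc_substitution_probability(d)
            p_mot = jc_substitution_probability(cfg.conservation * d)
            u = rng.random(length)
            mutate = np.where(motif_mask, u < p_mot, u < p_bg)
            idx = np.flatnonzero(mutate)
            if idx.size:
                child_seq[idx] = (
                    child_seq[idx] + 1 + rng.integers(0, 3, size=idx.size)
                ) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.tree.seed_node, root)

    records = []
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label
        seq = "".join(BASES[b] for b in seqs[label])
        records.append(
            PromoterRecord(id=label, sequence=seq, is_target=(label == TARGET_ID))
        )
        intervals[label] = [
            (pos, pos + width, "+") for pos in cfg.implant_positions
        ]
    truth = GroundTruth(
        intervals=intervals,
        tree=tree,
        root_sequence="".join(BASES[b] for b in root),
    )
    return records, truth


def make_decoy_database(
    implant_pwm: np.ndarray,
    n_decoys: int = 19,
    seed: int = 0,
    dominance: float = 0.85,
    implant_name: str = "IMPLANT",
) -> MotifDatabase:
    """The implant PWM hidden among random decoys of matched width/specificity."""
    rng = np.random.default_rng(seed)
    width = implant_pwm.shape[0]
    motifs = [DatabaseMotif(name=implant_name, pwm=np.asarray(implant_pwm, float))]
    for k in range(n_decoys):
        consensus = "".join(BASES[i] for i in rng.integers(0, 4, size=width))
        motifs.append(
            DatabaseMotif(name=f"DECOY_{k + 1:02d}", pwm=pwm_from_consensus(consensus, dominance))
        )
    return MotifDatabase(motifs=motifs)


def write_simulation(
    cfg: SimConfig, outdir: str | Path, n_decoys: int = 19
) -> tuple[list[PromoterRecord], GroundTruth, MotifDatabase]:
    """Emit FASTA, Newick, ground-truth BED and a decoy MEME database."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = evolve_promoters(cfg)
    db = make_decoy_database(cfg.implant_pwm, n_decoys=n_decoys, seed=cfg.seed + 1)
    write_fasta(records, outdir / "promoters.fasta")
    write_newick(truth.tree, outdir / "tree.nwk")
    truth.to_bed(outdir / "implants.bed")
    write_meme_motifs(db, outdir / "motif_db.meme")
    return records, truth, db
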