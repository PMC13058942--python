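"""Pairwise evolutionary distances and distance stratification.

Distances come from a user-supplied guide tree (patristic path sums) when
one is given; otherwise from pairwise global alignments with a Jukes-Cantor
correction. The orthologous set is then split into near/mid/far subgroups
relative to the target promoter, the ranges following the informativeness
argument that very close promoters carry too few background substitutions
to separate conserved sites from neutral sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .iodata import GuideTree, PromoterRecord

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative promoter-by-promoter distance matrix."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate promoter ids")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.8g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], d=df.to_numpy(dtype=float))


@dataclass
class StratificationConfig:
    """Distance cut points delimiting the near/mid/far subgroups."""

    lower_cut: float = 0.05
    b1: float = 0.31
    b2: float = 0.55
    upper_cut: float = 0.73

    def __post_init__(self) -> None:
        if not (self.lower_cut < self.b1 < self.b2 < self.upper_cut):
            raise ValueError("cut points must satisfy lower_cut < b1 < b2 < upper_cut")


@dataclass
class Subgroups:
    """Disjoint near/mid/far promoter-id lists plus out-of-range exclusions."""

    g1: list[str] = field(default_factory=list)
    g2: list[str] = field(default_factory=list)
    g3: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.g1), len(self.g2), len(self.g3))

    def group_of(self, pid: str) -> int | None:
        """0/1/2 for g1/g2/g3, None when excluded or unknown."""
        for k, g in enumerate((self.g1, self.g2, self.g3)):
            if pid in g:
                return k
        return None


# ---------------------------------------------------------------------------
# Tree distances


def patristic_distance(tree: GuideTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique leaf-to-leaf path."""
    if a == b:
        _leaf(tree, a)  # still validate the label
        return 0.0
    ta, tb = _leaf(tree, a), _leaf(tree, b)
    pdm = tree.tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(ta.taxon, tb.taxon))


def _leaf(tree: GuideTree, label: str):
    for lf in tree.tree.leaf_node_iter():
        if lf.taxon and lf.taxon.label == label:
            return lf
    raise KeyError(f"leaf '{label}' not found in guide tree")


def matrix_from_tree(tree: GuideTree, ids: Sequence[str]) -> DistanceMatrix:
    """Patristic distance matrix over the given promoter ids."""
    leaves = {lf.taxon.label: lf.taxon for lf in tree.tree.leaf_node_iter() if lf.taxon}
    missing = [i for i in ids if i not in leaves]
    if missing:
        raise KeyError(f"promoter ids missing from the guide tree: {missing}")
    pdm = tree.tree.phylogenetic_distance_matrix()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(leaves[ids[i]], leaves[ids[j]])
    return DistanceMatrix(ids=list(ids), d=d)


# ---------------------------------------------------------------------------
# Alignment fallback (Jukes-Cantor)

# Fixed scoring so the fallback distances are reproducible across runs.
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


class SaturationError(ValueError):
    """The observed mismatch fraction exceeds the Jukes-Cantor domain."""


def jc_from_p(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) of a p-distance."""
    if p < 0:
        raise ValueError("p-distance must be nonnegative")
    if p >= 0.75:
        raise SaturationError(
            f"p-distance {p:.3f} >= 0.75: Jukes-Cantor distance undefined (saturated)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance from a pairwise global alignment.

    Alignment scoring is fixed (+1 match / -1 mismatch / -2 gap); p is the
    mismatch fraction over aligned non-gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        raise ValueError("no aligned non-gap columns")
    p = counts.mismatches / aligned
    return jc_from_p(p)


def matrix_from_sequences(records: Sequence[PromoterRecord]) -> DistanceMatrix:
    """All-pairs Jukes-Cantor distances from pairwise alignments."""
    ids = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(records[i].sequence, records[j].sequence)
    return DistanceMatrix(ids=ids, d=d)


# ---------------------------------------------------------------------------
# Stratification


def stratify(
    dm: DistanceMatrix, target_id: str, cfg: StratificationConfig | None = None
) -> Subgroups:
    """Split promoters into near/mid/far bins by distance to the target.

    Bins are half-open [lower_cut, b1), [b1, b2) and closed-top [b2,
    upper_cut]; promoters below lower_cut (too similar to be informative) or
    above upper_cut land in ``excluded``. The target joins no subgroup.
    """
    cfg = cfg or StratificationConfig()
    if target_id not in dm.ids:
        raise KeyError(f"target '{target_id}' not in distance matrix")
    groups = Subgroups()
    for pid in dm.ids:
        if pid == target_id:
            continue
        dist = dm.get(pid, target_id)
        if cfg.lower_cut <= dist < cfg.b1:
            groups.g1.append(pid)
        elif cfg.b1 <= dist < cfg.b2:
            groups.g2.append(pid)
        elif cfg.b2 <= dist <= cfg.upper_cut:
            groups.g3.append(pid)
        else:
            groups.excluded.append(pid)
    if groups.excluded:
        logger.info(
            "stratify: excluded %d promoters outside [%.2f, %.2f]",
            len(groups.excluded),
            cfg.lower_cut,
            cfg.upper_cut,
        )
    logger.info("stratify: subgroup sizes %s", groups.sizes)
    return groups
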