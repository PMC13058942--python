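"""Stratified bootstrap generation of promoter subsets.

From subgroup sizes the maximum number M of complete, disjoint
quota-respecting subsets is computed; N = rounds * M subsets are then drawn
in ``rounds`` epochs. Within an epoch each subgroup is shuffled and consumed
without replacement (no promoter twice per epoch); promoters re-enter the
pool between epochs, which is the bootstrap-with-replacement character of
the scheme. A minimum pairwise distance among subset members keeps
near-duplicate promoters out of the same subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, Subgroups

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Subset-generation parameters.

    quota: members drawn from (near, mid, far) subgroups per subset.
    rounds: epoch multiplier r, giving N = r * M subsets.
    min_intra_distance: minimum pairwise distance among subset members;
        candidates violating it are retried, then waived with a warning.
    """

    quota: tuple[int, int, int] = (3, 3, 6)
    rounds: int = 2
    min_intra_distance: float = 0.02
    seed: int = 0
    retry_budget: int = 100

    def __post_init__(self) -> None:
        if any(q < 1 for q in self.quota):
            raise ValueError("quota entries must be >= 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.min_intra_distance < 0:
            raise ValueError("min_intra_distance must be >= 0")

    @property
    def subset_size(self) -> int:
        return sum(self.quota)


@dataclass
class SubsetSpec:
    """One bootstrap subset: quota members plus the appended target."""

    run_id: int
    member_ids: list[str]
    target_id: str

    @property
    def all_ids(self) -> list[str]:
        return self.member_ids + [self.target_id]


@dataclass
class SubsetPlan:
    M: int
    subsets: list[SubsetSpec] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.subsets)

    def to_tsv(self, path: str | Path, groups: Subgroups | None = None) -> None:
        rows = []
        for spec in self.subsets:
            for pid in spec.member_ids:
                grp = groups.group_of(pid) if groups is not None else None
                rows.append(
                    {
                        "run_id": spec.run_id,
                        "member_id": pid,
                        "subgroup": "" if grp is None else f"g{grp + 1}",
                        "is_target": 0,
                    }
                )
            rows.append(
                {
                    "run_id": spec.run_id,
                    "member_id": spec.target_id,
                    "subgroup": "",
                    "is_target": 1,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, M: int | None = None) -> "SubsetPlan":
        df = pd.read_csv(path, sep="\t", dtype={"member_id": str})
        subsets = []
        for run_id, grp in df.groupby("run_id", sort=True):
            members = grp.loc[grp["is_target"] == 0, "member_id"].tolist()
            target = grp.loc[grp["is_target"] == 1, "member_id"].iloc[0]
            subsets.append(SubsetSpec(run_id=int(run_id), member_ids=members, target_id=target))
        return cls(M=M if M is not None else len(subsets), subsets=subsets)


def max_subset_count(
    sizes: tuple[int, int, int], quota: tuple[int, int, int] = (3, 3, 6)
) -> int:
    """Largest M such that M disjoint subsets can honour the quota.

    With disjoint draws, subgroup k supports floor(sizes[k]/quota[k])
    subsets, so M is the minimum of those floors; any empty required
    subgroup gives M = 0.
    """
    return min(s // q for s, q in zip(sizes, quota))


def generate_subsets(
    groups: Subgroups, dm: DistanceMatrix, cfg: SamplerConfig
) -> SubsetPlan:
    """Draw N = rounds * M quota-respecting subsets from the subgroups.

    Deterministic for a fixed seed. The target promoter is appended after
    quota checking and never counts toward quota or the diversity rule.
    Raises when M = 0 (a subgroup smaller than its quota) with guidance to
    relax the stratification.
    """
    sizes = groups.sizes
    M = max_subset_count(sizes, cfg.quota)
    if M < 1:
        raise ValueError(
            f"subgroup sizes {sizes} cannot fill quota {cfg.quota} even once "
            "(M = 0); relax the stratification cut points or supply more "
            "promoters"
        )
    rng = np.random.default_rng(cfg.seed)
    pools = (list(groups.g1), list(groups.g2), list(groups.g3))
    subsets: list[SubsetSpec] = []
    n_waived = 0
    run_id = 0
    for _epoch in range(cfg.rounds):
        epoch_pools = []
        for pool in pools:
            order = rng.permutation(len(pool))
            epoch_pools.append([pool[i] for i in order])
        for _ in range(M):
            members: list[str] = []
            for k, quota_k in enumerate(cfg.quota):
                for _slot in range(quota_k):
                    pool = epoch_pools[k]
                    chosen = None
                    for attempt, cand in enumerate(pool):
                        if attempt >= cfg.retry_budget:
                            break
                        if all(
                            dm.get(cand, m) >= cfg.min_intra_distance for m in members
                        ):
                            chosen = cand
                            break
                    if chosen is None:
                        chosen = pool[0]  # waive the diversity rule for this slot
                        n_waived += 1
                        logger.warning(
                            "run %d: diversity rule waived for '%s' (no candidate "
                            "at distance >= %.3f from current members)",
                            run_id,
                            chosen,
                            cfg.min_intra_distance,
                        )
                    pool.remove(chosen)
                    members.append(chosen)
            target = _target_id(dm, groups)
            subsets.append(
                SubsetSpec(run_id=run_id, member_ids=members, target_id=target)
            )
            run_id += 1
    logger.info(
        "generated N=%d subsets (M=%d, rounds=%d), %d diversity waivers",
        len(subsets),
        M,
        cfg.rounds,
        n_waived,
    )
    return SubsetPlan(M=M, subsets=subsets)


def _target_id(dm: DistanceMatrix, groups: Subgroups) -> str:
    grouped = set(groups.g1) | set(groups.g2) | set(groups.g3) | set(groups.excluded)
    leftovers = [pid for pid in dm.ids if pid not in grouped]
    if len(leftovers) != 1:
        raise ValueError(
            "cannot infer the target promoter: exactly one id in the distance "
            "matrix must be outside all subgroups"
        )
    return leftovers[0]
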