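"""Greedy extraction of the largest clusters from neighbor sets.

Repeatedly the decoy with the most remaining neighbors is reported and
its whole neighbor set removed, both from the pool and from every other
neighbor set. Ties are broken toward the lowest input index so the output
is deterministic and oracle-comparable. Cluster sizes are the counts at
extraction time; later rounds shrink as members are removed, so sizes
need not be monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighbors import NeighborSet

__all__ = ["ClusterRanking", "ClusterRound", "extract_clusters", "best_decoy_only"]


@dataclass(frozen=True)
class ClusterRound:
    rank: int  # 1-based
    representative: int
    members: np.ndarray  # sorted decoy indices removed this round
    size: int = None  # count at extraction; len(members) unless best-only

    def __post_init__(self):
        if self.size is None:
            object.__setattr__(self, "size", int(self.members.size))


@dataclass
class ClusterRanking:
    """Ordered rounds of greedy largest-cluster extraction."""

    rounds: list[ClusterRound]

    def __len__(self) -> int:
        return len(self.rounds)

    def __iter__(self):
        return iter(self.rounds)

    def top(self, k: int) -> list[ClusterRound]:
        return self.rounds[:k]

    def labels(self, n_decoys: int) -> np.ndarray:
        """Round index (0-based) per decoy; -1 for decoys never ranked."""
        lab = np.full(n_decoys, -1, dtype=int)
        for rnd in self.rounds:
            lab[rnd.members] = rnd.rank - 1
        return lab


def extract_clusters(neighbor_sets: list[NeighborSet]) -> ClusterRanking:
    """Greedy extraction until the pool is empty.

    Relies on the symmetry of the neighbor relation (X in N_Y iff
    Y in N_X) for the removal bookkeeping.
    """
    sets: dict[int, set[int]] = {ns.owner: set(ns.members.tolist()) for ns in neighbor_sets}
    alive = set(sets)
    rounds: list[ClusterRound] = []
    rank = 0
    while alive:
        rank += 1
        best = min(alive, key=lambda i: (-len(sets[i]), i))
        members = sets[best]
        for y in members:
            for z in sets[y]:
                if z not in members:
                    sets[z].discard(y)
        for y in members:
            del sets[y]
        alive -= members
        rounds.append(
            ClusterRound(rank=rank, representative=best, members=np.array(sorted(members), dtype=int))
        )
    return ClusterRanking(rounds=rounds)


def best_decoy_only(decoys, grouping, metrics, d: float, counters=None) -> tuple[int, int]:
    """First-round winner from neighbor *counts* only (linear memory).

    Returns ``(decoy index, neighbor count)``; equals round 1 of the full
    extraction. Member lists are never materialised.
    """
    from .neighbors import find_neighbors
    from .trace import DecoySet

    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("no decoys to rank")
    counts = find_neighbors(decoys, grouping, metrics, d, counters=counters, count_only=True)
    winner = int(np.argmax(counts))  # argmax takes the lowest index on ties
    return winner, int(counts[winner])
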