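"""Neighbor-set construction: exact, but screened by groups and bounds.

For every decoy A the neighbor set N_A contains all decoys within the
threshold d (A included). Groups are examined with a fixed cascade; every
branch is one-sided sound, so the output is element-for-element identical
to the brute-force all-pairs computation:

group level (C = group center, r = group radius)
  Case 1  A's own group is admitted wholesale (requires 2r <= d);
  Case 2  an upper bound of d(A,C) <= d - r admits the group;
  Case 3  a lower bound of d(A,C) > d + r rejects the group;
  else the exact d(A,C) is computed and Cases 2/3 re-tested exactly;
member level (X in group, dist(C,X) recorded at grouping time)
  Case 4  d(A,C) + dist(C,X) <= d admits X;
  Case 5  |d(A,C) - dist(C,X)| > d rejects X;
  then pairwise upper bounds (reference, rRMSD), lower bounds
  (reference, signature), and finally the exact RMSD.

Per-case tallies are kept so the pruning profile can be inspected; the
tallies sum to the total number of pair decisions (n per query decoy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .grouping import Grouping
from .rmsd import PrecomputedMetrics, rmsd_one_to_many
from .trace import DecoySet

__all__ = ["CaseCounters", "NeighborSet", "within_threshold", "find_neighbors", "brute_force_neighbors"]


@dataclass
class CaseCounters:
    """Tallies of pair decisions by the branch that resolved them."""

    case1: int = 0  # own-group wholesale admission
    case2_bound: int = 0  # group admitted via upper bound on d(A,C)
    case2_exact: int = 0  # group admitted via exact d(A,C)
    case3_bound: int = 0  # group rejected via lower bound on d(A,C)
    case3_exact: int = 0  # group rejected via exact d(A,C)
    case4: int = 0  # member admitted via d(A,C) + dist(C,X)
    case5: int = 0  # member rejected via |d(A,C) - dist(C,X)|
    pair_upper: int = 0  # member admitted via reference/rRMSD upper bound
    pair_lower: int = 0  # member rejected via reference/signature lower bound
    pair_exact: int = 0  # member resolved by exact RMSD

    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def resolved_without_exact(self) -> int:
        return self.total() - self.pair_exact

    def to_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_table(self) -> str:
        """Tab-separated table: case label, tally, percentage of all pair decisions."""
        total = max(self.total(), 1)
        lines = ["case\tcount\tpercent"]
        for name, count in self.to_dict().items():
            lines.append(f"{name}\t{count}\t{100.0 * count / total:.2f}")
        return "\n".join(lines)


@dataclass
class NeighborSet:
    """All decoys within d of ``owner`` (owner included), as sorted indices."""

    owner: int
    members: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.members.size


def within_threshold(
    metrics: PrecomputedMetrics,
    coords: np.ndarray,
    x: int,
    y: int,
    d: float,
    counters: CaseCounters | None = None,
) -> bool:
    """Decide RMSD(x, y) <= d with bound pre-checks, exact as a last resort.

    Check order: reference upper bounds, rRMSD, reference lower bounds,
    signature lower bound, exact RMSD. Every branch agrees with the exact
    comparison.
    """
    if counters is None:
        counters = CaseCounters()
    yy = np.array([y])
    if metrics.ref_upper(x, yy)[0] <= d or metrics.rrmsd_many(x, yy)[0] <= d:
        counters.pair_upper += 1
        return True
    if metrics.ref_lower(x, yy)[0] > d or metrics.sig_lower(x, yy)[0] > d:
        counters.pair_lower += 1
        return False
    counters.pair_exact += 1
    return bool(rmsd_one_to_many(coords[x], coords[y][None])[0] <= d)


def _member_stage(
    coords, metrics, counters, a, members, member_dists, d_ac, d, use_bounds
):
    """Cases 4/5 then pairwise bounds then exact, for one group's members."""
    inside = np.zeros(members.size, dtype=bool)
    undecided = np.ones(members.size, dtype=bool)

    m4 = d_ac + member_dists <= d
    inside[m4] = True
    undecided &= ~m4
    counters.case4 += int(m4.sum())

    m5 = undecided & (np.abs(d_ac - member_dists) > d)
    undecided &= ~m5
    counters.case5 += int(m5.sum())

    if use_bounds and undecided.any():
        idx = members[undecided]
        up = (metrics.ref_upper(a, idx) <= d) | (metrics.rrmsd_many(a, idx) <= d)
        pos = np.nonzero(undecided)[0]
        inside[pos[up]] = True
        undecided[pos[up]] = False
        counters.pair_upper += int(up.sum())
        if undecided.any():
            idx = members[undecided]
            lo = (metrics.ref_lower(a, idx) > d) | (metrics.sig_lower(a, idx) > d)
            pos = np.nonzero(undecided)[0]
            undecided[pos[lo]] = False
            counters.pair_lower += int(lo.sum())

    if undecided.any():
        idx = members[undecided]
        exact = rmsd_one_to_many(coords[a], coords[idx])
        inside[undecided] = exact <= d
        counters.pair_exact += int(undecided.sum())

    return members[inside]


def find_neighbors(
    decoys,
    grouping: Grouping,
    metrics: PrecomputedMetrics,
    d: float,
    counters: CaseCounters | None = None,
    use_bounds: bool = True,
    use_groups: bool = True,
    count_only: bool = False,
):
    """Neighbor sets for all decoys via the group/bounds cascade.

    With ``count_only=True`` only per-decoy neighbor counts are returned
    (an ``(N,)`` int array); member lists are never materialised, keeping
    memory linear in the set size. Otherwise a list of ``NeighborSet`` is
    returned, set-equal to the brute-force result.
    """
    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    N = coords.shape[0]
    if counters is None:
        counters = CaseCounters()
    if not use_groups:
        grouping = _singleton_grouping(N)

    centers = np.asarray(grouping.centers, dtype=int)
    sizes = np.array([m.size for m in grouping.members])
    case1_ok = 2.0 * grouping.radius_r <= d

    counts = np.zeros(N, dtype=np.int64) if count_only else None
    out: list[NeighborSet] = []

    for a in range(N):
        member_chunks: list[np.ndarray] = []
        own = int(grouping.group_of[a])

        decided = np.zeros(centers.size, dtype=bool)
        admit = np.zeros(centers.size, dtype=bool)
        if case1_ok:
            decided[own] = admit[own] = True
            counters.case1 += int(sizes[own])

        todo = ~decided
        if use_bounds and todo.any():
            idx = centers[todo]
            ub = np.minimum(metrics.ref_upper(a, idx), metrics.rrmsd_many(a, idx))
            hit = ub <= d - grouping.radius_r
            pos = np.nonzero(todo)[0]
            admit[pos[hit]] = decided[pos[hit]] = True
            counters.case2_bound += int(sizes[pos[hit]].sum())
            todo = ~decided
            if todo.any():
                idx = centers[todo]
                lb = np.maximum(metrics.ref_lower(a, idx), metrics.sig_lower(a, idx))
                miss = lb > d + grouping.radius_r
                pos = np.nonzero(todo)[0]
                decided[pos[miss]] = True  # rejected
                counters.case3_bound += int(sizes[pos[miss]].sum())
                todo = ~decided

        # exact center distances for groups the bounds could not settle
        open_groups = np.nonzero(todo)[0]
        if open_groups.size:
            d_ac = rmsd_one_to_many(coords[a], coords[centers[open_groups]])
            for g, dist in zip(open_groups, d_ac):
                if dist + grouping.radius_r <= d:
                    admit[g] = True
                    counters.case2_exact += int(sizes[g])
                elif dist > d + grouping.radius_r:
                    counters.case3_exact += int(sizes[g])
                else:
                    chunk = _member_stage(
                        coords, metrics, counters, a,
                        grouping.members[g], grouping.member_dists[g],
                        float(dist), d, use_bounds,
                    )
                    if chunk.size:
                        member_chunks.append(chunk)

        for g in np.nonzero(admit)[0]:
            member_chunks.append(grouping.members[g])

        if count_only:
            counts[a] = sum(c.size for c in member_chunks)
        else:
            members = (
                np.sort(np.concatenate(member_chunks)) if member_chunks else np.empty(0, dtype=int)
            )
            out.append(NeighborSet(owner=a, members=members))

    return counts if count_only else out


def brute_force_neighbors(decoys, d: float, counters: CaseCounters | None = None):
    """All-pairs exact neighbor sets (the strategies-off oracle path)."""
    from .rmsd import rmsd_matrix

    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    D = rmsd_matrix(coords)
    N = coords.shape[0]
    if counters is not None:
        counters.pair_exact += N * N
    return [NeighborSet(owner=i, members=np.nonzero(D[i] <= d)[0]) for i in range(N)]


def _singleton_grouping(N: int) -> Grouping:
    """Degenerate grouping (every decoy its own center) for the --no-groups ablation."""
    g = Grouping(radius_r=0.0)
    g.centers = list(range(N))
    g.members = [[i] for i in range(N)]
    g.member_dists = [[0.0] for _ in range(N)]
    g.finalize(N)
    return g
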