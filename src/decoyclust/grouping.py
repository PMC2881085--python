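"""Leader clustering of decoys into auxiliary groups of radius r.

Decoys are scanned in input order; each joins the first existing center
within Cα RMSD ``r`` (centers in creation order), else becomes a new
center. Member-to-center distances are recorded because the neighbor
search reuses them for triangle-inequality decisions. Lower-bound
screening (reference / signature) may skip centers that cannot qualify;
assignments are identical to the unscreened algorithm because a lower
bound above r proves the exact distance is above r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rmsd import PrecomputedMetrics, rmsd_one_to_many
from .trace import DecoySet

__all__ = ["Grouping", "build_groups"]


@dataclass
class Grouping:
    """Partition of decoys into leader groups of radius ``radius_r`` (Å).

    Every decoy belongs to exactly one group; centers belong to their own
    group at distance 0. ``group_of[i]`` / ``dist_to_center[i]`` give the
    assignment for decoy ``i``.
    """

    radius_r: float
    centers: list[int] = field(default_factory=list)
    members: list[list[int]] = field(default_factory=list)
    member_dists: list[list[float]] = field(default_factory=list)
    group_of: np.ndarray | None = None
    dist_to_center: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return len(self.centers)

    def finalize(self, n_decoys: int) -> None:
        self.group_of = np.empty(n_decoys, dtype=int)
        self.dist_to_center = np.empty(n_decoys, dtype=float)
        for g, (mem, dists) in enumerate(zip(self.members, self.member_dists)):
            for i, dist in zip(mem, dists):
                self.group_of[i] = g
                self.dist_to_center[i] = dist
        self.members = [np.asarray(m, dtype=int) for m in self.members]
        self.member_dists = [np.asarray(d, dtype=float) for d in self.member_dists]


def build_groups(
    decoys,
    r: float,
    metrics: PrecomputedMetrics | None = None,
) -> Grouping:
    """Sequential leader algorithm over decoys in set order.

    ``metrics`` enables lower-bound screening of center candidates; it
    never changes the resulting partition, only skips provably
    non-qualifying exact computations.
    """
    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    if r <= 0:
        raise ValueError("group radius r must be > 0")
    N = coords.shape[0]
    grouping = Grouping(radius_r=float(r))
    centers_arr: list[int] = grouping.centers

    for i in range(N):
        assigned = False
        if centers_arr:
            cand = np.asarray(centers_arr, dtype=int)
            if metrics is not None:
                lb = np.maximum(metrics.ref_lower(i, cand), metrics.sig_lower(i, cand))
                cand = cand[lb <= r]
            if cand.size:
                dists = rmsd_one_to_many(coords[i], coords[cand])
                hits = np.nonzero(dists <= r)[0]
                if hits.size:
                    first = hits[0]  # first qualifying center in creation order
                    g = centers_arr.index(int(cand[first]))
                    grouping.members[g].append(i)
                    grouping.member_dists[g].append(float(dists[first]))
                    assigned = True
        if not assigned:
            centers_arr.append(i)
            grouping.members.append([i])
            grouping.member_dists.append([0.0])

    grouping.finalize(N)
    return grouping
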