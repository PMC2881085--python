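"""Automatic discovery of the clustering threshold d.

Two decoys are considered significantly related when their Cα RMSD is
small *relative to* the set's pairwise-distance distribution. The default
method therefore targets the x-th percentile of pairwise distances,
estimated from repeated small random samples rather than the full
quadratic matrix; x itself shrinks with the set size as
``min(100 * n**-0.25, 10)`` so that larger sets cluster at a tighter
threshold. A mode-based alternative sets ``d = c*f + b`` from the most
frequent sampled distance f and the minimum sampled distance b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rmsd import rmsd_one_to_many
from .trace import DecoySet

__all__ = [
    "ThresholdSpec",
    "default_percentile",
    "percentile_threshold",
    "mostfreq_threshold",
    "THRESHOLD_MODES",
]

THRESHOLD_MODES = {
    "fixed": "use the threshold d given on the command line as-is",
    "percentile": "d such that ~x percent of sampled pairwise RMSDs fall below it "
    "(default; x = min(100*n^-1/4, 10) unless given)",
    "mostfreq": "d = c*f + b, f = most frequent sampled pairwise RMSD, "
    "b = minimum sampled pairwise RMSD",
}


@dataclass
class ThresholdSpec:
    """Resolved threshold choice plus the knobs that produced it."""

    mode: str
    d: float
    x: float | None = None
    n_rounds: int = 10
    sample_size: int = 100
    c: float = 2.0 / 3.0
    b: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.d <= 0:
            raise ValueError("resolved threshold d must be > 0")
        if self.x is not None and not (0 < self.x <= 100):
            raise ValueError("percentile x must be in (0, 100]")


def default_percentile(n: int) -> float:
    """Default percentile x for a set of n decoys: min(100*n^-1/4, 10)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(min(100.0 * n ** (-0.25), 10.0))


def _coords(decoys) -> np.ndarray:
    return decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)


def _sample_pair_distances(coords, n_rounds, sample_size, rng):
    """Within-sample pairwise RMSDs for each of n_rounds random samples."""
    N = coords.shape[0]
    k = min(sample_size, N)
    rounds = []
    for _ in range(n_rounds):
        idx = np.sort(rng.choice(N, size=k, replace=False))
        sub = coords[idx]
        vals = [rmsd_one_to_many(sub[i], sub[i + 1 :]) for i in range(k - 1)]
        rounds.append(np.concatenate(vals))
    return rounds


def percentile_threshold(
    decoys,
    x: float,
    n_rounds: int = 10,
    sample_size: int = 100,
    seed: int | None = None,
) -> float:
    """Sampled x-percentile of pairwise Cα RMSDs, medianed over rounds.

    Each round draws ``sample_size`` decoys without replacement (the whole
    set if smaller), computes all within-sample pairwise RMSDs and takes
    the x-th percentile with linear interpolation; the median of the round
    estimates is returned. Deterministic given ``seed``.
    """
    coords = _coords(decoys)
    if coords.shape[0] < 2:
        raise ValueError("cannot estimate threshold from fewer than 2 decoys")
    if not (0 < x <= 100):
        raise ValueError("percentile x must be in (0, 100]")
    rng = np.random.default_rng(seed)
    estimates = [np.percentile(vals, x) for vals in _sample_pair_distances(coords, n_rounds, sample_size, rng)]
    return float(np.median(estimates))


def mostfreq_threshold(
    decoys,
    c: float = 2.0 / 3.0,
    n_rounds: int = 10,
    sample_size: int = 100,
    seed: int | None = None,
) -> float:
    """Mode-based threshold d = c*f + b from sampled pairwise RMSDs.

    f is the center of the densest Freedman–Diaconis histogram bin of the
    pooled sampled distances; b is the minimum sampled distance.
    """
    coords = _coords(decoys)
    if coords.shape[0] < 2:
        raise ValueError("cannot estimate threshold from fewer than 2 decoys")
    rng = np.random.default_rng(seed)
    pool = np.concatenate(_sample_pair_distances(coords, n_rounds, sample_size, rng))
    b = float(pool.min())
    if np.ptp(pool) == 0:  # all sampled distances identical
        f = float(pool[0])
    else:
        edges = np.histogram_bin_edges(pool, bins="fd")
        if edges.size < 3:  # FD degenerates (tiny IQR); fall back to sturges
            edges = np.histogram_bin_edges(pool, bins="sturges")
        counts, edges = np.histogram(pool, bins=edges)
        k = int(np.argmax(counts))
        f = float(0.5 * (edges[k] + edges[k + 1]))
    return c * f + b
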