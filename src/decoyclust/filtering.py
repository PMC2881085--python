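"""Outlier filtering before clustering.

A decoy is kept iff it lies within 2d of at least one of ``sample_size``
randomly drawn decoys. The rationale: if a decoy X is within d of some
well-connected decoy A (one with at least 10% of the set within d), then
a random probe lands within d of A — hence within 2d of X by the triangle
inequality — with probability 0.1 per draw, so X survives with
probability 1 - 0.9**sample_size (> 0.9999 at 100). Decoys failing the
test are unlikely to sit near any high-ranking decoy and are dropped.

Sampled decoys are trivially kept (distance 0 to themselves). Signature
lower bounds screen out probes that provably cannot rescue a decoy; the
result equals the exact rule. The filter runs before metric
precomputation, so it relies only on signatures and on-demand RMSDs.
"""

from __future__ import annotations

import numpy as np

from .rmsd import rmsd_one_to_many
from .trace import DecoySet

__all__ = ["filter_outliers", "retention_probability"]


def retention_probability(sample_size: int, neighbor_fraction: float = 0.1) -> float:
    """Probability that a decoy near a well-connected decoy survives the filter."""
    return 1.0 - (1.0 - neighbor_fraction) ** sample_size


def filter_outliers(
    decoys,
    d: float,
    sample_size: int = 100,
    seed: int | None = None,
    signatures: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split decoy indices into (kept, removed) by the 2d-to-sample rule.

    Deterministic given ``seed``. ``signatures`` (per-decoy centroid
    distance vectors) may be passed to reuse a precomputation; they only
    screen, never change the outcome.
    """
    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    if d <= 0:
        raise ValueError("threshold d must be > 0")
    N = coords.shape[0]
    rng = np.random.default_rng(seed)
    k = min(sample_size, N)
    sample = np.sort(rng.choice(N, size=k, replace=False))

    if signatures is None:
        centered = coords - coords.mean(axis=1, keepdims=True)
        signatures = np.linalg.norm(centered, axis=2)

    keep = np.zeros(N, dtype=bool)
    keep[sample] = True
    cutoff = 2.0 * d
    sig_sample = signatures[sample]
    for i in np.nonzero(~keep)[0]:
        diff = signatures[i] - sig_sample
        lb = np.sqrt(np.mean(diff * diff, axis=1))
        cand = sample[lb <= cutoff]  # probes the lower bound cannot rule out
        if cand.size and np.any(rmsd_one_to_many(coords[i], coords[cand]) <= cutoff):
            keep[i] = True

    return np.nonzero(keep)[0], np.nonzero(~keep)[0]
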