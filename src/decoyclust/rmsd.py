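"""Optimal-superposition Cα RMSD and the cheap bounds derived from it.

The distance between two equal-length Cα traces is the root-mean-square
point deviation minimised over all proper rotations and translations
(Kabsch superposition). This distance is a metric, which is what makes
triangle-inequality pruning sound. Three families of cheap bounds are
precomputed per decoy and reused throughout the pipeline:

* **reference-decoy bounds** — for a reference decoy O with precomputed
  distances, ``|d(X,O) - d(Y,O)| <= d(X,Y) <= d(X,O) + d(Y,O)``;
* **rRMSD** (upper bound) — the plain Euclidean RMS deviation between two
  decoys after each has been optimally superposed onto one fixed anchor
  decoy; no re-superposition is done per pair;
* **signature distance** (lower bound) — the RMS difference of the two
  per-residue centroid-distance vectors ("signatures"); superposition makes
  centroids coincide, and per-residue deviation can never fall below the
  difference of the two centroid distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace import CaTrace, DecoySet

__all__ = [
    "SuperpositionResult",
    "PrecomputedMetrics",
    "superpose",
    "rmsd",
    "rmsd_one_to_many",
    "rmsd_matrix",
    "compute_signature",
    "signature_distance",
    "precompute_metrics",
    "rrmsd",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of trace ``a`` onto trace ``b``.

    ``rotation`` is a proper rotation (det +1; reflections are excluded by
    the usual determinant sign correction). A point ``x`` of ``a`` maps to
    ``rotation @ x + translation``, which takes the centroid of ``a`` onto
    the centroid of ``b``.
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_coords(a) -> np.ndarray:
    if isinstance(a, CaTrace):
        return a.coords
    return np.asarray(a, dtype=float)


def _kabsch_terms(P: np.ndarray, Q: np.ndarray):
    """SVD of the cross-covariance of two *centered* point sets.

    Returns (U, S, Vt, sign) where sign corrects for reflections.
    """
    M = P.T @ Q
    U, S, Vt = np.linalg.svd(M)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    if sign == 0:  # rank-deficient: any completion works, pick +1
        sign = 1.0
    return U, S, Vt, sign


def superpose(a, b) -> SuperpositionResult:
    """Optimal (Kabsch) superposition of trace ``a`` onto trace ``b``.

    Raises ``ValueError`` on unequal lengths. Degenerate (e.g. collinear)
    inputs still return a minimiser; SVD handles rank deficiency.
    """
    A, B = _as_coords(a), _as_coords(b)
    if A.shape != B.shape:
        raise ValueError(f"length mismatch: {A.shape[0]} vs {B.shape[0]} residues")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    P, Q = A - ca, B - cb
    U, S, Vt, sign = _kabsch_terms(P, Q)
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    # explicit residuals: immune to the cancellation the trace formula
    # suffers when the two traces are (near-)rigid copies
    resid = P @ R.T - Q
    return SuperpositionResult(
        rotation=R, translation=cb - R @ ca, rmsd=float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    )


def rmsd(a, b) -> float:
    """Cα RMSD between two equal-length traces, in Å."""
    return superpose(a, b).rmsd


def rmsd_one_to_many(a, many: np.ndarray) -> np.ndarray:
    """Cα RMSD of one trace against a batch, via batched 3×3 SVD.

    Parameters
    ----------
    a : (n, 3) array or CaTrace
    many : (m, n, 3) array

    Returns
    -------
    (m,) array of RMSDs in Å.
    """
    A = _as_coords(a)
    B = np.asarray(many, dtype=float)
    if B.ndim == 2:
        B = B[None]
    if B.shape[1:] != A.shape:
        raise ValueError(f"length mismatch: {A.shape} vs {B.shape[1:]}")
    n = A.shape[0]
    P = A - A.mean(axis=0)
    Q = B - B.mean(axis=1, keepdims=True)
    M = np.einsum("ni,mnj->mij", P, Q)
    U, S, Vt = np.linalg.svd(M)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    sign[sign == 0] = 1.0
    D = np.zeros((M.shape[0], 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = sign
    R = np.einsum("mji,mjk,mlk->mil", Vt, D, U)  # rotates P onto Q_m
    resid = np.einsum("ni,mji->mnj", P, R) - Q
    return np.sqrt(np.einsum("mni,mni->m", resid, resid) / n)


def rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Full symmetric pairwise Cα RMSD matrix (the brute-force quadratic path)."""
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    D = np.zeros((N, N))
    for i in range(N - 1):
        D[i, i + 1 :] = rmsd_one_to_many(coords[i], coords[i + 1 :])
    return D + D.T


def compute_signature(a) -> np.ndarray:
    """Per-residue distances to the trace centroid, in residue order.

    The order is deliberately *not* sorted: the lower-bound argument pairs
    residue k of one trace with residue k of the other.
    """
    A = _as_coords(a)
    return np.linalg.norm(A - A.mean(axis=0), axis=1)


def signature_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """RMS difference of two signatures; a lower bound of the Cα RMSD."""
    s1, s2 = np.asarray(s1, dtype=float), np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"length mismatch: {s1.shape} vs {s2.shape}")
    return float(np.sqrt(np.mean((s1 - s2) ** 2)))


@dataclass
class PrecomputedMetrics:
    """Per-decoy quantities enabling cheap RMSD bounds.

    Attributes
    ----------
    signatures : (N, n) array
        Centroid-distance signature of each decoy.
    ref_indices : (m,) int array
        Indices of the reference decoys O_1..O_m.
    ref_distances : (N, m) array
        ``ref_distances[X, k]`` = Cα RMSD(X, O_k).
    oriented : (N, n, 3) array
        Each decoy centered and optimally rotated onto the anchor decoy
        (the first reference); pairwise Euclidean RMS deviation of these
        is the rRMSD upper bound.
    """

    signatures: np.ndarray
    ref_indices: np.ndarray
    ref_distances: np.ndarray
    oriented: np.ndarray

    @property
    def anchor(self) -> int:
        return int(self.ref_indices[0])

    # --- vectorised bounds: decoy x against a batch of decoy indices ---

    def ref_upper(self, x: int, idx) -> np.ndarray:
        return np.min(self.ref_distances[x] + self.ref_distances[idx], axis=-1)

    def ref_lower(self, x: int, idx) -> np.ndarray:
        return np.max(np.abs(self.ref_distances[x] - self.ref_distances[idx]), axis=-1)

    def sig_lower(self, x: int, idx) -> np.ndarray:
        diff = self.signatures[x] - self.signatures[idx]
        return np.sqrt(np.mean(diff * diff, axis=-1))

    def rrmsd_many(self, x: int, idx) -> np.ndarray:
        diff = self.oriented[x] - self.oriented[idx]
        return np.sqrt(np.einsum("...ni,...ni->...", diff, diff) / self.oriented.shape[1])


def precompute_metrics(decoys, m_refs: int = 3, seed: int | None = None) -> PrecomputedMetrics:
    """Compute signatures, reference distances and anchor-oriented coordinates.

    Reference decoys are chosen deterministically for spread: the first
    decoy, the decoy farthest from it, the decoy farthest from that one,
    then (for ``m_refs > 3``) repeated max-min selection. ``seed`` is
    accepted for interface stability; the default policy is deterministic.
    """
    coords = decoys.coords if isinstance(decoys, DecoySet) else np.asarray(decoys, dtype=float)
    N, n, _ = coords.shape
    if N == 0:
        raise ValueError("empty decoy set")
    if m_refs < 1:
        raise ValueError("m_refs must be >= 1")
    if m_refs > N:
        warnings.warn(f"m_refs={m_refs} exceeds set size {N}; clamping", stacklevel=2)
        m_refs = N

    centered = coords - coords.mean(axis=1, keepdims=True)
    signatures = np.linalg.norm(centered, axis=2)

    refs: list[int] = [0]
    cols = [rmsd_one_to_many(coords[0], coords)]
    while len(refs) < m_refs:
        if len(refs) < 3:
            cand = int(np.argmax(cols[-1]))  # farthest from the previous reference
        else:
            cand = int(np.argmax(np.min(np.stack(cols), axis=0)))  # max-min spread
        if cand in refs:  # duplicate geometry; fall back to first unused index
            cand = next(i for i in range(N) if i not in refs)
        refs.append(cand)
        cols.append(rmsd_one_to_many(coords[cand], coords))
    ref_indices = np.array(refs, dtype=int)
    ref_distances = np.stack(cols, axis=1)

    # orient every decoy onto the centered anchor (first reference)
    anchor = centered[refs[0]]
    M = np.einsum("mni,nj->mij", centered, anchor)
    U, S, Vt = np.linalg.svd(M)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    sign[sign == 0] = 1.0
    D = np.zeros((N, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = sign
    # rotation mapping decoy -> anchor frame: R_m = V D U^T; apply to rows
    R = np.einsum("mji,mjk,mlk->mil", Vt, D, U)
    oriented = np.einsum("mni,mji->mnj", centered, R)

    return PrecomputedMetrics(
        signatures=signatures,
        ref_indices=ref_indices,
        ref_distances=ref_distances,
        oriented=oriented,
    )


def rrmsd(metrics: PrecomputedMetrics, x: int, y: int) -> float:
    """Euclidean RMS deviation of two anchor-oriented decoys (≥ their Cα RMSD)."""
    return float(metrics.rrmsd_many(x, np.array([y]))[0])
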