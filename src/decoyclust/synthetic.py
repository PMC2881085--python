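"""Synthetic decoy ensembles with known ground truth.

Every pipeline stage is testable without external data: planted clusters
are Gaussian perturbations of protein-like random backbones, outliers are
independent backbones, and every decoy is given a random rigid pose (the
clustering must be pose-invariant). Backbones are self-avoiding random
walks with the canonical consecutive-Cα step of 3.8 Å and a 3.0 Å
excluded-volume floor between non-consecutive residues — geometrically
protein-like, with no claim to Ramachandran realism.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .rmsd import rmsd_one_to_many
from .trace import CaTrace, DecoySet

__all__ = ["random_backbone", "make_ensemble", "write_ensemble"]

CA_STEP = 3.8  # consecutive Calpha-Calpha distance, Å
MIN_NONCONSEC = 3.0  # excluded-volume floor for non-consecutive pairs, Å


def random_backbone(
    n_residues: int,
    seed: int | np.random.Generator | None = None,
    max_restarts: int = 200,
    max_step_tries: int = 60,
) -> CaTrace:
    """Self-avoiding random walk of ``n_residues`` Cα positions.

    Deterministic given ``seed``. Raises ``RuntimeError`` if the walk
    cannot be completed within the retry budget.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n_residues and ok:
            for _ in range(max_step_tries):
                v = rng.normal(size=3)
                v *= CA_STEP / np.linalg.norm(v)
                cand = pts[-1] + v
                prior = np.asarray(pts[:-1])
                if prior.size == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) >= MIN_NONCONSEC:
                    pts.append(cand)
                    break
            else:
                ok = False
        if ok:
            return CaTrace("backbone", np.asarray(pts))
    raise RuntimeError(f"self-avoiding walk failed for n_residues={n_residues}")


def _random_pose(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)  # uniform rotation via normalized quaternion
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-30.0, 30.0, size=3)
    return coords @ R.T + t


def _rejection_backbones(n_needed, n_residues, min_rmsd, against, rng, max_tries):
    """Random backbones pairwise (and vs ``against``) farther than min_rmsd in RMSD."""
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n_needed:
        if tries >= max_tries:
            raise RuntimeError(
                "rejection sampling exhausted; reduce separation or increase n_residues"
            )
        tries += 1
        cand = random_backbone(n_residues, rng).coords
        pool = against + out
        if all(rmsd_one_to_many(cand, ref[None])[0] > min_rmsd for ref in pool):
            out.append(cand)
    return out


def make_ensemble(
    n_clusters: int = 3,
    members_per_cluster: int = 30,
    n_outliers: int = 10,
    n_residues: int = 40,
    noise_sigma: float = 0.5,
    separation: float = 8.0,
    seed: int | None = None,
    max_tries: int = 2000,
) -> tuple[DecoySet, np.ndarray]:
    """Planted-cluster decoy ensemble with ground-truth labels.

    Cluster centers are backbones pairwise farther than ``separation`` in
    Cα RMSD; members add isotropic Gaussian noise (σ = ``noise_sigma`` Å
    per coordinate) to their center; outliers are independent backbones
    also farther than ``separation`` from every center and from each
    other. Every decoy then receives a random rigid pose. Labels: cluster
    id 0..k-1 for members, -1 for outliers. Decoy order is cluster by
    cluster, outliers last.
    """
    if separation <= 3.0 * noise_sigma:
        raise ValueError("separation must comfortably exceed the noise scale")
    rng = np.random.default_rng(seed)
    centers = _rejection_backbones(n_clusters, n_residues, separation, [], rng, max_tries)
    outlier_coords = _rejection_backbones(
        n_outliers, n_residues, separation, centers, rng, max_tries
    )

    coords, labels, names = [], [], []
    for c, center in enumerate(centers):
        for m in range(members_per_cluster):
            decoy = center + rng.normal(scale=noise_sigma, size=center.shape)
            coords.append(_random_pose(decoy, rng))
            labels.append(c)
            names.append(f"cluster{c}_member{m}")
    for o, out in enumerate(outlier_coords):
        coords.append(_random_pose(out, rng))
        labels.append(-1)
        names.append(f"outlier{o}")

    return DecoySet(names=names, coords=np.asarray(coords)), np.asarray(labels, dtype=int)


def write_ensemble(decoys: DecoySet, labels: np.ndarray, directory) -> Path:
    """Write an ensemble as PDB files + decoy-list file + labels JSON.

    Returns the path of the decoy list. Labels go to a sidecar
    ``labels.json`` (never into PDB fields).
    """
    from .io import write_ca_trace

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(decoys)):
        p = directory / f"decoy_{i:04d}.pdb"
        write_ca_trace(decoys[i], p)
        paths.append(p.name)
    list_path = directory / "decoys.list"
    list_path.write_text("# synthetic decoy ensemble\n" + "\n".join(paths) + "\n")
    (directory / "labels.json").write_text(
        json.dumps({"names": decoys.names, "labels": np.asarray(labels).tolist()})
    )
    return list_path
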