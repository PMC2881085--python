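"""Domain containers: a single Cα trace and an ordered set of equal-length traces.

A *decoy* is one candidate 3D structure from an ab initio structure
prediction run, represented here purely by the ordered coordinates of its
Cα atoms (one 3D point per residue, in Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CaTrace", "DecoySet"]


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one decoy.

    Parameters
    ----------
    name : str
        Identifier (typically the PDB file path or stem).
    coords : ndarray of shape (n, 3)
        Cα positions in Å, in residue order. ``n >= 3`` is required:
        rigid-body superposition is underdetermined below three points.
    """

    name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError(f"trace {self.name!r} has {coords.shape[0]} points; need >= 3")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"trace {self.name!r} contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class DecoySet:
    """A named, ordered collection of equal-length Cα traces.

    Stores coordinates as a single ``(n_decoys, n_residues, 3)`` array so
    that batched superposition can be vectorised. Decoy order is exactly
    construction order and is never permuted. Duplicate names are
    disambiguated by appending ``#<ordinal>``.
    """

    names: list[str]
    coords: np.ndarray  # (n_decoys, n_residues, 3)
    n_residues: int = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (N, n, 3), got {self.coords.shape}")
        if len(self.names) != self.coords.shape[0]:
            raise ValueError("names/coords length mismatch")
        self.n_residues = self.coords.shape[1]
        self.names = _uniquify(list(self.names))

    @classmethod
    def from_traces(cls, traces: list[CaTrace]) -> "DecoySet":
        if not traces:
            raise ValueError("no decoys")
        n = len(traces[0])
        for t in traces[1:]:
            if len(t) != n:
                raise ValueError(
                    f"length mismatch: decoy {traces[0].name!r} has {n} residues "
                    f"but decoy {t.name!r} has {len(t)}"
                )
        return cls(names=[t.name for t in traces], coords=np.stack([t.coords for t in traces]))

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> CaTrace:
        return CaTrace(self.names[i], self.coords[i])

    def subset(self, indices) -> "DecoySet":
        indices = np.asarray(indices, dtype=int)
        return DecoySet(names=[self.names[i] for i in indices], coords=self.coords[indices])


def _uniquify(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}#{seen[name]}")
        else:
            seen[name] = 1
            out.append(name)
    return out
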