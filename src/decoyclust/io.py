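"""Reading decoy lists and PDB Cα traces; writing clustering reports.

The PDB reader is deliberately minimal: it takes one point per ``ATOM``
record named ``CA`` (altloc blank or 'A'), in file order, from the first
model and first chain only (reading stops at the first TER). Columns
follow the fixed-width PDB v3.3 layout with a tolerant whitespace-split
fallback for slightly malformed files. No sequence validation is done —
the clustering uses coordinates only.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .trace import CaTrace, DecoySet

__all__ = [
    "read_decoy_list",
    "parse_ca_trace",
    "write_ca_trace",
    "load_decoy_set",
    "format_report",
    "format_json_report",
]


def read_decoy_list(path) -> list[Path]:
    """Paths from a decoy-list file, in file order.

    Blank lines and ``#`` comments are ignored; relative paths resolve
    against the list file's directory.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"decoy list not found: {path}")
    base = path.parent
    out: list[Path] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p = Path(line)
        out.append(p if p.is_absolute() else base / p)
    if not out:
        raise ValueError(f"no decoys listed in {path}")
    return out


def _parse_atom_line(line: str, lineno: int, path) -> tuple[str, str, np.ndarray]:
    """(atom name, altloc, xyz) from an ATOM record; fixed-width, then fallback."""
    try:
        name = line[12:16].strip()
        altloc = line[16:17]
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        return name, altloc, xyz
    except (ValueError, IndexError):
        pass
    # whitespace fallback: ATOM serial name resname [chain] resseq x y z ...
    # coordinates are the first three decimal-pointed numbers after the name
    fields = line.split()
    if len(fields) >= 6:
        name = fields[2]
        dotted = [f for f in fields[3:] if "." in f and _is_float(f)]
        if len(dotted) >= 3:
            return name, " ", np.array([float(v) for v in dotted[:3]])
    raise ValueError(f"{path}:{lineno}: unparseable ATOM record: {line.rstrip()!r}")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def parse_ca_trace(path, name: str | None = None) -> CaTrace:
    """One Cα point per residue from a PDB file.

    First model only; first chain only (stops at the first TER after any
    CA was read); altloc blank or 'A'. Raises on files with no CA atoms
    or unparseable coordinates (with line number).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"PDB file not found: {path}")
    pts: list[np.ndarray] = []
    truncated = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            head = line.split(None, 1)
            rec = head[0] if head else ""
            if rec == "ENDMDL":
                break
            if rec == "TER" and pts:
                truncated = True
                continue
            if rec == "ATOM":
                if truncated:
                    warnings.warn(
                        f"{path}: ATOM records beyond the first TER ignored "
                        "(single-chain convention)",
                        stacklevel=2,
                    )
                    break
                aname, altloc, xyz = _parse_atom_line(line, lineno, path)
                if aname == "CA" and altloc in (" ", "A", ""):
                    pts.append(xyz)
    if not pts:
        raise ValueError(f"no CA atoms found in {path}")
    return CaTrace(name or path.stem, np.asarray(pts))


def write_ca_trace(trace: CaTrace, path) -> None:
    """Write a Cα-only PDB file (one GLY residue per point, chain A)."""
    lines = []
    for i, (x, y, z) in enumerate(trace.coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def load_decoy_set(list_path) -> DecoySet:
    """DecoySet from a decoy-list file; all traces length-checked."""
    paths = read_decoy_list(list_path)
    traces = [parse_ca_trace(p) for p in paths]
    return DecoySet.from_traces(traces)


def format_report(result, show_members: bool = False) -> str:
    """Plain-text ranked report: rank, representative name, cluster size."""
    lines = [
        f"# threshold d = {result.threshold_:.4f} A ({result.threshold_spec_.mode})",
        f"# decoys: {result.n_decoys_} input, {len(result.filtered_idx_)} filtered out",
        "# rank\trepresentative\tsize" + ("\tmembers" if show_members else ""),
    ]
    for rnd in result.reported_rounds():
        row = f"{rnd.rank}\t{result.decoy_name(rnd.representative)}\t{rnd.size}"
        if show_members:
            row += "\t" + ",".join(result.decoy_name(m) for m in rnd.members)
        lines.append(row)
    return "\n".join(lines) + "\n"


def format_json_report(result, show_members: bool = False) -> str:
    """Machine-readable report: one JSON object per ranked cluster, one per line."""
    lines = []
    for rnd in result.reported_rounds():
        obj = {
            "rank": rnd.rank,
            "representative": result.decoy_name(rnd.representative),
            "size": int(rnd.size),
            "threshold": result.threshold_,
        }
        if show_members:
            obj["members"] = [result.decoy_name(m) for m in rnd.members]
        lines.append(json.dumps(obj))
    return "\n".join(lines) + "\n"
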