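"""Shared I/O: PDB structures, XYZ trajectories, TSV/JSON/YAML records,
and run manifests.

PDB reading is delegated to biotite (ATOM/HETATM records, occupancies,
altlocs); the altloc policy is "highest occupancy, ties to 'A'", and
residue numbering is preserved as deposited.  XYZ files are the plain
multi-frame flavour: an atom count line, a free-form comment line, then
``name x y z`` records in Å.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "read_yaml",
    "write_yaml",
    "write_json",
    "read_json",
    "RunManifest",
]


def read_pdb(path, altloc: str = "occupancy"):
    """Parse a PDB file into a biotite ``AtomArray``.

    ``altloc="occupancy"`` keeps, per atom, the alternate location with the
    highest occupancy (biotite resolves ties in favour of the first-listed
    altloc id, which is 'A' in a conformant file).  Raises ``ValueError``
    naming the offending line for malformed ATOM records.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        structure = pdb_file.get_structure(
            model=1, altloc=altloc, extra_fields=["occupancy", "b_factor"]
        )
    except Exception as exc:
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    return structure


def write_pdb(path, structure) -> None:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(structure)
    pdb_file.write(str(path))


def read_xyz(path):
    """Read a multi-frame XYZ file.

    Returns ``(names, frames, comments)``: atom names from the first frame,
    a (n_frames, n_atoms, 3) float array, and the per-frame comment lines.
    An empty file yields an empty trajectory.
    """
    names: list[str] = []
    frames = []
    comments = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{pos + 1}: expected atom count") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{pos + 1}: truncated frame (need {n} atoms)")
        coords = np.empty((n, 3))
        frame_names = []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{pos + 3 + k}: malformed atom line")
            frame_names.append(parts[0])
            coords[k] = [float(p) for p in parts[1:4]]
        if not names:
            names = frame_names
        frames.append(coords)
        comments.append(comment)
        pos += 2 + n
    traj = np.array(frames) if frames else np.empty((0, 0, 3))
    return names, traj, comments


def write_xyz(path, names, frames, comments=None) -> None:
    """Write frames (single (N,3) or stacked (M,N,3)) as multi-frame XYZ,
    coordinates at 6 decimals (sub-Å precision round trip)."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    if comments is None:
        comments = [f"frame {i}" for i in range(len(frames))]
    with open(path, "w", encoding="utf-8") as fh:
        for frame, comment in zip(frames, comments):
            fh.write(f"{len(names)}\n{comment}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_yaml(path):
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_yaml(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record attached to every pipeline output."""

    tool: str = "kemplab"
    version: str = ""
    config: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)
    created: str = ""

    def __post_init__(self):
        if not self.version:
            from kemplab import __version__

            self.version = __version__
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.input_checksums[str(path)] = file_sha256(path)

    def write(self, path) -> None:
        write_json(path, asdict(self))
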