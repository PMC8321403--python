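"""Readers and writers for coordinates and trajectories.

GRO and PDB files go through MDAnalysis (converted to nm on read; PDB files
are stored in Angstrom and divided by 10). Multi-frame binary trajectories
(XTC/TRR/DCD) are also read through MDAnalysis. In addition a self-contained
plain-text ``frames_txt`` dialect is supported for fixtures:

    N box_x box_y box_z time
    x y z          (N lines)
    ...repeated per frame

with lengths in nm and times in ns. Floats are written with 17 significant
digits so a write/read round trip is bitwise exact.

Only orthorhombic boxes are accepted; triclinic inputs raise ValueError.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .topology import CG_BEAD_MASS, NA, ParticleTopology
from .trajectory import Frame, Trajectory

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_trajectory",
    "write_frames_txt",
    "read_frames_txt",
]

_ANGLE_TOL = 1e-3


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None:
        raise ValueError("file carries no box information")
    lx, ly, lz, alpha, beta, gamma = [float(v) for v in dimensions]
    if any(abs(a - 90.0) > _ANGLE_TOL for a in (alpha, beta, gamma)):
        raise ValueError(
            f"triclinic box (angles {alpha}, {beta}, {gamma}) not supported; "
            "only orthorhombic boxes are handled")
    return np.array([lx, ly, lz]) / 10.0  # A -> nm


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"gro", "pdb"}:
        return suffix
    if suffix in {"txt", "frames"}:
        return "frames_txt"
    raise ValueError(f"cannot infer format from {path}; pass format= explicitly")


def read_coordinates(path, format: str | None = None):
    """Read a single-frame coordinate file.

    Returns ``(ParticleTopology, Frame)``. Region, species, leaflet and role
    labels are not present in standard formats and are left NA / 'other';
    apply a sidecar annotation table afterwards. Each residue becomes its own
    molecule; the annotation step may regroup.
    """
    fmt = _infer_format(path, format)
    if fmt == "frames_txt":
        frames = read_frames_txt(path)
        n = frames[0].n_particles
        topo = ParticleTopology.from_records(
            [{"name": "X", "molecule_kind": "solvent", "molecule_id": i,
              "residue_index": i + 1, "residue_name": "UNK"} for i in range(n)])
        return topo, frames[0]
    if fmt not in {"gro", "pdb"}:
        raise ValueError(f"unsupported coordinate format {fmt!r}")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(os.fspath(path))
        except Exception as exc:  # normalize parser failures
            raise ValueError(f"failed to parse {path}: {exc}") from exc
    box = _check_orthorhombic(u.dimensions)
    atoms = u.atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        time_ns = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0) / 1000.0
    try:
        chain_ids = [str(c) for c in atoms.chainIDs]
    except (AttributeError, mda.exceptions.NoDataError):
        try:
            chain_ids = [str(s) for s in atoms.segids]
        except (AttributeError, mda.exceptions.NoDataError):
            chain_ids = [""] * len(atoms)
    chain_ids = ["" if c in {"SYSTEM", "X"} else c for c in chain_ids]
    resindices = atoms.resindices
    records = []
    for i, atom in enumerate(atoms):
        records.append({
            "name": str(atom.name), "molecule_kind": "solvent",
            "molecule_id": int(resindices[i]), "residue_index": int(atom.resid),
            "residue_name": str(atom.resname), "chain_id": chain_ids[i],
            "mass": CG_BEAD_MASS,
        })
    topo = ParticleTopology.from_records(records)
    coords = atoms.positions.astype(float) / 10.0
    return topo, Frame(coords, box, time_ns)


def _as_universe(topology: ParticleTopology, frame: Frame):
    import MDAnalysis as mda

    n = topology.n_particles
    # residues keyed by (chain, resid, resname) in order of first appearance
    keys = list(zip(topology.chain_id, topology.residue_index, topology.residue_name))
    uniq: dict = {}
    res_of_atom = []
    for k in keys:
        if k not in uniq:
            uniq[k] = len(uniq)
        res_of_atom.append(uniq[k])
    n_res = len(uniq)
    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=np.array(res_of_atom),
                           residue_segindex=np.zeros(n_res, dtype=int), trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in topology.names])
    u.add_TopologyAttr("resids", [int(k[1]) for k in uniq])
    u.add_TopologyAttr("resnames", [str(k[2]) for k in uniq])
    # empty chain ids surface as "X" in PDB output; the reader maps X back to ""
    u.add_TopologyAttr("chainIDs", [str(c)[:1] if c else "X" for c in topology.chain_id])
    u.add_TopologyAttr("masses", topology.mass)
    u.atoms.positions = frame.coordinates * 10.0
    u.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
    return u


def write_coordinates(path, topology: ParticleTopology, frame: Frame,
                      format: str | None = None) -> None:
    """Write a single frame as GRO, PDB, or frames_txt."""
    fmt = _infer_format(path, format)
    if fmt == "frames_txt":
        write_frames_txt(path, [frame])
        return
    if fmt not in {"gro", "pdb"}:
        raise ValueError(f"unsupported coordinate format {fmt!r}")
    u = _as_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(os.fspath(path))


# ----------------------------------------------------------------------
# frames_txt dialect
# ----------------------------------------------------------------------

def write_frames_txt(path, frames) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            bx, by, bz = fr.box
            fh.write(f"{fr.n_particles} {bx:.17g} {by:.17g} {bz:.17g} {fr.time:.17g}\n")
            for x, y, z in fr.coordinates:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def read_frames_txt(path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 5:
            raise ValueError(f"{path}:{i + 1}: expected header 'N bx by bz time', got {lines[i]!r}")
        try:
            n = int(header[0])
            box = np.array([float(v) for v in header[1:4]])
            time = float(header[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: malformed header: {exc}") from exc
        if i + n >= n_lines:
            raise ValueError(
                f"{path}: truncated frame {len(frames)} (header at line {i + 1} "
                f"promises {n} particles, file ends early)")
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 1 + j].split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{i + 2 + j}: expected 'x y z', got {lines[i + 1 + j]!r}")
            try:
                coords[j] = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{i + 2 + j}: malformed coordinate: {exc}") from exc
        frames.append(Frame(coords, box, time))
        i += 1 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def read_trajectory(path, topology: ParticleTopology,
                    frame_interval: float = 0.2, format: str | None = None) -> Trajectory:
    """Read a multi-frame trajectory against a known topology.

    frames_txt is parsed natively; other formats (XTC/TRR/DCD/multi-model
    PDB) go through MDAnalysis. Missing or constant time stamps are
    synthesized as ``0, dt, 2 dt, ...`` from ``frame_interval`` (ns).
    """
    fmt = format
    if fmt is None:
        suffix = Path(path).suffix.lower().lstrip(".")
        fmt = "frames_txt" if suffix in {"txt", "frames"} else suffix
    if fmt == "frames_txt":
        frames = read_frames_txt(path)
        for i, fr in enumerate(frames):
            if fr.n_particles != topology.n_particles:
                raise ValueError(
                    f"frame {i} has {fr.n_particles} particles, topology has "
                    f"{topology.n_particles}")
    else:
        import MDAnalysis as mda

        u = mda.Universe.empty(topology.n_particles, trajectory=True)
        u.load_new(os.fspath(path))
        frames = []
        for ts in u.trajectory:
            box = _check_orthorhombic(ts.dimensions)
            frames.append(Frame(ts.positions.astype(float) / 10.0, box,
                                float(ts.time) / 1000.0))
    times = np.array([fr.time for fr in frames])
    if len(frames) > 1 and not np.all(np.diff(times) > 0):
        if np.allclose(times, times[0]):
            for i, fr in enumerate(frames):
                fr.time = i * frame_interval
        else:
            raise ValueError("non-increasing frame times in trajectory")
    return Trajectory(topology, frames)
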