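"""Particle-level system description and selections.

The topology records, for every particle, its molecule, residue, chain,
protein region (ECD / TMR / CYR), lipid species and leaflet, and a coarse
functional role (backbone, headgroup, phosphate, nitrogen, acyl, sterol, ...).
These labels drive every grouping used by the analysis modules: per-residue
contact fingerprints are keyed by (chain_id, residue_index), per-species
normalizers count lipid molecules, and leaflet-resolved maps filter on the
leaflet label.

Standard coordinate formats carry none of region/species/leaflet/role, so
they are supplied by a sidecar annotation table (TSV) keyed by chain and
residue range for protein rows and by residue name for lipid rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOLECULE_KINDS",
    "REGIONS",
    "ROLES",
    "LEAFLETS",
    "NA",
    "ParticleTopology",
    "Selection",
    "read_annotation_table",
    "write_annotation_table",
    "apply_annotations",
]

NA = "NA"
MOLECULE_KINDS = ("protein", "lipid", "solvent", "ion")
REGIONS = ("ECD", "TMR", "CYR", NA)
LEAFLETS = ("outer", "inner", NA)
ROLES = ("backbone", "sidechain", "headgroup", "phosphate", "nitrogen", "acyl", "sterol", "other")

#: Default coarse-grained bead mass (amu), Martini convention.
CG_BEAD_MASS = 72.0


@dataclass
class ParticleTopology:
    """Columnar per-particle identity table.

    All fields are 1-D arrays of equal length N. ``molecule_id`` groups
    particles into molecules (one lipid, one protein chain complex, one
    water...); every particle of a molecule shares ``molecule_kind``.
    """

    names: np.ndarray
    molecule_kind: np.ndarray
    molecule_id: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    region: np.ndarray
    lipid_species: np.ndarray
    leaflet: np.ndarray
    role: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        arrays = {
            "names": object, "molecule_kind": object, "molecule_id": np.int64,
            "residue_index": np.int64, "residue_name": object, "chain_id": object,
            "region": object, "lipid_species": object, "leaflet": object,
            "role": object, "mass": float,
        }
        for attr, dtype in arrays.items():
            arr = np.asarray(getattr(self, attr))
            if dtype is object:
                arr = arr.astype(str).astype(object)
            else:
                arr = arr.astype(dtype)
            if arr.shape != (n,):
                raise ValueError(f"topology field {attr!r} has shape {arr.shape}, expected ({n},)")
            setattr(self, attr, arr)

    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_particles

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if np.any(self.mass <= 0):
            raise ValueError("all particle masses must be > 0")
        df = self.to_frame()
        kinds_per_mol = df.groupby("molecule_id")["molecule_kind"].nunique()
        if (kinds_per_mol > 1).any():
            bad = kinds_per_mol[kinds_per_mol > 1].index.tolist()
            raise ValueError(f"molecules with mixed molecule_kind: {bad}")
        prot = df[df.molecule_kind == "protein"]
        if (prot.region == NA).any():
            raise ValueError("every protein particle must carry a region label")
        lip = df[df.molecule_kind == "lipid"]
        if (lip.lipid_species == NA).any() or (lip.leaflet == NA).any():
            raise ValueError("every lipid particle must carry species and leaflet labels")
        for col, allowed in (("molecule_kind", MOLECULE_KINDS), ("region", REGIONS),
                             ("leaflet", LEAFLETS), ("role", ROLES)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise ValueError(f"unknown {col} values: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names, "molecule_kind": self.molecule_kind,
            "molecule_id": self.molecule_id, "residue_index": self.residue_index,
            "residue_name": self.residue_name, "chain_id": self.chain_id,
            "region": self.region, "lipid_species": self.lipid_species,
            "leaflet": self.leaflet, "role": self.role, "mass": self.mass,
        })

    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "ParticleTopology":
        """Build from an iterable of per-particle dicts; missing labels -> NA."""
        cols: dict[str, list] = {k: [] for k in (
            "name", "molecule_kind", "molecule_id", "residue_index", "residue_name",
            "chain_id", "region", "lipid_species", "leaflet", "role", "mass")}
        defaults = {"region": NA, "lipid_species": NA, "leaflet": NA,
                    "role": "other", "chain_id": "", "mass": CG_BEAD_MASS}
        for rec in records:
            for k in cols:
                cols[k].append(rec.get(k, defaults.get(k)))
        return cls(
            names=np.array(cols["name"], dtype=object),
            molecule_kind=np.array(cols["molecule_kind"], dtype=object),
            molecule_id=np.array(cols["molecule_id"]),
            residue_index=np.array(cols["residue_index"]),
            residue_name=np.array(cols["residue_name"], dtype=object),
            chain_id=np.array(cols["chain_id"], dtype=object),
            region=np.array(cols["region"], dtype=object),
            lipid_species=np.array(cols["lipid_species"], dtype=object),
            leaflet=np.array(cols["leaflet"], dtype=object),
            role=np.array(cols["role"], dtype=object),
            mass=np.array(cols["mass"], dtype=float),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["ParticleTopology"]) -> "ParticleTopology":
        """Stack topologies, renumbering molecule_ids to stay unique."""
        offset = 0
        mol_ids = []
        for p in parts:
            ids = p.molecule_id
            mol_ids.append(ids + offset)
            if len(ids):
                offset += ids.max() + 1
        kw = {}
        for attr in ("names", "molecule_kind", "residue_index", "residue_name",
                     "chain_id", "region", "lipid_species", "leaflet", "role", "mass"):
            kw[attr] = np.concatenate([getattr(p, attr) for p in parts])
        return cls(molecule_id=np.concatenate(mol_ids) if mol_ids else np.array([], dtype=int), **kw)


_SELECTION_FIELDS = {
    "region": "region",
    "chain_id": "chain_id",
    "species": "lipid_species",
    "leaflet": "leaflet",
    "role": "role",
    "molecule_kind": "molecule_kind",
    "residue_name": "residue_name",
    "name": "names",
}


@dataclass(frozen=True)
class Selection:
    """Conjunctive predicate over topology fields.

    Each set field restricts to particles whose attribute is in the given
    value(s); ``residue_range`` is an inclusive ``(lo, hi)`` on
    ``residue_index``; ``indices`` restricts to an explicit particle set.
    Resolution is deterministic (ascending indices) and a pure function of
    the topology.
    """

    region: str | Sequence[str] | None = None
    chain_id: str | Sequence[str] | None = None
    species: str | Sequence[str] | None = None
    leaflet: str | None = None
    role: str | Sequence[str] | None = None
    molecule_kind: str | None = None
    residue_name: str | Sequence[str] | None = None
    name: str | Sequence[str] | None = None
    residue_range: tuple[int, int] | None = None
    indices: tuple[int, ...] | None = None

    def resolve(self, topology: ParticleTopology) -> np.ndarray:
        """Return the sorted particle index array matching the predicate."""
        mask = np.ones(topology.n_particles, dtype=bool)
        for field_name, attr in _SELECTION_FIELDS.items():
            value = getattr(self, field_name)
            if value is None:
                continue
            values = [value] if isinstance(value, str) else list(value)
            mask &= np.isin(getattr(topology, attr), values)
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (topology.residue_index >= lo) & (topology.residue_index <= hi)
        if self.indices is not None:
            idx_mask = np.zeros(topology.n_particles, dtype=bool)
            idx_mask[np.asarray(self.indices, dtype=int)] = True
            mask &= idx_mask
        return np.flatnonzero(mask)


def resolve_selection(sel: Selection, topology: ParticleTopology) -> np.ndarray:
    """Functional alias for :meth:`Selection.resolve`."""
    return sel.resolve(topology)


# ----------------------------------------------------------------------
# Annotation sidecar table
# ----------------------------------------------------------------------

_ANNOT_COLUMNS = ["kind", "chain_id", "res_start", "res_end", "region",
                  "species", "leaflet", "role_map"]


def read_annotation_table(path) -> pd.DataFrame:
    """Read the sidecar annotation TSV.

    Rows with ``kind == protein`` map ``(chain_id, res_start..res_end)`` to a
    region; rows with ``kind == lipid`` map a residue name (``species``
    column doubles as the match key) to species/leaflet and a per-particle
    role map of the form ``"NAME:role,NAME:role"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns: {sorted(missing)}")
    return df


def write_annotation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _parse_role_map(text: str) -> dict[str, str]:
    mapping = {}
    for item in filter(None, (s.strip() for s in text.split(","))):
        name, _, role = item.partition(":")
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} in role_map entry {item!r}")
        mapping[name] = role
    return mapping


def apply_annotations(topology: ParticleTopology, table: pd.DataFrame) -> ParticleTopology:
    """Return a copy of ``topology`` with labels filled from the table."""
    topo = ParticleTopology(**{k: np.copy(getattr(topology, k)) for k in (
        "names", "molecule_kind", "molecule_id", "residue_index", "residue_name",
        "chain_id", "region", "lipid_species", "leaflet", "role", "mass")})
    for _, row in table.iterrows():
        if row["kind"] == "protein":
            mask = topo.chain_id == row["chain_id"]
            if row["res_start"] and row["res_end"]:
                lo, hi = int(row["res_start"]), int(row["res_end"])
                mask &= (topo.residue_index >= lo) & (topo.residue_index <= hi)
            topo.molecule_kind[mask] = "protein"
            if row["region"]:
                topo.region[mask] = row["region"]
            if row["role_map"]:
                for nm, role in _parse_role_map(row["role_map"]).items():
                    topo.role[mask & (topo.names == nm)] = role
        elif row["kind"] == "lipid":
            mask = topo.residue_name == row["species"]
            topo.molecule_kind[mask] = "lipid"
            topo.lipid_species[mask] = row["species"]
            if row["leaflet"]:
                topo.leaflet[mask] = row["leaflet"]
            if row["role_map"]:
                for nm, role in _parse_role_map(row["role_map"]).items():
                    topo.role[mask & (topo.names == nm)] = role
        else:
            raise ValueError(f"unknown annotation row kind {row['kind']!r}")
    return topo


def assign_leaflets_by_midplane(topology: ParticleTopology, coords: np.ndarray) -> ParticleTopology:
    """Assign lipid leaflets from the first frame's phosphate-z midplane.

    Lipids whose phosphate (or sterol) reference bead sits above the mean
    reference z are labelled ``outer``, the rest ``inner``. Valid for planar,
    non-flipping membranes.
    """
    topo = ParticleTopology(**{k: np.copy(getattr(topology, k)) for k in (
        "names", "molecule_kind", "molecule_id", "residue_index", "residue_name",
        "chain_id", "region", "lipid_species", "leaflet", "role", "mass")})
    is_lipid = topo.molecule_kind == "lipid"
    is_ref = is_lipid & np.isin(topo.role, ["phosphate", "sterol"])
    if not is_ref.any():
        raise ValueError("no phosphate/sterol reference beads to assign leaflets from")
    midplane = coords[is_ref, 2].mean()
    for mol in np.unique(topo.molecule_id[is_lipid]):
        mol_mask = topo.molecule_id == mol
        ref = mol_mask & is_ref
        z = coords[ref, 2].mean() if ref.any() else coords[mol_mask, 2].mean()
        topo.leaflet[mol_mask] = "outer" if z > midplane else "inner"
    return topo
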