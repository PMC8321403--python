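"""Protein-lipid and protein-protein contact analysis under PBC.

A residue and a lipid are "in contact" in a frame when any particle of the
residue lies within the distance cutoff (minimum image, orthorhombic box)
of any particle of the lipid — 0.55 nm for coarse-grained systems, 0.4 nm
for atomistic ones. On top of raw contacts this module produces the
normalized profiles used for membrane-protein interaction fingerprinting:

* per-residue x per-species fingerprint N = n1 / n2 / n3, where n1 counts
  residue-lipid contact frames, n2 is the number of lipids of that species
  in the bilayer and n3 the number of frames analysed;
* acyl-chain (membrane core) contact profiles normalized by the *total*
  lipid count and frame count;
* contacts of selected residues with lipid nitrogen atoms (choline/amine),
  per species;
* per-frame bound-lipid time series for low-abundance species (PIP2/PIP3)
  with cubic polynomial smoothing;
* inter-chain contact profiles with per-dimer max normalization;
* 0-1 min-max scaling, per species or global.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pbc import wrap_coordinates
from .topology import ParticleTopology, Selection
from .trajectory import Frame, Trajectory

__all__ = [
    "CG_CUTOFF",
    "AT_CUTOFF",
    "ContactFingerprint",
    "find_contacts",
    "contact_pairs",
    "fingerprint",
    "acyl_contact_profile",
    "nitrogen_contact_counts",
    "minmax_scale",
    "bound_lipid_timeseries",
    "interchain_contact_profile",
]

#: Contact cutoffs (nm) for coarse-grained and atomistic inputs.
CG_CUTOFF = 0.55
AT_CUTOFF = 0.4


def _resolve(sel, topology: ParticleTopology) -> np.ndarray:
    if isinstance(sel, Selection):
        return sel.resolve(topology)
    return np.asarray(sel, dtype=int)


def _unit_codes(topology: ParticleTopology, idx: np.ndarray, group: str):
    """Integer unit code per particle plus the unit key table."""
    if group == "residue":
        keys = pd.MultiIndex.from_arrays(
            [topology.chain_id[idx], topology.residue_index[idx]],
            names=["chain_id", "residue_index"])
        codes, uniques = pd.factorize(keys)
        return codes, list(uniques)
    if group == "molecule":
        codes, uniques = pd.factorize(topology.molecule_id[idx])
        return codes, [int(u) for u in uniques]
    if group == "particle":
        return np.arange(len(idx)), [int(i) for i in idx]
    raise ValueError(f"unknown grouping {group!r}")


def contact_pairs(coords: np.ndarray, box: np.ndarray, idx_a: np.ndarray,
                  idx_b: np.ndarray, cutoff: float) -> np.ndarray:
    """Particle index pairs (a, b) within ``cutoff`` under the minimum image.

    Periodic cell-list search via a KD-tree with box topology; the result
    equals the all-pairs minimum-image oracle exactly. ``cutoff`` must be
    below half the smallest box edge or the minimum image is ambiguous.
    """
    box = np.asarray(box, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if cutoff > box.min() / 2.0:
        raise ValueError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({box.min() / 2.0} nm); minimum image is invalid")
    a = wrap_coordinates(coords[idx_a], box)
    b = wrap_coordinates(coords[idx_b], box)
    tree = cKDTree(b, boxsize=box)
    hits = tree.query_ball_point(a, r=cutoff)
    pairs = [(i, j) for i, lst in enumerate(hits) for j in lst]
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.array(pairs, dtype=int)


def find_contacts(frame: Frame, topology: ParticleTopology, group_a, group_b,
                  cutoff: float, unit_a: str = "residue",
                  unit_b: str = "molecule") -> set:
    """Set of contacting (unit_a, unit_b) pairs in one frame.

    Units are residues ``(chain_id, residue_index)``, molecule ids, or raw
    particle indices depending on the grouping. The two groups must be
    disjoint at particle level.
    """
    idx_a = _resolve(group_a, topology)
    idx_b = _resolve(group_b, topology)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("contact groups must be disjoint at particle level")
    codes_a, units_a = _unit_codes(topology, idx_a, unit_a)
    codes_b, units_b = _unit_codes(topology, idx_b, unit_b)
    pairs = contact_pairs(frame.coordinates, frame.box, idx_a, idx_b, cutoff)
    return {(units_a[codes_a[i]], units_b[codes_b[j]]) for i, j in pairs}


@dataclass
class ContactFingerprint:
    """Raw and normalized per-residue x per-species contact fingerprint.

    ``n1`` holds raw contact-frame counts (rows: residues, columns:
    species), ``n2`` the per-species lipid counts in the membrane, ``n3``
    the number of frames analysed. ``normalized`` is N = n1 / n2 / n3.
    """

    n1: pd.DataFrame
    n2: pd.Series
    n3: int

    @property
    def normalized(self) -> pd.DataFrame:
        return self.n1.div(self.n2, axis=1) / self.n3

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with raw and normalized values."""
        long = self.n1.stack().rename("n1").reset_index()
        long.columns = ["chain_id", "residue_index", "species", "n1"]
        long["n2"] = long["species"].map(self.n2)
        long["n3"] = self.n3
        long["N"] = long["n1"] / long["n2"] / long["n3"]
        return long


def _species_lipid_counts(topology: ParticleTopology) -> pd.Series:
    lip = topology.molecule_kind == "lipid"
    df = pd.DataFrame({"mol": topology.molecule_id[lip],
                       "species": topology.lipid_species[lip]})
    return df.groupby("species")["mol"].nunique()


def fingerprint(traj: Trajectory, cutoff: float = CG_CUTOFF,
                protein_sel: Selection | np.ndarray | None = None,
                species: list[str] | None = None,
                count_mode: str = "per_lipid") -> ContactFingerprint:
    """Contact fingerprint N = n1 / n2 / n3 over a trajectory.

    By default a residue contacting k lipids of one species in one frame
    contributes k to n1 (``count_mode='per_lipid'``); with
    ``count_mode='per_frame'`` it contributes 1.
    """
    topo = traj.topology
    idx_p = _resolve(protein_sel, topo) if protein_sel is not None else \
        Selection(molecule_kind="protein").resolve(topo)
    if len(idx_p) == 0:
        raise ValueError("empty protein selection")
    counts = _species_lipid_counts(topo)
    if species is None:
        species = list(counts.index)
    missing = [s for s in species if counts.get(s, 0) == 0]
    if missing:
        raise ValueError(f"species with zero lipids in the membrane: {missing}")
    idx_l = Selection(molecule_kind="lipid", species=species).resolve(topo)

    codes_p, residues = _unit_codes(topo, idx_p, "residue")
    codes_l, mols = _unit_codes(topo, idx_l, "molecule")
    sp_of_mol = {}
    for k, m in enumerate(mols):
        sp_of_mol[k] = topo.lipid_species[idx_l[codes_l == k][0]]
    sp_index = {s: i for i, s in enumerate(species)}

    n1 = np.zeros((len(residues), len(species)), dtype=np.int64)
    for f in range(traj.n_frames):
        pairs = contact_pairs(traj.coordinates[f], traj.boxes[f], idx_p, idx_l, cutoff)
        if len(pairs) == 0:
            continue
        units = np.unique(np.column_stack([codes_p[pairs[:, 0]], codes_l[pairs[:, 1]]]), axis=0)
        res_codes = units[:, 0]
        spc = np.array([sp_index[sp_of_mol[m]] for m in units[:, 1]])
        if count_mode == "per_lipid":
            np.add.at(n1, (res_codes, spc), 1)
        elif count_mode == "per_frame":
            seen = np.unique(np.column_stack([res_codes, spc]), axis=0)
            np.add.at(n1, (seen[:, 0], seen[:, 1]), 1)
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
    index = pd.MultiIndex.from_tuples(residues, names=["chain_id", "residue_index"])
    n1_df = pd.DataFrame(n1, index=index, columns=species)
    n2 = pd.Series({s: int(counts[s]) for s in species})
    return ContactFingerprint(n1=n1_df, n2=n2, n3=traj.n_frames)


def acyl_contact_profile(traj: Trajectory, cutoff: float = CG_CUTOFF,
                         residue_sel: Selection | np.ndarray | None = None) -> pd.Series:
    """Per-residue contacts with lipid acyl (hydrophobic core) particles.

    Normalizer is the total lipid count (all species) times the frame
    count — the membrane-penetration profile convention, distinct from the
    per-species fingerprint normalizer.
    """
    topo = traj.topology
    idx_r = _resolve(residue_sel, topo) if residue_sel is not None else \
        Selection(molecule_kind="protein").resolve(topo)
    if len(idx_r) == 0:
        raise ValueError("empty residue selection")
    idx_acyl = Selection(molecule_kind="lipid", role="acyl").resolve(topo)
    if len(idx_acyl) == 0:
        raise ValueError("no acyl-role lipid particles annotated")
    total_lipids = int(_species_lipid_counts(topo).sum())
    codes_r, residues = _unit_codes(topo, idx_r, "residue")
    codes_l, _ = _unit_codes(topo, idx_acyl, "molecule")
    raw = np.zeros(len(residues), dtype=np.int64)
    for f in range(traj.n_frames):
        pairs = contact_pairs(traj.coordinates[f], traj.boxes[f], idx_r, idx_acyl, cutoff)
        if len(pairs) == 0:
            continue
        units = np.unique(np.column_stack([codes_r[pairs[:, 0]], codes_l[pairs[:, 1]]]), axis=0)
        np.add.at(raw, units[:, 0], 1)
    index = pd.MultiIndex.from_tuples(residues, names=["chain_id", "residue_index"])
    return pd.Series(raw / (total_lipids * traj.n_frames), index=index, name="acyl_profile")


def nitrogen_contact_counts(traj: Trajectory, cutoff: float = AT_CUTOFF,
                            residue_sel: Selection | np.ndarray | None = None) -> pd.Series:
    """Contacts of selected residues with lipid nitrogen particles, per species."""
    topo = traj.topology
    if residue_sel is None:
        raise ValueError("a residue selection is required")
    idx_r = _resolve(residue_sel, topo)
    if len(idx_r) == 0:
        raise ValueError("empty residue selection")
    idx_n = Selection(molecule_kind="lipid", role="nitrogen").resolve(topo)
    species_present = sorted(set(topo.lipid_species[idx_n])) if len(idx_n) else []
    counts = {s: 0 for s in ("POPC", "POPE", "DPSM")}
    for s in species_present:
        counts.setdefault(s, 0)
    if len(idx_n) == 0:
        return pd.Series(counts, name="nitrogen_contacts")
    codes_r, _ = _unit_codes(topo, idx_r, "residue")
    codes_l, mols = _unit_codes(topo, idx_n, "molecule")
    sp_of_code = {k: topo.lipid_species[idx_n[codes_l == k][0]] for k in range(len(mols))}
    for f in range(traj.n_frames):
        pairs = contact_pairs(traj.coordinates[f], traj.boxes[f], idx_r, idx_n, cutoff)
        if len(pairs) == 0:
            continue
        units = np.unique(np.column_stack([codes_r[pairs[:, 0]], codes_l[pairs[:, 1]]]), axis=0)
        for _, mcode in units:
            counts[sp_of_code[mcode]] += 1
    return pd.Series(counts, name="nitrogen_contacts")


def minmax_scale(profile, mode: str = "per_species"):
    """Scale values to [0, 1]; the maximum maps to 1, zeros stay 0.

    ``per_species`` scales each column of a DataFrame independently;
    ``per_system`` divides everything by the global maximum. All-zero input
    is returned unchanged with a warning.
    """
    if mode not in {"per_species", "per_system"}:
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(profile, pd.DataFrame):
        values = profile.to_numpy(dtype=float)
        if not (values > 0).any():
            warnings.warn("min-max scaling an all-zero profile", stacklevel=2)
            return profile.astype(float)
        if mode == "per_system":
            return profile / values.max()
        maxima = profile.max(axis=0).replace(0, np.nan)
        return profile.div(maxima, axis=1).fillna(0.0)
    series = pd.Series(profile, dtype=float)
    top = series.max()
    if top <= 0:
        warnings.warn("min-max scaling an all-zero profile", stacklevel=2)
        return series
    return series / top


def bound_lipid_timeseries(traj: Trajectory, cutoff: float = CG_CUTOFF,
                           species: tuple[str, ...] = ("PIP2", "PIP3"),
                           protein_sel: Selection | np.ndarray | None = None,
                           smooth_degree: int | None = 3):
    """Per-frame normalized bound-lipid count for the given species.

    For each frame the number of distinct lipids of a species within
    ``cutoff`` of any protein particle is divided by that species' count in
    the membrane. The smoothed curve is a least-squares polynomial fit
    (default cubic) over time; requires more frames than the degree.

    Returns ``(series, smoothed)`` DataFrames indexed by time (ns);
    ``smoothed`` is None when ``smooth_degree`` is None.
    """
    topo = traj.topology
    idx_p = _resolve(protein_sel, topo) if protein_sel is not None else \
        Selection(molecule_kind="protein").resolve(topo)
    counts = _species_lipid_counts(topo)
    missing = [s for s in species if counts.get(s, 0) == 0]
    if missing:
        raise ValueError(f"species absent from the membrane: {missing}")
    if smooth_degree is not None and traj.n_frames <= smooth_degree:
        raise ValueError(
            f"need more than {smooth_degree} frames for a degree-{smooth_degree} fit")
    data = np.zeros((traj.n_frames, len(species)))
    sel_cache = {s: Selection(molecule_kind="lipid", species=s).resolve(topo)
                 for s in species}
    for f in range(traj.n_frames):
        for k, s in enumerate(species):
            idx_l = sel_cache[s]
            pairs = contact_pairs(traj.coordinates[f], traj.boxes[f], idx_p, idx_l, cutoff)
            n_bound = len(np.unique(topo.molecule_id[idx_l[pairs[:, 1]]])) if len(pairs) else 0
            data[f, k] = n_bound / counts[s]
    series = pd.DataFrame(data, index=pd.Index(traj.times, name="time_ns"),
                          columns=list(species))
    smoothed = None
    if smooth_degree is not None:
        sm = np.empty_like(data)
        for k in range(len(species)):
            poly = np.polynomial.Polynomial.fit(traj.times, data[:, k], smooth_degree)
            sm[:, k] = poly(traj.times)
        smoothed = pd.DataFrame(sm, index=series.index, columns=series.columns)
    return series, smoothed


def interchain_contact_profile(traj: Trajectory, cutoff: float,
                               chain_a_sel, chain_b_sel) -> pd.DataFrame:
    """Per-residue inter-chain contact counts for both chains of a dimer.

    Every contacting residue pair contributes to both chains' profiles;
    normalization divides by the largest count within the dimer (both
    profiles share one maximum). Returns a long-format DataFrame with
    columns side, chain_id, residue_index, count, normalized.
    """
    topo = traj.topology
    idx_a = _resolve(chain_a_sel, topo)
    idx_b = _resolve(chain_b_sel, topo)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty chain selection")
    if len(idx_a) == len(idx_b) and np.array_equal(np.sort(idx_a), np.sort(idx_b)):
        raise ValueError("chain selections are identical")
    codes_a, res_a = _unit_codes(topo, idx_a, "residue")
    codes_b, res_b = _unit_codes(topo, idx_b, "residue")
    raw_a = np.zeros(len(res_a), dtype=np.int64)
    raw_b = np.zeros(len(res_b), dtype=np.int64)
    for f in range(traj.n_frames):
        pairs = contact_pairs(traj.coordinates[f], traj.boxes[f], idx_a, idx_b, cutoff)
        if len(pairs) == 0:
            continue
        units = np.unique(np.column_stack([codes_a[pairs[:, 0]], codes_b[pairs[:, 1]]]), axis=0)
        np.add.at(raw_a, units[:, 0], 1)
        np.add.at(raw_b, units[:, 1], 1)
    top = max(raw_a.max(initial=0), raw_b.max(initial=0))
    rows = []
    for side, keys, raw in (("A", res_a, raw_a), ("B", res_b, raw_b)):
        for (chain, resid), value in zip(keys, raw):
            rows.append({"side": side, "chain_id": chain, "residue_index": resid,
                         "count": int(value),
                         "normalized": value / top if top > 0 else 0.0})
    return pd.DataFrame(rows)
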