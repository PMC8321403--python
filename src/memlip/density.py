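"""Protein-fixed lateral lipid density and enrichment maps.

To see where lipids accumulate around a membrane protein, each frame is
first rigidly moved so the protein sits at the box center in a fixed
orientation: a lateral translation brings the reference selection's COM to
the center, then a rotation about z (the membrane normal) minimizes the XY
RMSD of the reference selection to the reference frame. Restricting the
rotation to z keeps leaflets intact. Headgroup reference beads (phosphate,
or sterol for cholesterol) of each species/leaflet are then binned on an XY
grid; dividing the per-bin mean number density by the species' bulk areal
density gives an enrichment map (1 = bulk-like, > 1 = enriched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import ParticleTopology, Selection
from .trajectory import Trajectory

__all__ = ["DensityGrid", "align_frames", "optimal_z_rotation",
           "density_map", "enrichment_map"]


@dataclass
class DensityGrid:
    """Accumulated 2D lateral histogram for one (species, leaflet)."""

    counts: np.ndarray          # (nx, ny)
    bin_size: float
    origin: tuple[float, float]
    species: str
    leaflet: str
    n_frames: int
    n_lipids: int

    @property
    def mean_number(self) -> np.ndarray:
        """Mean lipid count per bin per frame."""
        return self.counts / self.n_frames

    def to_frame(self, mode: str = "counts") -> pd.DataFrame:
        if mode == "counts":
            values = self.counts
        elif mode == "mean_number":
            values = self.mean_number
        else:
            raise ValueError(f"unknown mode {mode!r}")
        nx, ny = self.counts.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame({
            "x_bin": self.origin[0] + (ii.ravel() + 0.5) * self.bin_size,
            "y_bin": self.origin[1] + (jj.ravel() + 0.5) * self.bin_size,
            "value": values.ravel(),
        })


def optimal_z_rotation(current_xy: np.ndarray, reference_xy: np.ndarray) -> float:
    """Angle (rad) of the z-rotation minimizing RMSD of centered XY sets.

    Closed-form 2D Kabsch: theta = atan2(sum(x b_y - y b_x), sum(x b_x + y b_y))
    for current points (x, y) against reference points b.
    """
    a = current_xy - current_xy.mean(axis=0)
    b = reference_xy - reference_xy.mean(axis=0)
    num = float((a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum())
    den = float((a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]).sum())
    return float(np.arctan2(num, den))


def align_frames(traj: Trajectory, reference_frame: int = 0,
                 reference_sel=None) -> Trajectory:
    """Fix the reference selection's lateral position and orientation.

    Every frame is translated in XY so the reference selection's COM sits
    at the box center, then rotated about z (through the box center) by the
    angle minimizing the selection's XY RMSD to its configuration in
    ``reference_frame``. z coordinates are untouched. Coordinates are not
    re-wrapped: a rotated lipid may leave the primary cell, which the
    gridders treat as out-of-grid.

    Assumes the reference selection does not straddle a periodic boundary
    (true after protein-centered preprocessing).
    """
    topo = traj.topology
    if reference_sel is None:
        reference_sel = Selection(molecule_kind="protein", role="backbone")
    idx = reference_sel.resolve(topo) if isinstance(reference_sel, Selection) \
        else np.asarray(reference_sel, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty reference selection")
    m = topo.mass[idx]
    box = traj.boxes[0]
    center = np.array([box[0] / 2.0, box[1] / 2.0])

    # reference configuration: centered XY of the reference frame's selection
    ref_xy = traj.coordinates[reference_frame][idx, :2]
    ref_centered = ref_xy - (ref_xy * m[:, None]).sum(axis=0) / m.sum()

    out = traj.coordinates.copy()
    for f in range(traj.n_frames):
        sel_xy = out[f][idx, :2]
        com_xy = (sel_xy * m[:, None]).sum(axis=0) / m.sum()
        out[f, :, 0] += center[0] - com_xy[0]
        out[f, :, 1] += center[1] - com_xy[1]
        theta = optimal_z_rotation(out[f][idx, :2] - center, ref_centered)
        c, s = np.cos(theta), np.sin(theta)
        rel = out[f, :, :2] - center
        out[f, :, :2] = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                                         s * rel[:, 0] + c * rel[:, 1]]) + center
    return Trajectory.from_arrays(topo, out, traj.boxes.copy(), traj.times.copy())


def density_map(traj: Trajectory, species: str, leaflet: str,
                bin_size: float = 0.2) -> DensityGrid:
    """Accumulate headgroup reference beads of one species on an XY grid.

    Expects an aligned trajectory when the map is to be read relative to
    the protein. The grid covers the full box; observations outside (only
    possible after rotation) are dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    topo = traj.topology
    idx = Selection(molecule_kind="lipid", species=species, leaflet=leaflet,
                    role=["phosphate", "sterol"]).resolve(topo)
    box = traj.boxes[0]
    nx, ny = int(np.ceil(box[0] / bin_size)), int(np.ceil(box[1] / bin_size))
    counts = np.zeros((nx, ny))
    if len(idx) == 0:
        warnings.warn(f"no {species} lipids in {leaflet} leaflet; empty grid",
                      stacklevel=2)
        return DensityGrid(counts, bin_size, (0.0, 0.0), species, leaflet,
                           traj.n_frames, 0)
    for f in range(traj.n_frames):
        xy = traj.coordinates[f][idx, :2]
        inside = (xy[:, 0] >= 0) & (xy[:, 0] < box[0]) & \
                 (xy[:, 1] >= 0) & (xy[:, 1] < box[1])
        ix = (xy[inside, 0] // bin_size).astype(int)
        iy = (xy[inside, 1] // bin_size).astype(int)
        np.add.at(counts, (np.minimum(ix, nx - 1), np.minimum(iy, ny - 1)), 1)
    return DensityGrid(counts, bin_size, (0.0, 0.0), species, leaflet,
                       traj.n_frames, len(idx))


def enrichment_map(grid: DensityGrid, bulk_density: float | None = None,
                   box_area: float | None = None) -> np.ndarray:
    """Per-bin ratio of observed mean number density to the bulk density.

    ``bulk_density`` is the expected areal density (lipids per nm^2) of the
    species in its leaflet; if omitted it is computed as
    ``n_lipids / box_area``. A value of 1 means bulk-like occupancy.
    """
    if bulk_density is None:
        if box_area is None or box_area <= 0:
            raise ValueError("provide bulk_density or a positive box_area")
        bulk_density = grid.n_lipids / box_area
    if bulk_density <= 0:
        raise ValueError("bulk density must be > 0")
    bin_area = grid.bin_size ** 2
    return grid.mean_number / (bin_area * bulk_density)
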