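"""Scalar and angular observables of the membrane-protein system.

Centers of mass and their vertical separation, radius of gyration, Kabsch
superposition with RMSD/RMSF series, transmembrane helix tilt, lateral
radial distribution functions, relative nitrogen-height maps, and
least-squares polynomial smoothing of time series.

COM and Rg are computed on wrapped coordinates without unwrapping: analyses
assume the selected group does not straddle a periodic boundary (center the
protein first when in doubt; see :mod:`memlip.density`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pbc import minimum_image_displacement
from .topology import ParticleTopology, Selection
from .trajectory import Frame, Trajectory

__all__ = [
    "ScalarSeries",
    "com",
    "com_z_distance_series",
    "radius_of_gyration_series",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "helix_tilt_series",
    "lateral_rdf",
    "nitrogen_height_map",
    "smooth_series",
]


@dataclass
class ScalarSeries:
    """A per-frame scalar observable, optionally with a polynomial smooth."""

    times: np.ndarray
    values: np.ndarray
    smoothed: np.ndarray | None = None
    degree: int | None = None
    rss: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ns": self.times, "value": self.values})
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


def _resolve(sel, topology: ParticleTopology) -> np.ndarray:
    if sel is None:
        return np.arange(topology.n_particles)
    if isinstance(sel, Selection):
        return sel.resolve(topology)
    return np.asarray(sel, dtype=int)


def com(frame: Frame, selection, topology: ParticleTopology,
        masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted center of mass of a selection (no PBC unwrapping)."""
    idx = _resolve(selection, topology)
    if len(idx) == 0:
        raise ValueError("empty selection for center of mass")
    m = topology.mass[idx] if masses is None else np.asarray(masses, dtype=float)[idx]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    return (frame.coordinates[idx] * m[:, None]).sum(axis=0) / m.sum()


def com_z_distance_series(traj: Trajectory, sel_a, sel_b) -> ScalarSeries:
    """|z_COM(A) - z_COM(B)| per frame (nm)."""
    topo = traj.topology
    idx_a, idx_b = _resolve(sel_a, topo), _resolve(sel_b, topo)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty selection")
    ma, mb = topo.mass[idx_a], topo.mass[idx_b]
    za = (traj.coordinates[:, idx_a, 2] * ma).sum(axis=1) / ma.sum()
    zb = (traj.coordinates[:, idx_b, 2] * mb).sum(axis=1) / mb.sum()
    return ScalarSeries(traj.times, np.abs(za - zb))


def radius_of_gyration_series(traj: Trajectory, selection,
                              masses: np.ndarray | None = None) -> ScalarSeries:
    """Mass-weighted radius of gyration per frame (nm)."""
    topo = traj.topology
    idx = _resolve(selection, topo)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if len(idx) == 1:
        warnings.warn("radius of gyration of a single particle is 0", stacklevel=2)
        return ScalarSeries(traj.times, np.zeros(traj.n_frames))
    m = topo.mass[idx] if masses is None else np.asarray(masses, dtype=float)[idx]
    x = traj.coordinates[:, idx, :]
    c = (x * m[None, :, None]).sum(axis=1) / m.sum()
    sq = ((x - c[:, None, :]) ** 2).sum(axis=2)
    return ScalarSeries(traj.times, np.sqrt((sq * m[None, :]).sum(axis=1) / m.sum()))


def kabsch_superpose(x: np.ndarray, y: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal rigid superposition of ``x`` onto ``y``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) and translation minimizing the weighted RMSD of
    ``R x + t`` against ``y``. For degenerate (collinear) inputs the
    rotation about the degenerate axis is arbitrary but the RMSD is still
    the unique minimum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("point sets must share shape (N, 3)")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cx = (x * w[:, None]).sum(axis=0)
    cy = (y * w[:, None]).sum(axis=0)
    xc, yc = x - cx, y - cy
    h = (xc * w[:, None]).T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cy - rot @ cx
    diff = (rot @ x.T).T + trans - y
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, reference_frame: int | Frame, selection,
                superpose: bool = True) -> ScalarSeries:
    """Per-frame (optionally superposed) RMSD to a reference structure."""
    topo = traj.topology
    idx = _resolve(selection, topo)
    if len(idx) == 0:
        raise ValueError("empty selection")
    ref = (traj.coordinates[reference_frame][idx]
           if isinstance(reference_frame, (int, np.integer))
           else reference_frame.coordinates[idx])
    w = topo.mass[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coordinates[f][idx]
        if superpose:
            _, _, out[f] = kabsch_superpose(x, ref, w)
        else:
            wn = w / w.sum()
            out[f] = np.sqrt((wn * ((x - ref) ** 2).sum(axis=1)).sum())
    return ScalarSeries(traj.times, out)


def rmsf(traj: Trajectory, selection, superpose: bool = True) -> pd.Series:
    """Per-residue RMSF: RMS deviation from the time-mean position.

    Frames are superposed onto the time-mean structure (two passes: align
    to frame 0, average, re-align to the average) unless ``superpose`` is
    False. Per-particle fluctuations are averaged within each residue.
    """
    topo = traj.topology
    idx = _resolve(selection, topo)
    if len(idx) == 0:
        raise ValueError("empty selection")
    w = topo.mass[idx]
    xs = traj.coordinates[:, idx, :].copy()
    if superpose:
        for _ in range(2):
            ref = xs.mean(axis=0)
            for f in range(traj.n_frames):
                rot, trans, _ = kabsch_superpose(xs[f], ref, w)
                xs[f] = (rot @ xs[f].T).T + trans
    mean = xs.mean(axis=0)
    per_particle = np.sqrt(((xs - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    keys = pd.MultiIndex.from_arrays(
        [topo.chain_id[idx], topo.residue_index[idx]],
        names=["chain_id", "residue_index"])
    return pd.Series(per_particle, index=keys).groupby(level=[0, 1], sort=False).mean()


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit vector of the largest singular direction of centered points."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def helix_tilt_series(traj: Trajectory, helix_selection) -> ScalarSeries:
    """Per-frame helix tilt (deg) to the membrane normal z, folded to [0, 90].

    The helix axis is the principal axis of the centered backbone
    coordinates; tilt = arccos(|axis . z|).
    """
    topo = traj.topology
    idx = _resolve(helix_selection, topo)
    if len(idx) < 4:
        raise ValueError("need at least 4 backbone particles to define a helix axis")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        axis = principal_axis(traj.coordinates[f][idx])
        out[f] = np.degrees(np.arccos(np.clip(abs(axis[2]), 0.0, 1.0)))
    return ScalarSeries(traj.times, out)


def lateral_rdf(traj: Trajectory, species: str, leaflet: str,
                reference_sel=None, dr: float = 0.2,
                r_max: float | None = None) -> pd.DataFrame:
    """Lateral (2D) radial distribution of lipid headgroups around an axis.

    Distances are measured in the XY plane from the reference selection's
    per-frame COM (default: the protein) to the headgroup reference bead
    (phosphate, or sterol for cholesterol) of every matching lipid;
    g(r) normalizes annulus counts by the species' uniform areal density
    over the box. This is a per-leaflet 2D variant appropriate for a
    quasi-planar membrane (a 3D RDF of the same system is not comparable).
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    topo = traj.topology
    if reference_sel is None:
        reference_sel = Selection(molecule_kind="protein")
    idx_ref = _resolve(reference_sel, topo)
    if len(idx_ref) == 0:
        raise ValueError("empty reference selection")
    idx_l = Selection(molecule_kind="lipid", species=species, leaflet=leaflet,
                      role=["phosphate", "sterol"]).resolve(topo)
    if len(idx_l) == 0:
        raise ValueError(f"no {species} reference beads in {leaflet} leaflet")
    half_min = float(traj.boxes[:, :2].min()) / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min + 1e-9:
        raise ValueError("r_max must not exceed half the smallest lateral box edge")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    m = topo.mass[idx_ref]
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        ref_xy = (traj.coordinates[f][idx_ref, :2] * m[:, None]).sum(axis=0) / m.sum()
        d = minimum_image_displacement(
            np.append(ref_xy, 0.0), np.column_stack(
                [traj.coordinates[f][idx_l, :2], np.zeros(len(idx_l))]), box)
        r = np.hypot(d[:, 0], d[:, 1])
        counts += np.histogram(r, bins=edges)[0]
    area = traj.boxes[0, 0] * traj.boxes[0, 1]
    rho = len(idx_l) / area
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = counts / (traj.n_frames * rho * annulus)
    return pd.DataFrame({"r_nm": 0.5 * (edges[1:] + edges[:-1]),
                         "g": g, "count": counts.astype(int)})


def nitrogen_height_map(traj: Trajectory, leaflet: str = "outer",
                        bin_size: float = 0.5) -> pd.DataFrame:
    """Mean relative nitrogen height (nm) per XY bin.

    Per frame, each nitrogen bead's height is referenced to the mean
    phosphate z of the same leaflet; accumulated per XY bin over frames.
    Run on an aligned trajectory (protein fixed in the center) for maps
    around the protein. Empty bins carry NaN.
    """
    topo = traj.topology
    idx_n = Selection(molecule_kind="lipid", role="nitrogen", leaflet=leaflet).resolve(topo)
    if len(idx_n) == 0:
        raise ValueError(f"no nitrogen particles in {leaflet} leaflet")
    idx_p = Selection(molecule_kind="lipid", role="phosphate", leaflet=leaflet).resolve(topo)
    if len(idx_p) == 0:
        raise ValueError(f"no phosphate particles in {leaflet} leaflet")
    box = traj.boxes[0]
    nx, ny = int(np.ceil(box[0] / bin_size)), int(np.ceil(box[1] / bin_size))
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    for f in range(traj.n_frames):
        plane = traj.coordinates[f][idx_p, 2].mean()
        xy = traj.coordinates[f][idx_n, :2]
        rel = traj.coordinates[f][idx_n, 2] - plane
        ix = np.clip((xy[:, 0] // bin_size).astype(int), 0, nx - 1)
        iy = np.clip((xy[:, 1] // bin_size).astype(int), 0, ny - 1)
        inside = (xy[:, 0] >= 0) & (xy[:, 0] < box[0]) & (xy[:, 1] >= 0) & (xy[:, 1] < box[1])
        np.add.at(total, (ix[inside], iy[inside]), rel[inside])
        np.add.at(count, (ix[inside], iy[inside]), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return pd.DataFrame({
        "x_bin": (ii.ravel() + 0.5) * bin_size,
        "y_bin": (jj.ravel() + 0.5) * bin_size,
        "mean_height_nm": mean.ravel(),
        "n_obs": count.ravel().astype(int),
    })


def smooth_series(series: ScalarSeries, degree: int) -> ScalarSeries:
    """Least-squares polynomial smooth of a scalar series.

    Degree 3 is the convention for bound-lipid time series; degree 10 for
    long inter-helix distance traces. Requires more points than the degree.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    n = len(series.values)
    if degree >= n:
        raise ValueError(f"degree {degree} needs more than {n} points")
    poly = np.polynomial.Polynomial.fit(series.times, series.values, degree)
    fitted = poly(series.times)
    rss = float(((series.values - fitted) ** 2).sum())
    return ScalarSeries(series.times, series.values, smoothed=fitted,
                        degree=degree, rss=rss)
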