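"""Lateral spatial structure: RDF profiles, occupancy density maps, RMSF.

The radial distribution function here is lateral: for every bead of a
species in every frame, the minimum-image distance to the nearest protein
anchor is histogrammed, each bin is divided by its annulus area (the
geometric normalisation for a 2D system), and the profile is rescaled so
the area under the curve equals one. Unit-area rescaling removes the
dimensional prefactors and makes profiles of different species directly
comparable; the first shell of an interacting anionic species shows as an
interior maximum near the bead contact distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GeometryError, UnknownSpeciesError
from .trajectory import Trajectory, as_trajectory_list

DEFAULT_BIN_WIDTH = 1.0
DEFAULT_R_MAX = 30.0


@dataclass
class RDFProfile:
    """Unit-area-normalised lateral RDF with replicate spread.

    ``values`` is the replicate-mean profile; ``replicate_values`` holds one
    profile per input trajectory and ``std`` their per-bin standard
    deviation. The unit-area invariant sum(values) * bin_width == 1 holds
    for the mean and for every replicate profile.
    """

    bin_edges: np.ndarray  # (n_bins + 1,)
    values: np.ndarray  # (n_bins,)
    std: np.ndarray
    replicate_values: np.ndarray  # (n_replicates, n_bins)
    species: str
    r_max: float
    bin_width: float

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.bin_centres, "value": self.values, "std": self.std}
        )


def _min_distances(traj: Trajectory, species: str) -> np.ndarray:
    """Min-image distance of every bead of ``species`` to the anchor set."""
    if not traj.has_species(species):
        raise UnknownSpeciesError(f"species {species!r} absent from trajectory")
    pos = traj.lipid_xy[:, traj.species_mask(species), :]
    delta = pos[:, :, None, :] - traj.anchors.xy[None, None, :, :]
    delta -= traj.box_edge * np.round(delta / traj.box_edge)
    d2 = np.sum(delta * delta, axis=-1).min(axis=2)
    return np.sqrt(d2).ravel()


def lateral_rdf(
    trajs: Trajectory | Sequence[Trajectory],
    species: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
) -> RDFProfile:
    """Lateral RDF of a species around the protein anchor set.

    Distances are measured to the nearest anchor (TM + JM), histogrammed on
    [0, r_max], divided by the annulus area of each bin, and rescaled to
    unit area under the curve. One profile is computed per replicate; the
    returned values are the replicate mean (itself renormalised to unit
    area) with the per-bin replicate standard deviation.

    Raises
    ------
    GeometryError
        If ``r_max`` exceeds half the box edge (minimum-image distances are
        only unambiguous below that).
    """
    traj_list = as_trajectory_list(trajs)
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    if r_max > traj_list[0].box_edge / 2.0:
        raise GeometryError(
            f"r_max {r_max} exceeds half the box edge "
            f"({traj_list[0].box_edge / 2:.1f} A)"
        )
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    profiles = []
    for traj in traj_list:
        dists = _min_distances(traj, species)
        hist, _ = np.histogram(dists, bins=edges)
        if hist.sum() == 0:
            raise EmptyInputError(
                f"no {species} bead ever within r_max={r_max} A of the protein"
            )
        g = hist / annulus
        g /= g.sum() * bin_width  # unit area under the curve
        profiles.append(g)
    rep = np.asarray(profiles)
    mean = rep.mean(axis=0)
    mean /= mean.sum() * bin_width
    return RDFProfile(
        bin_edges=edges,
        values=mean,
        std=rep.std(axis=0),
        replicate_values=rep,
        species=species,
        r_max=float(r_max),
        bin_width=float(bin_width),
    )


def first_peak(rdf: RDFProfile) -> float | None:
    """Radial position (bin centre) of the first local maximum.

    A bin qualifies if its value strictly exceeds both neighbours; the
    first bin qualifies if it strictly exceeds its right neighbour. Ties
    resolve to smaller r by taking the first qualifying bin. Returns None
    if no bin qualifies (monotonically non-decreasing profile).
    """
    v = rdf.values
    if v.size < 3:
        raise ValueError("need at least 3 bins to locate a peak")
    centres = rdf.bin_centres
    if v[0] > v[1]:
        return float(centres[0])
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            return float(centres[i])
    return None


@dataclass
class DensityMap:
    """VolMap-style occupancy map: fraction of frames each cell is occupied."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # (nx, ny) in [0, 1]
    species: str
    cell: float

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "occupancy": self.occupancy.ravel()}
        )


def density_map(
    trajs: Trajectory | Sequence[Trajectory],
    species: str,
    cell: float = 1.0,
) -> DensityMap:
    """Per-cell occupancy fraction of a species over concatenated frames.

    A cell is occupied in a frame if at least one bead of the species lies
    in it; the map value is the fraction of all frames (all replicates) in
    which the cell is occupied.
    """
    traj_list = as_trajectory_list(trajs)
    box = traj_list[0].box_edge
    if cell <= 0:
        raise ValueError("cell must be positive")
    n_cells = int(np.ceil(box / cell))
    edges = np.linspace(0.0, box, n_cells + 1)
    occupied_frames = np.zeros((n_cells, n_cells), dtype=np.int64)
    total_frames = 0
    for traj in traj_list:
        if not traj.has_species(species):
            raise UnknownSpeciesError(f"species {species!r} absent from trajectory")
        pos = traj.lipid_xy[:, traj.species_mask(species), :]
        ix = np.clip((pos[..., 0] / box * n_cells).astype(int), 0, n_cells - 1)
        iy = np.clip((pos[..., 1] / box * n_cells).astype(int), 0, n_cells - 1)
        for f in range(traj.n_frames):
            frame_hit = np.zeros((n_cells, n_cells), dtype=bool)
            frame_hit[ix[f], iy[f]] = True
            occupied_frames += frame_hit
        total_frames += traj.n_frames
    if total_frames == 0:
        raise EmptyInputError("no frames in trajectory set")
    return DensityMap(
        x_edges=edges, y_edges=edges,
        occupancy=occupied_frames / total_frames,
        species=species, cell=float(box / n_cells),
    )


def rmsf(track: np.ndarray, labels: Sequence[str] | None = None) -> pd.Series:
    """Root-mean-square fluctuation per labelled particle.

    ``track`` has shape (n_frames, n_particles, n_dim); the RMSF of a
    particle is the square root of the time-mean squared deviation from its
    time-mean position. No superposition or alignment is applied (the
    reference frame is assumed fixed, as it is for anchor tracks).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 3:
        raise ValueError("track must have shape (frames, particles, dim)")
    if track.shape[0] < 2:
        raise EmptyInputError("RMSF requires at least 2 frames")
    mean_pos = track.mean(axis=0, keepdims=True)
    dev2 = np.sum((track - mean_pos) ** 2, axis=2)
    values = np.sqrt(dev2.mean(axis=0))
    idx = list(labels) if labels is not None else list(range(track.shape[1]))
    if len(idx) != track.shape[1]:
        raise ValueError("labels length does not match particle count")
    return pd.Series(values, index=idx, name="rmsf")
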