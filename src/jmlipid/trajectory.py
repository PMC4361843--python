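"""Trajectory container and protein anchor layout.

The simulator works in two dimensions: lipid headgroup beads diffuse in the
membrane plane around an immobile protein footprint. The footprint encodes
the surface-lying pose of the juxtamembrane arm directly — one TM anchor at
the box centre and one anchor per JM residue laid out along a fixed
direction at a constant spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .residues import TMJMModel

#: Default distance between successive JM residue anchors, Angstrom
#: (a coarse-grained backbone-bead spacing for an extended chain lying on
#: the membrane surface).
DEFAULT_ANCHOR_SPACING = 3.5


@dataclass(frozen=True)
class ProteinAnchors:
    """Immobile protein footprint: TM bead plus one bead per JM residue."""

    xy: np.ndarray  # (M, 2) positions
    labels: tuple[str, ...]  # "TM", "JM1", ..., "JM<L>"
    classes: tuple[str, ...]  # "TM" for the TM anchor, residue class otherwise
    charges: np.ndarray  # (M,) int
    receptor_id: str = "unnamed"

    def __post_init__(self) -> None:
        if self.xy.shape != (len(self.labels), 2):
            raise ValueError("anchor positions and labels disagree in length")

    @property
    def n_anchors(self) -> int:
        return len(self.labels)

    @property
    def jm_labels(self) -> tuple[str, ...]:
        return tuple(lb for lb in self.labels if lb != "TM")


def place_protein(
    model: TMJMModel,
    box_edge: float,
    spacing: float = DEFAULT_ANCHOR_SPACING,
) -> ProteinAnchors:
    """Lay out the protein footprint for a periodic square box.

    The TM anchor sits at the box centre; JM residue i (1-based) sits at
    distance ``i * spacing`` from it along +x. Anchors never move during a
    simulation.

    Raises
    ------
    GeometryError
        If the JM arm would exceed half the box edge (it would interact
        with its own periodic image).
    """
    arm = model.jm_length * spacing
    if arm > box_edge / 2.0:
        raise GeometryError(
            f"JM arm of {arm:.1f} A exceeds half the box edge ({box_edge / 2:.1f} A)"
        )
    centre = box_edge / 2.0
    n = model.jm_length + 1
    xy = np.zeros((n, 2))
    xy[:, 0] = centre + spacing * np.arange(n)
    xy[:, 1] = centre
    labels = ("TM",) + tuple(f"JM{i}" for i in range(1, model.jm_length + 1))
    classes = ("TM",) + model.per_residue_class
    charges = np.array((0,) + model.per_residue_charge, dtype=int)
    return ProteinAnchors(
        xy=xy, labels=labels, classes=classes, charges=charges,
        receptor_id=model.receptor_id,
    )


@dataclass
class Trajectory:
    """Frames of 2D lipid bead positions around a fixed protein footprint.

    Attributes
    ----------
    lipid_xy : (n_frames, n_lipids, 2) float array
        Wrapped coordinates in [0, box_edge).
    species : (n_lipids,) str array
        Species label per bead; identical in every frame by construction.
    anchors : ProteinAnchors
        The immobile protein footprint.
    box_edge : float
        Periodic square box edge, Angstrom.
    frame_interval : float
        Time between saved frames (timestep x save_stride), ns.
    seed : int
        PRNG seed actually used for this replicate.
    replicate_id : int
    """

    lipid_xy: np.ndarray
    species: np.ndarray
    anchors: ProteinAnchors
    box_edge: float
    frame_interval: float
    seed: int
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.lipid_xy.ndim != 3 or self.lipid_xy.shape[2] != 2:
            raise ValueError("lipid_xy must have shape (frames, beads, 2)")
        if self.lipid_xy.shape[1] != len(self.species):
            raise ValueError("species labels do not match bead count")

    @property
    def n_frames(self) -> int:
        return self.lipid_xy.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.lipid_xy.shape[1]

    def species_mask(self, name: str) -> np.ndarray:
        return self.species == name

    def has_species(self, name: str) -> bool:
        return bool(np.any(self.species == name))


def as_trajectory_list(trajs: "Trajectory | Sequence[Trajectory]") -> list[Trajectory]:
    """Normalise a single trajectory or a replicate sequence to a list."""
    if isinstance(trajs, Trajectory):
        return [trajs]
    out = list(trajs)
    if not out:
        raise ValueError("empty trajectory sequence")
    return out


def minimum_image_distances(
    points: np.ndarray, refs: np.ndarray, box_edge: float
) -> np.ndarray:
    """Minimum distance from each point to the reference set (periodic).

    Parameters
    ----------
    points : (..., N, 2)
    refs : (M, 2)

    Returns
    -------
    (..., N) array of distances to the nearest reference.
    """
    delta = points[..., :, None, :] - refs[None, :, :]
    delta -= box_edge * np.round(delta / box_edge)
    d2 = np.sum(delta * delta, axis=-1)  # (..., N, M)
    return np.sqrt(d2.min(axis=-1))
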