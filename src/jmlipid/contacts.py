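"""Per-residue lipid contact statistics.

A contact is a lipid headgroup bead of a given species within the cutoff
distance (default 6 A, inclusive, minimum-image) of a protein residue
anchor. From the residue x frame count matrix the module derives the three
standard per-residue fingerprints:

* mean contacts per frame,
* occupancy fraction — the percentage of frames with at least one contact,
* mean residence time — total occupied time divided by the number of
  association events (maximal runs of consecutive occupied frames).

Replicates are concatenated frame-wise for time-averaged statistics, but an
association run never bridges the boundary between two replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UnknownSpeciesError
from .trajectory import Trajectory, as_trajectory_list

DEFAULT_CONTACT_CUTOFF = 6.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Contact definition: cutoff distance and run-gap tolerance.

    ``gap_tolerance`` is the number of consecutive unoccupied frames allowed
    inside one association event; the default 0 means any unoccupied frame
    terminates the event (no smoothing).
    """

    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be non-negative")


@dataclass
class ContactMatrix:
    """Residues x frames integer contact counts for one lipid species.

    ``segment_lengths`` records the frame count contributed by each
    concatenated replicate, in order; event counting respects these
    boundaries.
    """

    residues: tuple[str, ...]
    counts: np.ndarray  # (n_residues, n_frames) int
    species: str
    cutoff: float
    frame_interval: float
    segment_lengths: tuple[int, ...]
    replicate_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.residues):
            raise ValueError("counts shape does not match residue labels")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if sum(self.segment_lengths) != self.counts.shape[1]:
            raise ValueError("segment lengths do not sum to the frame count")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (residue labels x frame index)."""
        return pd.DataFrame(self.counts, index=list(self.residues))


def _species_positions(traj: Trajectory, species: str) -> np.ndarray:
    if not traj.has_species(species):
        raise UnknownSpeciesError(
            f"species {species!r} absent from trajectory "
            f"(present: {sorted(set(traj.species.tolist()))})"
        )
    return traj.lipid_xy[:, traj.species_mask(species), :]


def count_contacts(
    trajs: Trajectory | Sequence[Trajectory],
    species: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> ContactMatrix:
    """Count, per residue anchor and frame, beads of ``species`` within cutoff.

    The cutoff boundary is inclusive: a bead at exactly the cutoff distance
    counts. A bead within the cutoff of several residues counts once for
    each of them. Replicates are concatenated along the frame axis.
    """
    traj_list = as_trajectory_list(trajs)
    first = traj_list[0]
    cutoff2 = config.contact_cutoff ** 2
    blocks: list[np.ndarray] = []
    for traj in traj_list:
        if tuple(traj.anchors.labels) != tuple(first.anchors.labels):
            raise ValueError("trajectories have different anchor layouts")
        pos = _species_positions(traj, species)  # (F, B, 2)
        delta = pos[:, :, None, :] - traj.anchors.xy[None, None, :, :]
        delta -= traj.box_edge * np.round(delta / traj.box_edge)
        d2 = np.sum(delta * delta, axis=-1)  # (F, B, M)
        blocks.append(np.sum(d2 <= cutoff2, axis=1).T.astype(np.int64))  # (M, F)
    counts = np.concatenate(blocks, axis=1)
    return ContactMatrix(
        residues=tuple(first.anchors.labels),
        counts=counts,
        species=species,
        cutoff=config.contact_cutoff,
        frame_interval=first.frame_interval,
        segment_lengths=tuple(b.shape[1] for b in blocks),
        replicate_ids=tuple(t.replicate_id for t in traj_list),
    )


def _require_frames(cm: ContactMatrix) -> None:
    if cm.n_frames == 0:
        raise EmptyInputError("contact matrix has zero frames")


def mean_contacts(cm: ContactMatrix) -> pd.Series:
    """Per-residue arithmetic mean contacts per frame (replicates pooled)."""
    _require_frames(cm)
    return pd.Series(cm.counts.mean(axis=1), index=list(cm.residues), name="mean_contacts")


def occupancy_fraction(cm: ContactMatrix) -> pd.Series:
    """Per-residue percentage of frames with at least one contact."""
    _require_frames(cm)
    frac = 100.0 * np.mean(cm.counts >= 1, axis=1)
    return pd.Series(frac, index=list(cm.residues), name="occupancy_pct")


def _count_events(occupied: np.ndarray, gap_tolerance: int) -> int:
    """Number of association events in one binary occupancy row segment."""
    idx = np.flatnonzero(occupied)
    if idx.size == 0:
        return 0
    gaps = np.diff(idx) - 1
    return 1 + int(np.sum(gaps > gap_tolerance))


def residence_time(
    cm: ContactMatrix,
    frame_interval: float | None = None,
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """Per-residue mean residence time: occupancy time / association events.

    Occupancy is binarised per residue (count >= 1). The occupancy time is
    the number of occupied frames times the frame interval; association
    events are maximal runs of consecutive occupied frames, counted within
    each replicate segment (runs never bridge the concatenation boundary).
    Residues that are never occupied get a residence time of 0 and are
    flagged with ``n_events == 0``.

    Returns a DataFrame with columns ``residence_time``, ``n_events`` and
    ``occupancy_time`` indexed by residue label.
    """
    _require_frames(cm)
    dt = cm.frame_interval if frame_interval is None else float(frame_interval)
    occupied = cm.counts >= 1
    bounds = np.cumsum((0,) + cm.segment_lengths)
    rows = []
    for r in range(occupied.shape[0]):
        n_occ = int(occupied[r].sum())
        events = sum(
            _count_events(occupied[r, a:b], gap_tolerance)
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        occ_time = n_occ * dt
        rows.append(
            {
                "residence_time": occ_time / events if events else 0.0,
                "n_events": events,
                "occupancy_time": occ_time,
            }
        )
    return pd.DataFrame(rows, index=list(cm.residues))


def first_shell_count(
    trajs: Trajectory | Sequence[Trajectory],
    species: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """Mean number of beads of ``species`` within cutoff of the anchor set.

    A bead counts once per frame if its minimum-image distance to the
    nearest protein anchor is <= cutoff; the count is averaged over all
    frames of all replicates (the first interaction shell population).
    """
    traj_list = as_trajectory_list(trajs)
    total = 0.0
    frames = 0
    cutoff2 = cutoff * cutoff
    for traj in traj_list:
        pos = _species_positions(traj, species)
        delta = pos[:, :, None, :] - traj.anchors.xy[None, None, :, :]
        delta -= traj.box_edge * np.round(delta / traj.box_edge)
        d2 = np.sum(delta * delta, axis=-1).min(axis=2)  # (F, B)
        total += float(np.sum(d2 <= cutoff2))
        frames += traj.n_frames
    if frames == 0:
        raise EmptyInputError("no frames in trajectory set")
    return total / frames


def contact_summary(
    trajs: Trajectory | Sequence[Trajectory],
    species_list: Sequence[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Tidy per-residue summary over several species.

    Columns: receptor, residue, residue_class, species, statistic, value.
    """
    traj_list = as_trajectory_list(trajs)
    anchors = traj_list[0].anchors
    records = []
    for sp in species_list:
        cm = count_contacts(traj_list, sp, config)
        stats = {
            "mean_contacts": mean_contacts(cm),
            "occupancy_pct": occupancy_fraction(cm),
            "residence_time": residence_time(cm)["residence_time"],
        }
        for stat_name, series in stats.items():
            for label, cls in zip(anchors.labels, anchors.classes):
                records.append(
                    {
                        "receptor": anchors.receptor_id,
                        "residue": label,
                        "residue_class": cls,
                        "species": sp,
                        "statistic": stat_name,
                        "value": float(series[label]),
                    }
                )
    return pd.DataFrame.from_records(records)
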