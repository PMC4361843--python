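"""Optional ingestion adapter for externally produced CG trajectories.

Maps a standard structure (+ optional trajectory) file pair — e.g. GRO, or
GRO + XTC — onto the internal :class:`~jmlipid.trajectory.Trajectory` by
extracting one designated headgroup bead per lipid and one backbone bead
per protein residue, projecting everything onto the membrane (xy) plane.

Requires MDAnalysis, which is imported lazily; the rest of the package has
no dependency on it. Protein anchors are taken from the first frame and
treated as immobile — alignment of a mobile protein is the caller's
responsibility and is not applied here.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .residues import classify_residue, residue_charge
from .trajectory import ProteinAnchors, Trajectory

#: 3-letter -> 1-letter amino-acid codes for anchor classification.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def ingest_external(
    topology: str,
    trajectory: str | None = None,
    *,
    lipid_selections: Mapping[str, str],
    protein_selection: str = "protein and name BB",
    frame_interval: float = 1.0,
    receptor_id: str = "external",
) -> Trajectory:
    """Build an internal Trajectory from external CG files.

    Parameters
    ----------
    topology, trajectory
        Paths understood by MDAnalysis (GRO alone gives one frame).
    lipid_selections
        Species name -> MDAnalysis selection string picking exactly one
        headgroup bead per lipid of that species (e.g.
        ``{"PIP2": "resname PIP2 and name PO4"}``).
    protein_selection
        Selection giving one backbone bead per protein residue; the first
        residue is labelled TM, the rest JM1..JMn.
    frame_interval
        Time between frames, ns (external readers often lack reliable
        time metadata for text formats).
    """
    import MDAnalysis as mda  # deferred: optional dependency

    universe = (
        mda.Universe(topology, trajectory) if trajectory else mda.Universe(topology)
    )
    box_edge = float(universe.dimensions[0])

    prot = universe.select_atoms(protein_selection)
    if len(prot) == 0:
        raise ValueError(f"protein selection {protein_selection!r} matched no atoms")
    resnames = [THREE_TO_ONE.get(rn.upper(), "X") for rn in prot.residues.resnames]
    labels = ["TM"] + [f"JM{i}" for i in range(1, len(resnames))]
    classes = ["TM"] + [
        classify_residue(aa) if aa != "X" else "polar" for aa in resnames[1:]
    ]
    charges = np.array(
        [0] + [residue_charge(aa) if aa != "X" else 0 for aa in resnames[1:]], dtype=int
    )

    groups = {sp: universe.select_atoms(sel) for sp, sel in lipid_selections.items()}
    for sp, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"selection for {sp!r} matched no atoms")
    species = np.array(
        [sp for sp, g in groups.items() for _ in range(len(g))], dtype="U8"
    )

    frames = []
    anchor_xy = None
    for _ in universe.trajectory:
        if anchor_xy is None:
            anchor_xy = prot.positions[:, :2].astype(float) % box_edge
        xy = np.vstack([g.positions[:, :2] for g in groups.values()]).astype(float)
        frames.append(xy % box_edge)

    anchors = ProteinAnchors(
        xy=anchor_xy, labels=tuple(labels), classes=tuple(classes),
        charges=charges, receptor_id=receptor_id,
    )
    return Trajectory(
        lipid_xy=np.asarray(frames), species=species, anchors=anchors,
        box_edge=box_edge, frame_interval=float(frame_interval),
        seed=-1, replicate_id=0,
    )
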