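"""Readers and writers: receptor tables, trajectories, analysis tables.

Trajectory text format (tab-separated, ``# key=value`` header lines)::

    # jmlipid-trajectory v1
    # box_edge=150.000
    # frame_interval=0.500
    # seed=1
    # replicate_id=0
    # n_frames=400
    # n_lipids=220
    # anchors=<JSON: labels, classes, charges, receptor_id>
    # species=<JSON list, one label per lipid bead>
    frame  bead_id  kind  label  x  y

Anchor beads are immobile, so their rows are written once with frame -1;
lipid rows follow frame by frame. Coordinates are written with three
decimals (0.001 A granularity, far below the bead radius); the companion
binary container (NumPy ``.npz``) round-trips coordinates exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ReferenceError_, TruncatedJMError
from .residues import TMJMModel, build_model
from .trajectory import ProteinAnchors, Trajectory

logger = logging.getLogger("jmlipid")

_TRAJ_MAGIC = "# jmlipid-trajectory v1"


def load_rtk_manifest() -> list[str]:
    """The bundled list of the 58 human RTK gene symbols."""
    text = resources.files("jmlipid.data").joinpath("rtk_manifest.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


# --- Receptor tables ------------------------------------------------------

def read_receptor_table(
    fasta_path: str | Path,
    annotation_path: str | Path,
    jm_length: int = 20,
) -> list[TMJMModel]:
    """Build TM-JM models from a FASTA file and a TM-span annotation table.

    The annotation table is delimited text with columns ``receptor_id``,
    ``tm_start``, ``tm_end`` (1-based inclusive). Receptors whose JM
    segment cannot be extracted (too few residues after the TM span) are
    skipped with a warning; an annotation referring to an id absent from
    the FASTA raises.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    try:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except (ValueError, AssertionError) as exc:
        raise ParseError(f"malformed FASTA {fasta_path}: {exc}") from exc
    if not records:
        raise ParseError(f"no sequences parsed from {fasta_path}")
    try:
        table = pd.read_csv(annotation_path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"malformed annotation table {annotation_path}: {exc}") from exc
    required = {"receptor_id", "tm_start", "tm_end"}
    if not required.issubset(table.columns):
        raise ParseError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    models: list[TMJMModel] = []
    for row in table.itertuples(index=False):
        rid = str(row.receptor_id)
        if rid not in records:
            raise ReferenceError_(f"annotation refers to id {rid!r} absent from FASTA")
        try:
            models.append(
                build_model(rid, records[rid], (int(row.tm_start), int(row.tm_end)),
                            jm_length=jm_length)
            )
        except TruncatedJMError as exc:
            warnings.warn(f"skipping receptor {rid!r}: {exc}", stacklevel=2)
            logger.warning("skipping receptor %s: %s", rid, exc)
    return models


# --- Trajectory round-trip ------------------------------------------------

def _anchor_meta(anchors: ProteinAnchors) -> dict:
    return {
        "labels": list(anchors.labels),
        "classes": list(anchors.classes),
        "charges": [int(c) for c in anchors.charges],
        "receptor_id": anchors.receptor_id,
    }


def write_trajectory_text(traj: Trajectory, path: str | Path) -> Path:
    """Write the documented columnar text format (3-decimal coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_TRAJ_MAGIC}\n")
        fh.write(f"# box_edge={traj.box_edge:.6f}\n")
        fh.write(f"# frame_interval={traj.frame_interval:.6f}\n")
        fh.write(f"# seed={traj.seed}\n")
        fh.write(f"# replicate_id={traj.replicate_id}\n")
        fh.write(f"# n_frames={traj.n_frames}\n")
        fh.write(f"# n_lipids={traj.n_lipids}\n")
        fh.write(f"# anchors={json.dumps(_anchor_meta(traj.anchors))}\n")
        fh.write(f"# species={json.dumps(traj.species.tolist())}\n")
        fh.write("frame\tbead_id\tkind\tlabel\tx\ty\n")
        for i, label in enumerate(traj.anchors.labels):
            x, y = traj.anchors.xy[i]
            fh.write(f"-1\t{i}\tanchor\t{label}\t{x:.3f}\t{y:.3f}\n")
        for f in range(traj.n_frames):
            for b in range(traj.n_lipids):
                x, y = traj.lipid_xy[f, b]
                fh.write(f"{f}\t{b}\tlipid\t{traj.species[b]}\t{x:.3f}\t{y:.3f}\n")
    return path


def read_trajectory_text(path: str | Path) -> Trajectory:
    """Read the text format back; exact to the written 3-decimal precision."""
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRAJ_MAGIC:
            raise ParseError(f"{path}: not a jmlipid trajectory (bad magic line)")
        line_no = 1
        for line in fh:
            line_no += 1
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition("=")
                header[key] = value
            else:
                if not line.startswith("frame\t"):
                    raise ParseError(f"{path}:{line_no}: expected column header row")
                break
        try:
            box = float(header["box_edge"])
            frame_interval = float(header["frame_interval"])
            seed = int(header["seed"])
            replicate_id = int(header["replicate_id"])
            n_frames = int(header["n_frames"])
            n_lipids = int(header["n_lipids"])
            anchor_meta = json.loads(header["anchors"])
            species = np.array(json.loads(header["species"]), dtype="U8")
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: incomplete or malformed header: {exc}") from exc
        if len(species) != n_lipids:
            raise ParseError(f"{path}: species list length != n_lipids")

        n_anchors = len(anchor_meta["labels"])
        anchor_xy = np.zeros((n_anchors, 2))
        lipid_xy = np.zeros((n_frames, n_lipids, 2))
        seen = np.zeros((max(n_frames, 1), n_lipids), dtype=bool)
        for line in fh:
            line_no += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{line_no}: expected 6 fields, got {len(parts)}")
            try:
                frame, bead_id = int(parts[0]), int(parts[1])
                kind, label = parts[2], parts[3]
                x, y = float(parts[4]), float(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
            if kind == "anchor":
                if not (0 <= bead_id < n_anchors):
                    raise ParseError(f"{path}:{line_no}: anchor id {bead_id} out of range")
                anchor_xy[bead_id] = (x, y)
            elif kind == "lipid":
                if not (0 <= frame < n_frames) or not (0 <= bead_id < n_lipids):
                    raise ParseError(
                        f"{path}:{line_no}: lipid row (frame {frame}, bead {bead_id}) "
                        f"out of range"
                    )
                lipid_xy[frame, bead_id] = (x, y)
                seen[frame, bead_id] = True
            else:
                raise ParseError(f"{path}:{line_no}: unknown kind {kind!r}")
    if n_frames and not seen.all():
        f, b = np.argwhere(~seen)[0]
        raise ParseError(f"{path}: truncated file; missing frame {f}, bead {b}")
    anchors = ProteinAnchors(
        xy=anchor_xy,
        labels=tuple(anchor_meta["labels"]),
        classes=tuple(anchor_meta["classes"]),
        charges=np.array(anchor_meta["charges"], dtype=int),
        receptor_id=anchor_meta.get("receptor_id", "unnamed"),
    )
    return Trajectory(
        lipid_xy=lipid_xy, species=species, anchors=anchors, box_edge=box,
        frame_interval=frame_interval, seed=seed, replicate_id=replicate_id,
    )


def write_trajectory_npz(traj: Trajectory, path: str | Path) -> Path:
    """Exact binary container (NumPy ``.npz``)."""
    path = Path(path)
    np.savez_compressed(
        path,
        lipid_xy=traj.lipid_xy,
        species=traj.species,
        anchor_xy=traj.anchors.xy,
        anchor_charges=traj.anchors.charges,
        meta=np.array(
            json.dumps(
                {
                    "box_edge": traj.box_edge,
                    "frame_interval": traj.frame_interval,
                    "seed": traj.seed,
                    "replicate_id": traj.replicate_id,
                    "anchor_labels": list(traj.anchors.labels),
                    "anchor_classes": list(traj.anchors.classes),
                    "receptor_id": traj.anchors.receptor_id,
                }
            )
        ),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_trajectory_npz(path: str | Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        anchors = ProteinAnchors(
            xy=data["anchor_xy"],
            labels=tuple(meta["anchor_labels"]),
            classes=tuple(meta["anchor_classes"]),
            charges=data["anchor_charges"],
            receptor_id=meta["receptor_id"],
        )
        return Trajectory(
            lipid_xy=data["lipid_xy"],
            species=data["species"].astype("U8"),
            anchors=anchors,
            box_edge=float(meta["box_edge"]),
            frame_interval=float(meta["frame_interval"]),
            seed=int(meta["seed"]),
            replicate_id=int(meta["replicate_id"]),
        )


def read_trajectory(path: str | Path) -> Trajectory:
    """Dispatch on extension: ``.npz`` binary, anything else text."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_trajectory_npz(path)
    return read_trajectory_text(path)


# --- Analysis tables ------------------------------------------------------

def write_contact_matrix(cm, path: str | Path) -> Path:
    """Contact matrix as delimited residues x frames table with metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# species={cm.species} cutoff={cm.cutoff} "
                 f"frame_interval={cm.frame_interval} "
                 f"segment_lengths={','.join(map(str, cm.segment_lengths))}\n")
        cm.to_frame().to_csv(fh)
    return path


def write_rdf_csv(rdf, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# species={rdf.species} bin_width={rdf.bin_width} r_max={rdf.r_max}\n")
        rdf.to_frame().to_csv(fh, index=False)
    return path


def write_density_csv(dmap, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# species={dmap.species} cell={dmap.cell}\n")
        dmap.to_frame().to_csv(fh, index=False)
    return path


def write_density_matrix(dmap, path: str | Path) -> Path:
    """Plain matrix text layout (rows = x cells, columns = y cells)."""
    path = Path(path)
    np.savetxt(path, dmap.occupancy, fmt="%.6f",
               header=f"species={dmap.species} cell={dmap.cell}")
    return path


def write_pwm(aa_frequency: pd.DataFrame, path: str | Path) -> Path:
    """Position-weight-matrix text layout consumable by logo tools.

    One row per JM position, one column per amino acid, tab-separated,
    with a ``PO`` header row (the classic matrix layout).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("PO\t" + "\t".join(aa_frequency.columns) + "\n")
        for pos, row in aa_frequency.iterrows():
            fh.write(str(pos) + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
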