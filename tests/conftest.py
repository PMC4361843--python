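"""Shared fixtures: reduced-size seeded simulations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import jmlipid as jm


@pytest.fixture(scope="session")
def insr_model():
    return jm.insr_like_model()


@pytest.fixture(scope="session")
def production_runs(insr_model):
    """Three calibrated-default replicates of the reference system.

    This is the package's standard production protocol; several analyses
    (first-shell occupancy, RDF structure, residence-time ordering) share
    these runs, so they are simulated once per session.
    """
    config = jm.SimulationConfig(seed=11)
    anchors = jm.place_protein(insr_model, config.box_edge)
    return jm.simulate_replicates(anchors, jm.INNER_LEAFLET_SIMPLE, config, 3)


@pytest.fixture(scope="session")
def quick_runs(insr_model):
    """Two short replicates of the reference system for cheap checks."""
    config = jm.quick_config(seed=5)
    anchors = jm.place_protein(insr_model, config.box_edge)
    return jm.simulate_replicates(anchors, jm.INNER_LEAFLET_SIMPLE, config, 2)


@pytest.fixture()
def toy_trajectory():
    """Hand-buildable random toy trajectory (no dynamics; uniform positions)."""
    rng = np.random.default_rng(42)
    box = 60.0
    n_frames, n_lipids = 10, 30
    species = np.array(["PIP2"] * 10 + ["PS"] * 10 + ["PC"] * 10, dtype="U8")
    anchors = jm.ProteinAnchors(
        xy=np.array([[30.0, 30.0], [34.0, 30.0], [38.0, 30.0]]),
        labels=("TM", "JM1", "JM2"),
        classes=("TM", "basic", "polar"),
        charges=np.array([0, 1, 0]),
        receptor_id="toy",
    )
    return jm.Trajectory(
        lipid_xy=rng.uniform(0, box, size=(n_frames, n_lipids, 2)),
        species=species,
        anchors=anchors,
        box_edge=box,
        frame_interval=0.5,
        seed=42,
    )


def make_matrix(counts, species="PIP2", frame_interval=1.0, segments=None):
    """Build a ContactMatrix straight from a count array."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    residues = tuple(f"JM{i + 1}" for i in range(counts.shape[0]))
    return jm.ContactMatrix(
        residues=residues,
        counts=counts,
        species=species,
        cutoff=6.0,
        frame_interval=frame_interval,
        segment_lengths=segments or (counts.shape[1],),
    )
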