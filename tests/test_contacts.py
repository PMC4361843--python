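"""Contact counting, occupancy, residence times, first-shell statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jmlipid as jm
from jmlipid.errors import EmptyInputError, UnknownSpeciesError

from conftest import make_matrix


def brute_force_contacts(traj, species, cutoff):
    """O(N^2) python-loop oracle for the contact matrix."""
    mask = traj.species == species
    out = np.zeros((traj.anchors.n_anchors, traj.n_frames), dtype=int)
    for f in range(traj.n_frames):
        for b in np.flatnonzero(mask):
            for a in range(traj.anchors.n_anchors):
                dx, dy = traj.lipid_xy[f, b] - traj.anchors.xy[a]
                dx -= traj.box_edge * round(dx / traj.box_edge)
                dy -= traj.box_edge * round(dy / traj.box_edge)
                if np.hypot(dx, dy) <= cutoff:
                    out[a, f] += 1
    return out


class TestCountContacts:
    def test_matches_brute_force_oracle(self, toy_trajectory):
        for species in ("PIP2", "PS", "PC"):
            cm = jm.count_contacts(toy_trajectory, species)
            expected = brute_force_contacts(toy_trajectory, species, 6.0)
            assert np.array_equal(cm.counts, expected)

    def test_inclusive_boundary(self):
        anchors = jm.ProteinAnchors(
            xy=np.array([[10.0, 10.0]]), labels=("TM",), classes=("TM",),
            charges=np.array([0]), receptor_id="t",
        )
        pos = np.array([[[16.0, 10.0], [16.01, 10.0]]])  # exactly 6.0 and 6.01
        traj = jm.Trajectory(
            lipid_xy=pos, species=np.array(["PIP2", "PIP2"], dtype="U8"),
            anchors=anchors, box_edge=40.0, frame_interval=1.0, seed=0,
        )
        cm = jm.count_contacts(traj, "PIP2")
        assert cm.counts[0, 0] == 1

    def test_single_bead_near_one_residue(self):
        anchors = jm.ProteinAnchors(
            xy=np.array([[10.0, 10.0], [20.0, 10.0], [30.0, 10.0]]),
            labels=("TM", "JM1", "JM2"), classes=("TM", "basic", "polar"),
            charges=np.array([0, 1, 0]), receptor_id="t",
        )
        pos = np.array([[[25.0, 10.0]]])  # 5 A from JM1, 5 A from JM2? -> 5 and 5
        traj = jm.Trajectory(
            lipid_xy=pos, species=np.array(["PIP2"], dtype="U8"),
            anchors=anchors, box_edge=60.0, frame_interval=1.0, seed=0,
        )
        cm = jm.count_contacts(traj, "PIP2")
        assert cm.counts[:, 0].tolist() == [0, 1, 1]

    def test_unknown_species_raises(self, toy_trajectory):
        with pytest.raises(UnknownSpeciesError):
            jm.count_contacts(toy_trajectory, "GM3")

    def test_replicates_concatenate(self, toy_trajectory):
        cm = jm.count_contacts([toy_trajectory, toy_trajectory], "PS")
        assert cm.n_frames == 2 * toy_trajectory.n_frames
        assert cm.segment_lengths == (10, 10)

    def test_conservation_against_direct_pair_count(self, toy_trajectory):
        """Sum of per-residue means equals the mean total contact-pair count."""
        cm = jm.count_contacts(toy_trajectory, "PC")
        total_pairs = brute_force_contacts(toy_trajectory, "PC", 6.0).sum()
        assert jm.mean_contacts(cm).sum() == pytest.approx(
            total_pairs / toy_trajectory.n_frames
        )


class TestDerivedStatistics:
    def test_mean_contacts_rows(self):
        cm = make_matrix([[1, 0, 1], [0, 0, 0]])
        mc = jm.mean_contacts(cm)
        assert mc["JM1"] == pytest.approx(2 / 3)
        assert mc["JM2"] == 0.0

    def test_mean_contacts_pools_replicates_equally(self):
        cm = make_matrix([[1, 1, 0, 0]], segments=(2, 2))
        assert jm.mean_contacts(cm)["JM1"] == pytest.approx(0.5)

    def test_occupancy_fraction(self):
        cm = make_matrix([[1, 1, 0, 1, 0], [2, 3, 5, 1, 4], [0, 0, 0, 0, 0]])
        occ = jm.occupancy_fraction(cm)
        assert occ.tolist() == [60.0, 100.0, 0.0]

    @pytest.mark.parametrize(
        "row,interval,expected_rt,expected_events",
        [([1, 1, 0, 1, 0], 1.0, 1.5, 2),
         ([1, 1, 1, 1], 1.0, 4.0, 1),
         ([0, 0, 0, 0], 1.0, 0.0, 0),
         ([1, 1, 0, 1, 0], 2.0, 3.0, 2)],
    )
    def test_residence_time_formula(self, row, interval, expected_rt, expected_events):
        cm = make_matrix([row], frame_interval=interval)
        rt = jm.residence_time(cm)
        assert rt.loc["JM1", "residence_time"] == pytest.approx(expected_rt)
        assert rt.loc["JM1", "n_events"] == expected_events

    def test_residence_runs_do_not_bridge_replicates(self):
        # occupied across the boundary: one run per segment, not one long run
        cm = make_matrix([[1, 1, 1, 1]], segments=(2, 2))
        rt = jm.residence_time(cm)
        assert rt.loc["JM1", "n_events"] == 2
        assert rt.loc["JM1", "residence_time"] == pytest.approx(2.0)

    def test_full_occupancy_means_single_event_spanning_all(self):
        cm = make_matrix([[3, 1, 2, 1]])
        assert jm.occupancy_fraction(cm)["JM1"] == 100.0
        rt = jm.residence_time(cm)
        assert rt.loc["JM1", "n_events"] == 1
        assert rt.loc["JM1", "residence_time"] == pytest.approx(4.0)

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=40))
    @settings(max_examples=80, derandomize=True)
    def test_residence_time_against_run_length_oracle(self, row):
        """Formula agrees with explicit run enumeration on random series."""
        cm = make_matrix([row])
        occupied = [c >= 1 for c in row]
        runs = []
        current = 0
        for o in occupied:
            if o:
                current += 1
            elif current:
                runs.append(current)
                current = 0
        if current:
            runs.append(current)
        rt = jm.residence_time(cm)
        assert rt.loc["JM1", "n_events"] == len(runs)
        expected = sum(runs) / len(runs) if runs else 0.0
        assert rt.loc["JM1", "residence_time"] == pytest.approx(expected)
        assert rt.loc["JM1", "residence_time"] <= len(row) * 1.0

    def test_empty_matrix_raises(self):
        cm = make_matrix(np.zeros((2, 0)))
        for fn in (jm.mean_contacts, jm.occupancy_fraction, jm.residence_time):
            with pytest.raises(EmptyInputError):
                fn(cm)


class TestFirstShell:
    def test_pinned_lipid_counts_once(self):
        anchors = jm.ProteinAnchors(
            xy=np.array([[10.0, 10.0], [14.0, 10.0]]), labels=("TM", "JM1"),
            classes=("TM", "basic"), charges=np.array([0, 1]), receptor_id="t",
        )
        # within 6 A of both anchors in every frame -> still one bead
        pos = np.tile(np.array([[12.0, 10.0]]), (5, 1, 1))
        traj = jm.Trajectory(
            lipid_xy=pos, species=np.array(["PIP2"], dtype="U8"), anchors=anchors,
            box_edge=40.0, frame_interval=1.0, seed=0,
        )
        assert jm.first_shell_count(traj, "PIP2") == 1.0

    def test_no_lipid_in_shell(self):
        anchors = jm.ProteinAnchors(
            xy=np.array([[5.0, 5.0]]), labels=("TM",), classes=("TM",),
            charges=np.array([0]), receptor_id="t",
        )
        pos = np.tile(np.array([[30.0, 30.0]]), (4, 1, 1))
        traj = jm.Trajectory(
            lipid_xy=pos, species=np.array(["PIP2"], dtype="U8"), anchors=anchors,
            box_edge=60.0, frame_interval=1.0, seed=0,
        )
        assert jm.first_shell_count(traj, "PIP2") == 0.0


def test_basic_residues_hold_pip2_longer_than_polar(production_runs):
    """Basic JM residues show longer mean PIP2 residence than polar ones."""
    cm = jm.count_contacts(production_runs, "PIP2")
    rt = jm.residence_time(cm)["residence_time"]
    anchors = production_runs[0].anchors
    basic = [lb for lb, cl in zip(anchors.labels, anchors.classes) if cl == "basic"]
    polar = [lb for lb, cl in zip(anchors.labels, anchors.classes) if cl == "polar"]
    assert rt[basic].mean() > rt[polar].mean()
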