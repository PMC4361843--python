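"""Simulator contracts: determinism, conservation, geometry, calibration."""

import numpy as np
import pytest
from scipy import stats

import jmlipid as jm
from jmlipid.errors import CalibrationError, GeometryError
from jmlipid.simulate import quick_config


class TestPlaceProtein:
    def test_anchor_count_and_spacing(self, insr_model):
        anchors = jm.place_protein(insr_model, 150.0)
        assert anchors.n_anchors == 21
        assert anchors.labels[0] == "TM"
        # residue 5 sits 5 * 3.5 A from the TM anchor
        d = np.linalg.norm(anchors.xy[5] - anchors.xy[0])
        assert d == pytest.approx(5 * 3.5)

    def test_empty_jm_single_anchor(self):
        anchors = jm.place_protein(jm.tm_only_model(), 150.0)
        assert anchors.n_anchors == 1
        assert anchors.labels == ("TM",)

    def test_arm_exceeding_half_box_raises(self, insr_model):
        with pytest.raises(GeometryError):
            jm.place_protein(insr_model, 100.0)  # arm 70 A > 50 A

    def test_charges_follow_sequence(self, insr_model):
        anchors = jm.place_protein(insr_model, 150.0)
        assert anchors.charges[0] == 0
        assert anchors.charges[1:].tolist() == list(insr_model.per_residue_charge)


class TestSimulate:
    def test_same_seed_bit_identical(self, insr_model):
        config = quick_config(seed=3, n_frames=5, save_stride=20, n_equil_steps=200)
        anchors = jm.place_protein(insr_model, config.box_edge)
        t1 = jm.simulate(anchors, jm.INNER_LEAFLET_SIMPLE, config)
        t2 = jm.simulate(anchors, jm.INNER_LEAFLET_SIMPLE, config)
        assert np.array_equal(t1.lipid_xy, t2.lipid_xy)
        assert np.array_equal(t1.species, t2.species)

    def test_replicates_differ(self, quick_runs):
        assert not np.array_equal(quick_runs[0].lipid_xy, quick_runs[1].lipid_xy)
        assert quick_runs[0].seed != quick_runs[1].seed

    def test_species_conserved_and_wrapped(self, quick_runs):
        traj = quick_runs[0]
        assert traj.lipid_xy.shape[1] == len(traj.species)
        assert np.all((traj.lipid_xy >= 0) & (traj.lipid_xy < traj.box_edge))

    def test_frame_interval(self, quick_runs):
        cfg = quick_config()
        assert quick_runs[0].frame_interval == cfg.timestep * cfg.save_stride

    def test_instability_detected_for_huge_timestep(self, insr_model):
        from jmlipid.errors import InstabilityError

        config = quick_config(seed=1, timestep=50.0, n_frames=2, save_stride=5,
                              n_equil_steps=0)
        anchors = jm.place_protein(insr_model, config.box_edge)
        with pytest.raises(InstabilityError):
            jm.simulate(anchors, jm.INNER_LEAFLET_SIMPLE, config)


class TestNeutralControls:
    def test_uniform_density_without_charges(self, insr_model):
        """epsilon = 0: density outside the footprint is uniform (chi^2).

        One well-separated frame is taken per independent replicate so the
        pooled bead positions are effectively independent samples; frames
        within one replicate decorrelate far too slowly for a chi^2 count
        test.
        """
        config = quick_config(seed=4, epsilon_elec=0.0, n_frames=2,
                              save_stride=50, n_equil_steps=3000)
        anchors = jm.place_protein(insr_model, config.box_edge)
        trajs = jm.simulate_replicates(anchors, jm.INNER_LEAFLET_SIMPLE, config, 4)
        box = config.box_edge
        n_cells = 5
        counts = np.zeros((n_cells, n_cells))
        for traj in trajs:
            idx = (traj.lipid_xy[-1] / box * n_cells).astype(int).clip(0, n_cells - 1)
            np.add.at(counts, (idx[:, 0], idx[:, 1]), 1)
        # drop the row of cells containing the anchor arm (excluded volume)
        arm_row = int(anchors.xy[0, 1] / box * n_cells)
        keep = counts[:, [r for r in range(n_cells) if r != arm_row]].ravel()
        expected = keep.sum() / keep.size
        chi2 = np.sum((keep - expected) ** 2 / expected)
        p = stats.chi2.sf(chi2, keep.size - 1)
        assert p > 0.01

    def test_no_species_preference_without_charges(self, insr_model):
        """epsilon = 0: PIP2 and PC RDFs statistically indistinguishable."""
        config = quick_config(seed=8, epsilon_elec=0.0)
        anchors = jm.place_protein(insr_model, config.box_edge)
        trajs = jm.simulate_replicates(anchors, jm.INNER_LEAFLET_SIMPLE, config, 3)
        shell_pip2 = [jm.lateral_rdf(t, "PIP2").values[4] for t in trajs]
        shell_pc = [jm.lateral_rdf(t, "PC").values[4] for t in trajs]
        # paired per-replicate differences show no systematic sign
        diffs = np.array(shell_pip2) - np.array(shell_pc)
        assert np.abs(diffs.mean()) < 3 * (diffs.std(ddof=1) / np.sqrt(len(diffs)) + 1e-12) + 0.05


class TestCalibration:
    def test_monotone_first_shell_in_epsilon(self, insr_model):
        """Mean first-shell count increases with coupling over a coarse grid."""
        config = quick_config(seed=2, n_frames=80, save_stride=60,
                              n_equil_steps=3000)
        anchors = jm.place_protein(insr_model, config.box_edge)
        counts = []
        from dataclasses import replace

        for eps in (0.0, 10.0, 40.0):
            traj = jm.simulate(
                anchors, jm.INNER_LEAFLET_SIMPLE, replace(config, epsilon_elec=eps)
            )
            counts.append(jm.first_shell_count(traj, "PIP2"))
        assert counts[0] < counts[1] < counts[2]

    def test_trivial_window_returns_smallest_grid_value(self, insr_model):
        config = quick_config(seed=2, n_frames=10, save_stride=10, n_equil_steps=100)
        anchors = jm.place_protein(insr_model, config.box_edge)
        res = jm.calibrate_affinity(
            anchors, jm.INNER_LEAFLET_SIMPLE, config,
            target_window=(0.0, np.inf), epsilon_grid=(5.0, 10.0),
        )
        assert res.epsilon_elec == 5.0

    def test_unreachable_window_raises(self, insr_model):
        """Excluded volume alone cannot reach a 4-6 PIP2 shell at 10% PIP2."""
        config = quick_config(seed=2, n_frames=40, save_stride=40, n_equil_steps=1500)
        anchors = jm.place_protein(insr_model, config.box_edge)
        with pytest.raises(CalibrationError):
            jm.calibrate_affinity(
                anchors, jm.INNER_LEAFLET_SIMPLE, config,
                target_window=(4.0, 6.0), epsilon_grid=(0.0,),
            )
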