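"""Lateral RDFs, peak detection, density maps and RMSF."""

import numpy as np
import pytest

import jmlipid as jm
from jmlipid.errors import GeometryError, UnknownSpeciesError
from jmlipid.spatial import RDFProfile


def _uniform_trajectory(seed=0, n_frames=600, n_beads=300, box=100.0):
    rng = np.random.default_rng(seed)
    anchors = jm.ProteinAnchors(
        xy=np.array([[box / 2, box / 2]]), labels=("TM",), classes=("TM",),
        charges=np.array([0]), receptor_id="uniform",
    )
    return jm.Trajectory(
        lipid_xy=rng.uniform(0, box, size=(n_frames, n_beads, 2)),
        species=np.array(["PC"] * n_beads, dtype="U8"),
        anchors=anchors, box_edge=box, frame_interval=1.0, seed=seed,
    )


class TestLateralRDF:
    def test_unit_area_invariant(self, toy_trajectory):
        for sp in ("PIP2", "PS", "PC"):
            rdf = jm.lateral_rdf(toy_trajectory, sp, bin_width=1.0, r_max=25.0)
            assert abs(np.sum(rdf.values) * rdf.bin_width - 1.0) < 1e-6
            for rep in rdf.replicate_values:
                assert abs(np.sum(rep) * rdf.bin_width - 1.0) < 1e-6
            assert np.all(rdf.values >= 0)

    def test_uniform_density_gives_flat_profile(self):
        """Uniform beads around a point protein: value ~ 1/r_max per bin."""
        rdf = jm.lateral_rdf(_uniform_trajectory(), "PC", 1.0, 30.0)
        assert rdf.values == pytest.approx(np.full(30, 1 / 30), rel=0.2)

    def test_delta_distribution_single_bin(self):
        """All beads pinned at one distance: single bin of height 1/width."""
        box = 80.0
        anchors = jm.ProteinAnchors(
            xy=np.array([[40.0, 40.0]]), labels=("TM",), classes=("TM",),
            charges=np.array([0]), receptor_id="d",
        )
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = 40.0 + 7.3 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        traj = jm.Trajectory(
            lipid_xy=np.tile(ring, (5, 1, 1)),
            species=np.array(["PIP2"] * 12, dtype="U8"),
            anchors=anchors, box_edge=box, frame_interval=1.0, seed=0,
        )
        rdf = jm.lateral_rdf(traj, "PIP2", 1.0, 20.0)
        assert rdf.values[7] == pytest.approx(1.0)  # bin [7,8) holds 7.3
        assert np.sum(rdf.values > 0) == 1

    def test_r_max_beyond_half_box_raises(self, toy_trajectory):
        with pytest.raises(GeometryError):
            jm.lateral_rdf(toy_trajectory, "PC", 1.0, toy_trajectory.box_edge)

    def test_unknown_species_raises(self, toy_trajectory):
        with pytest.raises(UnknownSpeciesError):
            jm.lateral_rdf(toy_trajectory, "CHOL")


class TestFirstPeak:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        values /= values.sum()
        n = len(values)
        return RDFProfile(
            bin_edges=np.arange(n + 1.0), values=values, std=np.zeros(n),
            replicate_values=values[None, :], species="PIP2",
            r_max=float(n), bin_width=1.0,
        )

    def test_example_profile(self):
        assert jm.first_peak(self._profile([0, 1, 3, 2, 2, 4, 1])) == 2.5

    def test_decreasing_profile_first_bin(self):
        assert jm.first_peak(self._profile([5, 4, 3, 2, 1])) == 0.5

    def test_no_peak_returns_none(self):
        assert jm.first_peak(self._profile([1, 1, 1, 1])) is None

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            jm.first_peak(self._profile([1, 2]))


class TestDensityMap:
    def test_immobile_bead_occupancy_one(self):
        box = 20.0
        anchors = jm.ProteinAnchors(
            xy=np.array([[10.0, 10.0]]), labels=("TM",), classes=("TM",),
            charges=np.array([0]), receptor_id="d",
        )
        pos = np.tile(np.array([[3.5, 7.5]]), (6, 1, 1))
        traj = jm.Trajectory(
            lipid_xy=pos, species=np.array(["PS"], dtype="U8"), anchors=anchors,
            box_edge=box, frame_interval=1.0, seed=0,
        )
        dmap = jm.density_map(traj, "PS", cell=1.0)
        assert dmap.occupancy[3, 7] == 1.0
        assert dmap.occupancy.sum() == 1.0

    def test_values_are_fractions(self, toy_trajectory):
        dmap = jm.density_map(toy_trajectory, "PC", cell=2.0)
        assert np.all((dmap.occupancy >= 0) & (dmap.occupancy <= 1))

    def test_enrichment_near_jm_matches_contacts(self, quick_runs):
        """PIP2 occupancy near the JM arm exceeds the box-wide average."""
        dmap = jm.density_map(quick_runs, "PIP2", cell=2.0)
        traj = quick_runs[0]
        xc = 0.5 * (dmap.x_edges[:-1] + dmap.x_edges[1:])
        yc = 0.5 * (dmap.y_edges[:-1] + dmap.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        from jmlipid.trajectory import minimum_image_distances

        d = minimum_image_distances(pts, traj.anchors.xy, traj.box_edge)
        near = d.reshape(dmap.occupancy.shape) <= 6.0
        assert dmap.occupancy[near].mean() > dmap.occupancy.mean()


class TestRMSF:
    def test_static_track_zero(self):
        track = np.tile(np.array([[1.0, 2.0]]), (10, 1, 1))
        assert jm.rmsf(track).iloc[0] == 0.0

    def test_two_frame_example(self):
        track = np.array([[[0.0, 0.0]], [[2.0, 0.0]]])
        assert jm.rmsf(track).iloc[0] == pytest.approx(1.0)

    def test_gaussian_jitter_converges_to_sigma_sqrt2(self):
        """2D i.i.d. Gaussian jitter with std sigma -> RMSF = sigma * sqrt(2)."""
        rng = np.random.default_rng(12)
        sigma = 0.7
        track = rng.normal(0, sigma, size=(20000, 3, 2))
        values = jm.rmsf(track, labels=["a", "b", "c"])
        assert values.values == pytest.approx(sigma * np.sqrt(2), rel=0.03)

    def test_single_frame_raises(self):
        from jmlipid.errors import EmptyInputError

        with pytest.raises(EmptyInputError):
            jm.rmsf(np.zeros((1, 2, 2)))


def test_first_shell_rdf_ordering_with_replicates(production_runs):
    """First-shell RDF orders PIP2 > PS > PC in every replicate set."""
    shell = {}
    for sp in ("PIP2", "PS", "PC"):
        rdf = jm.lateral_rdf(production_runs, sp)
        shell[sp] = rdf.values[4]  # bin [4,5): the contact shell
    assert shell["PIP2"] > shell["PS"] > shell["PC"]


def test_anionic_rdf_has_interior_maximum(production_runs):
    """Shell structure: the PIP2 profile is nonmonotone with an interior peak."""
    rdf = jm.lateral_rdf(production_runs, "PIP2")
    peak = jm.first_peak(rdf)
    assert peak is not None and 0 < peak < rdf.r_max
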