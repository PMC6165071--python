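import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rinpipe.geometry import (
    GeometrySeries,
    angle_series,
    assign_ss_lite,
    dihedral_series,
    distance_series,
    hbond_occupancy,
    phi_psi,
    turn_occupancy,
    window_occupancy,
)
from rinpipe.synthetic import (
    ChainSpec,
    HbondPlant,
    PlantSpec,
    TwoStateSpec,
    build_ideal_chain,
    plant_hbonds,
    plant_two_state_segment,
)
from conftest import make_points_ensemble


class TestDistance:
    def test_three_four_five(self):
        ens = make_points_ensemble([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        assert distance_series(ens, 0, 1).values[0] == pytest.approx(5.0)

    def test_same_atom_zero(self):
        ens = make_points_ensemble([[[1.0, 2, 3]]])
        assert distance_series(ens, 0, 0).values[0] == 0.0

    def test_matches_loop_oracle(self, noisy_helix):
        series = distance_series(noisy_helix, 0, 17)
        for f in range(noisy_helix.n_frames):
            d = noisy_helix.coords[f, 0] - noisy_helix.coords[f, 17]
            assert series.values[f] == pytest.approx(
                float(np.sqrt(d @ d)), abs=1e-12
            )


class TestAngle:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]], 180.0),  # collinear
            ([[1.0, 0, 0], [0, 0, 0], [0, 1, 0]], 90.0),  # right angle
            ([[1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0], [0, 0, 0]], 60.0),
        ],
    )
    def test_closed_forms(self, points, expected):
        ens = make_points_ensemble([points])
        assert angle_series(ens, 0, 1, 2).values[0] == pytest.approx(expected)

    def test_coincident_atoms_raise(self):
        ens = make_points_ensemble([[[0.0, 0, 0], [0.0, 0, 0], [1, 0, 0]]])
        with pytest.raises(ValueError):
            angle_series(ens, 0, 1, 2)


class TestDihedral:
    def test_planar_cis_zero(self):
        pts = [[1.0, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        ens = make_points_ensemble([pts])
        assert dihedral_series(ens, 0, 1, 2, 3).values[0] == pytest.approx(
            0.0, abs=1e-10
        )

    def test_planar_trans_180(self):
        pts = [[1.0, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]
        ens = make_points_ensemble([pts])
        assert abs(dihedral_series(ens, 0, 1, 2, 3).values[0]) == pytest.approx(
            180.0, abs=1e-10
        )

    def test_helix_chain_identity(self):
        ens = build_ideal_chain(ChainSpec(8))
        phi, psi = phi_psi(ens, 4)
        assert phi.values[0] == pytest.approx(-57.0, abs=1e-3)
        assert psi.values[0] == pytest.approx(-47.0, abs=1e-3)

    def test_terminal_residue_raises(self):
        ens = build_ideal_chain(ChainSpec(4))
        with pytest.raises(KeyError):
            phi_psi(ens, 1)
        with pytest.raises(KeyError):
            phi_psi(ens, 4)

    def test_sign_flips_under_mirror(self, noisy_helix):
        """A signed dihedral is a chirality-sensitive quantity."""
        mirrored = make_points_ensemble(
            noisy_helix.coords * np.array([-1.0, 1.0, 1.0])
        )
        a = dihedral_series(noisy_helix, 0, 1, 2, 3).values
        b = dihedral_series(mirrored, 0, 1, 2, 3).values
        assert np.allclose(a, -b, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 5
        rot = Rotation.random(rng=rng)
        moved = rot.apply(pts) + rng.uniform(-10, 10, 3)
        e1 = make_points_ensemble([pts])
        e2 = make_points_ensemble([moved])
        assert dihedral_series(e1, 0, 1, 2, 3).values[0] == pytest.approx(
            dihedral_series(e2, 0, 1, 2, 3).values[0], abs=1e-8
        )
        assert angle_series(e1, 0, 1, 2).values[0] == pytest.approx(
            angle_series(e2, 0, 1, 2).values[0], abs=1e-8
        )
        assert distance_series(e1, 0, 1).values[0] == pytest.approx(
            distance_series(e2, 0, 1).values[0], abs=1e-8
        )


class TestWindowOccupancy:
    def test_all_inside(self):
        s = GeometrySeries("angle", (0, 1, 2), np.full(50, 110.0))
        assert window_occupancy(s) == 100.0

    def test_all_at_75_outside(self):
        # 75 deg lies outside the 110 +/- 20 deg catalytic window
        s = GeometrySeries("angle", (0, 1, 2), np.full(50, 75.0))
        assert window_occupancy(s) == 0.0

    def test_half_and_half(self):
        s = GeometrySeries(
            "angle", (0, 1, 2), np.r_[np.full(25, 110.0), np.full(25, 75.0)]
        )
        assert window_occupancy(s) == 50.0

    def test_boundary_closed(self):
        s = GeometrySeries("angle", (0, 1, 2), np.array([130.0, 90.0]))
        assert window_occupancy(s) == 100.0

    def test_empty_raises(self):
        s = GeometrySeries("angle", (0, 1, 2), np.empty(0))
        with pytest.raises(ValueError):
            window_occupancy(s)


class TestHbonds:
    def test_beyond_cutoff_zero(self):
        ens = make_points_ensemble(
            [[[0.0, 0, 0], [4.2, 0, 0]]], elements=["N", "O"]
        )
        t = hbond_occupancy(ens, [0], [1])
        assert t.rows["occupancy"].iloc[0] == 0.0

    def test_distance_only_fallback_without_h(self):
        ens = make_points_ensemble(
            [[[0.0, 0, 0], [2.9, 0, 0]]], elements=["N", "O"]
        )
        t = hbond_occupancy(ens, [0], [1])
        assert t.rows["occupancy"].iloc[0] == 100.0

    def test_angle_criterion_with_hydrogen(self):
        # donor N with H pointing at (resp. away from) the acceptor
        toward = [[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]]
        away = [[0.0, 0, 0], [0, 1.0, 0], [2.9, 0, 0]]
        for pts, expected in ((toward, 100.0), (away, 0.0)):
            ens = make_points_ensemble(
                [pts],
                elements=["N", "H", "O"],
                resids=[1, 1, 2],
                names=["N", "H", "O"],
            )
            t = hbond_occupancy(ens, [0], [2])
            assert t.rows["occupancy"].iloc[0] == expected

    def test_monotone_in_cutoffs(self, noisy_helix):
        donors = [i for i, a in enumerate(noisy_helix.topology.atoms) if a.name == "N"]
        acceptors = [i for i, a in enumerate(noisy_helix.topology.atoms) if a.name == "O"]
        loose = hbond_occupancy(noisy_helix, donors, acceptors, 4.0, 40.0)
        strict = hbond_occupancy(noisy_helix, donors, acceptors, 3.0, 20.0)
        merged = loose.rows.merge(
            strict.rows, on=["donor", "acceptor"], suffixes=("_l", "_s")
        )
        assert (merged["occupancy_s"] <= merged["occupancy_l"] + 1e-9).all()

    def test_carbon_acceptors_excluded_by_default(self):
        ens = make_points_ensemble(
            [[[0.0, 0, 0], [2.9, 0, 0]]],
            elements=["N", "C"],
            names=["N", "CB"],
        )
        t = hbond_occupancy(ens, [0], [1])
        assert len(t.rows) == 0
        t2 = hbond_occupancy(ens, [0], [1], allow_any_acceptor=True)
        assert len(t2.rows) == 1

    def test_empty_lists_raise(self, noisy_helix):
        with pytest.raises(ValueError):
            hbond_occupancy(noisy_helix, [], [1])

    def test_rows_sorted_descending(self):
        ts = TwoStateSpec(segment=(10, 20), switch_frame=50)
        ens = plant_two_state_segment(ChainSpec(40), ts, 100, seed=0)
        plants = PlantSpec(
            hbonds=[
                HbondPlant((5, "N"), (30, "O"), 0.2),
                HbondPlant((6, "N"), (32, "O"), 0.9),
            ]
        )
        planted = plant_hbonds(ens, plants, seed=1)
        t = hbond_occupancy(
            planted, [(5, "N"), (6, "N")], [(30, "O"), (32, "O")]
        )
        occ = t.rows["occupancy"].to_numpy()
        assert (np.diff(occ) <= 0).all()
        assert occ[0] == pytest.approx(90.0)


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        ens = build_ideal_chain(ChainSpec(12))
        track = assign_ss_lite(ens)
        assert (track.classes[:, 1:-1] == "H").all()
        # termini have undefined phi/psi and stay "other"
        assert (track.classes[:, 0] == "-").all()

    def test_extended_chain_has_no_helix(self):
        n = 12
        ens = build_ideal_chain(
            ChainSpec(n, phi_psi=np.tile([180.0, 180.0], (n, 1)))
        )
        track = assign_ss_lite(ens)
        assert not (track.classes == "H").any()

    def test_turn_occupancy_extremes(self):
        helix = build_ideal_chain(ChainSpec(12))
        track = assign_ss_lite(helix, (2, 11))
        assert turn_occupancy(track, (2, 11)) == 0.0
        n = 12
        other = build_ideal_chain(
            ChainSpec(n, phi_psi=np.tile([70.0, 70.0], (n, 1)))
        )
        track2 = assign_ss_lite(other, (2, 11))
        assert turn_occupancy(track2, (2, 11)) == 100.0

    def test_half_switch_recovery(self):
        """Planted two-state cap switch recovered within one frame."""
        n_frames = 80
        ts = TwoStateSpec(segment=(10, 20), switch_frame=n_frames // 2)
        ens = plant_two_state_segment(ChainSpec(40), ts, n_frames, seed=3)
        track = assign_ss_lite(ens)
        occ = turn_occupancy(track, (10, 20))
        assert abs(occ - 50.0) <= 100.0 / n_frames

    def test_bad_range_raises(self):
        ens = build_ideal_chain(ChainSpec(6))
        track = assign_ss_lite(ens)
        with pytest.raises(ValueError):
            turn_occupancy(track, (100, 120))
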