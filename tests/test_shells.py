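"""Water perception, RDFs, shell cutoffs, cluster carving, coordination."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from conftest import fake_water_frame, image_distance, single_water_frame
from mdifm.errors import ShellStructureError, WaterPerceptionError
from mdifm.frames import Frame
from mdifm.shells import (
    ProbeSpec,
    RadialDistribution,
    ShellCutoffs,
    carve_cluster,
    compute_rdf,
    count_first_shell,
    locate_shell_cutoffs,
    perceive_waters,
    snapshot_schedule,
)


class TestPerceiveWaters:
    def test_single_intact_water(self):
        waters = perceive_waters(single_water_frame())
        assert len(waters) == 1
        assert waters[0].indices == (0, 1, 2)

    def test_random_box_matches_nearest_oxygen_oracle(self, water_box):
        waters = perceive_waters(water_box)
        # oracle: exhaustive pairwise image distances, nearest O per H
        els = water_box.elements
        o_idx = [i for i, e in enumerate(els) if e == "O"]
        assignment = {}
        for h in (i for i, e in enumerate(els) if e == "H"):
            d = [image_distance(water_box.coords[h] % water_box.box,
                                water_box.coords[o][None, :] % water_box.box,
                                water_box.box) for o in o_idx]
            assert min(d) < 1.25
            assignment.setdefault(o_idx[int(np.argmin(d))], set()).add(h)
        got = {w.o: {w.h1, w.h2} for w in waters}
        assert got == assignment

    def test_lone_oxygen_rejected_with_index(self):
        frame = Frame(np.array(["O", "H", "H", "O"], dtype=object),
                      np.array([[5, 5, 5], [5.96, 5, 5], [4.76, 5.73, 5], [1, 1, 1.0]]),
                      np.full(3, 20.0))
        with pytest.raises(WaterPerceptionError) as exc:
            perceive_waters(frame)
        assert exc.value.atom_index == 3

    def test_stray_hydrogen_rejected(self):
        frame = Frame(np.array(["O", "H", "H", "H"], dtype=object),
                      np.array([[5, 5, 5], [5.96, 5, 5], [4.76, 5.73, 5], [12, 12, 12.0]]),
                      np.full(3, 20.0))
        with pytest.raises(WaterPerceptionError) as exc:
            perceive_waters(frame)
        assert exc.value.atom_index == 3

    def test_non_water_species_rejected(self):
        frame = Frame(np.array(["O", "H", "H", "Na"], dtype=object),
                      np.array([[5, 5, 5], [5.96, 5, 5], [4.76, 5.73, 5], [1, 1, 1.0]]),
                      np.full(3, 20.0))
        with pytest.raises(WaterPerceptionError):
            perceive_waters(frame)

    def test_assignment_uses_minimum_image(self):
        # O at the box corner, its hydrogens across the boundary
        frame = Frame(np.array(["O", "H", "H"], dtype=object),
                      np.array([[0.1, 0.1, 0.1], [19.3, 0.1, 0.1], [0.1, 19.3, 0.1]]),
                      np.full(3, 20.0))
        waters = perceive_waters(frame)
        assert len(waters) == 1


class TestComputeRdf:
    def test_homogeneous_poisson_gr_tends_to_one(self):
        rng = np.random.default_rng(11)
        box = np.full(3, 20.0)
        frames, waters = [], []
        for _ in range(40):
            f, w = fake_water_frame(rng.uniform(0, 20.0, (600, 3)), box)
            frames.append(f)
            waters.append(w)
        rdf = compute_rdf(frames, waters, r_max=8.0, dr=0.2)
        sel = rdf.r > 2.0
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 0.05)

    def test_single_pair_all_counts_in_one_bin(self):
        box = np.full(3, 30.0)
        o = np.array([[5.0, 5, 5], [5 + 3.17, 5, 5]])
        frame, waters = fake_water_frame(o, box)
        rdf = compute_rdf([frame], waters, r_max=10.0, dr=0.05)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert abs(rdf.r[occupied[0]] - 3.17) <= 0.05 / 2

    def test_simple_cubic_first_peak_at_lattice_spacing(self):
        a = 4.0
        pts = np.array([[i, j, k] for i in range(3) for j in range(3) for k in range(3)],
                       dtype=float) * a + 0.5
        frame, waters = fake_water_frame(pts, np.full(3, 3 * a))
        rdf = compute_rdf([frame], waters, r_max=5.5, dr=0.05)
        first_peak = rdf.r[np.flatnonzero(rdf.g > 0)[0]]
        assert abs(first_peak - a) <= 0.05

    def test_r_max_beyond_half_box_rejected(self):
        frame, waters = fake_water_frame(np.array([[5.0, 5, 5]]), np.full(3, 12.0))
        with pytest.raises(ValueError, match="minimum-image"):
            compute_rdf([frame], waters, r_max=6.5)


def _synthetic_gr(r):
    """Water-like g(r): three damped oscillations with known extrema."""
    return (1.0
            + 1.0 * np.exp(-((r - 2.8) ** 2) / 0.05)
            - 0.6 * np.exp(-((r - 3.4) ** 2) / 0.05)
            + 0.40 * np.exp(-((r - 4.5) ** 2) / 0.08)
            - 0.20 * np.exp(-((r - 5.3) ** 2) / 0.08)
            + 0.20 * np.exp(-((r - 6.4) ** 2) / 0.10)
            - 0.10 * np.exp(-((r - 7.2) ** 2) / 0.10))


class TestShellCutoffs:
    def test_minima_of_constructed_gr(self):
        dr = 0.05
        r = np.arange(dr / 2, 9.0, dr)
        rdf = RadialDistribution(r, np.clip(_synthetic_gr(r), 0, None), dr)
        cut = locate_shell_cutoffs(rdf)
        # independent oracle: numerical minima of the analytic curve
        m1 = minimize_scalar(_synthetic_gr, bounds=(3.0, 4.0), method="bounded").x
        m3 = minimize_scalar(_synthetic_gr, bounds=(6.8, 8.0), method="bounded").x
        assert abs(cut.r_first_min - m1) <= 2 * dr
        assert abs(cut.r_third_min - m3) <= 2 * dr

    def test_water_like_first_minimum_window(self):
        dr = 0.05
        r = np.arange(dr / 2, 9.0, dr)
        rdf = RadialDistribution(r, np.clip(_synthetic_gr(r), 0, None), dr)
        cut = locate_shell_cutoffs(rdf)
        assert 3.2 <= cut.r_first_min <= 3.6

    def test_monotone_gr_has_no_shells(self):
        dr = 0.05
        r = np.arange(dr / 2, 9.0, dr)
        rdf = RadialDistribution(r, r / r.max(), dr)
        with pytest.raises(ShellStructureError):
            locate_shell_cutoffs(rdf)


class TestCarveCluster:
    CUT = ShellCutoffs(3.4, 5.0)

    def test_probe_alone(self):
        frame = single_water_frame()
        waters = perceive_waters(frame)
        probe = ProbeSpec(waters[0], waters[0].h1)
        cluster = carve_cluster(frame, probe, self.CUT, mode="radius", waters=waters)
        assert cluster.n_molecules == 1
        assert cluster.n_first_shell == 0

    def test_radius_membership_matches_image_oracle(self, small_box, probe_and_waters):
        probe, waters = probe_and_waters
        cluster = carve_cluster(small_box, probe, self.CUT, mode="radius", waters=waters)
        po = small_box.coords[probe.water.o] % small_box.box
        expected = {
            w.o for w in waters if w.o != probe.water.o
            and image_distance(po, (small_box.coords[w.o] % small_box.box)[None, :],
                               small_box.box) < self.CUT.r_third_min
        }
        got = set(cluster.source_indices[3::3].tolist())
        assert got == expected

    def test_cross_boundary_neighbor_unwrapped(self):
        box = np.full(3, 20.0)
        # probe at the corner; neighbor wrapped to the far corner, true distance 2.8 Å
        probe_o = np.array([0.2, 0.2, 0.2])
        nb_o = np.array([20.0 - 1.4165, 20.0 - 1.4165, 20.0 - 1.4165])
        coords = np.vstack([
            probe_o, probe_o + [0.96, 0, 0], probe_o + [-0.24, 0.93, 0],
            nb_o, nb_o + [0.96, 0, 0], nb_o + [-0.24, 0.93, 0],
        ])
        frame = Frame(np.array(["O", "H", "H"] * 2, dtype=object), coords, box)
        waters = perceive_waters(frame)
        probe = ProbeSpec(waters[0], waters[0].h1)
        cluster = carve_cluster(frame, probe, self.CUT, mode="radius", waters=waters)
        assert cluster.n_molecules == 2
        assert cluster.n_first_shell == 1
        d = np.linalg.norm(cluster.coords[3] - cluster.coords[0])
        assert d == pytest.approx(2.8, abs=1e-3)  # contiguous, not wrapped

    def test_nearest_n_exact_count_and_error(self, small_box, probe_and_waters):
        probe, waters = probe_and_waters
        cluster = carve_cluster(small_box, probe, self.CUT, mode="nearest_n", n=29,
                                waters=waters)
        assert cluster.n_molecules == 30
        with pytest.raises(ValueError, match="available"):
            carve_cluster(small_box, probe, self.CUT, mode="nearest_n", n=60, waters=waters)

    def test_cluster_size_nondecreasing_in_radius(self, small_box, probe_and_waters):
        probe, waters = probe_and_waters
        sizes = [
            carve_cluster(small_box, probe, ShellCutoffs(3.0, r3), mode="radius",
                          waters=waters).n_molecules
            for r3 in np.linspace(3.2, 6.0, 8)
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_molecules_are_whole(self, small_box, probe_and_waters):
        probe, waters = probe_and_waters
        cluster = carve_cluster(small_box, probe, self.CUT, mode="radius", waters=waters)
        for m in range(cluster.n_molecules):
            o, h1, h2 = cluster.coords[3 * m : 3 * m + 3]
            assert np.linalg.norm(h1 - o) < 1.25
            assert np.linalg.norm(h2 - o) < 1.25


class TestCountFirstShell:
    def _frame_with_neighbors(self, dists):
        box = np.full(3, 30.0)
        center = np.full(3, 15.0)
        mols = [center]
        for k, d in enumerate(dists):
            direction = np.zeros(3)
            direction[k % 3] = 1 if k < 3 else -1
            mols.append(center + d * direction)
        coords = []
        for o in mols:
            coords += [o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]]
        frame = Frame(np.array(["O", "H", "H"] * len(mols), dtype=object),
                      np.array(coords), box)
        return frame, perceive_waters(frame)

    def test_four_neighbors_at_2p8(self):
        frame, waters = self._frame_with_neighbors([2.8] * 4)
        probe = ProbeSpec(waters[0], waters[0].h1)
        assert count_first_shell(frame, probe, 3.4, waters) == 4

    def test_boundary_is_strict(self):
        # 3.5 is exactly representable, so the neighbor sits exactly at r1
        frame, waters = self._frame_with_neighbors([3.5])
        probe = ProbeSpec(waters[0], waters[0].h1)
        assert count_first_shell(frame, probe, 3.5, waters) == 0
        assert count_first_shell(frame, probe, 3.5 + 1e-9, waters) == 1

    def test_matches_carve_first_shell_subset(self, small_box, probe_and_waters):
        probe, waters = probe_and_waters
        cut = ShellCutoffs(3.4, 5.0)
        cluster = carve_cluster(small_box, probe, cut, mode="radius", waters=waters)
        assert count_first_shell(small_box, probe, cut.r_first_min, waters) \
            == cluster.n_first_shell

    def test_matches_brute_force_on_random_frames(self):
        from mdifm.kubo import SyntheticBoxParams, generate_water_box

        for seed in range(10):
            frame = generate_water_box(SyntheticBoxParams(n_waters=40, box_length=11.0,
                                                          seed=seed))
            waters = perceive_waters(frame)
            probe = ProbeSpec(waters[0], waters[0].h1)
            po = frame.coords[probe.water.o] % frame.box
            oracle = sum(
                1 for w in waters[1:]
                if image_distance(po, (frame.coords[w.o] % frame.box)[None, :], frame.box) < 3.4
            )
            assert count_first_shell(frame, probe, 3.4, waters) == oracle


class TestSnapshotSchedule:
    def test_protocol_totals_12000(self):
        sched = snapshot_schedule(12, 50.0, 50.0)
        assert len(sched) == 12_000
        assert sched[0] == (0, 0.05)
        assert sched[999] == (0, 50.0)
        assert sched[-1] == (11, 50.0)

    @pytest.mark.parametrize(
        "replicas,usable,stride,expected",
        [(1, 1.0, 50.0, 20), (1, 0.48, 48.0, 10), (3, 2.0, 100.0, 60)],
    )
    def test_counts(self, replicas, usable, stride, expected):
        assert len(snapshot_schedule(replicas, usable, stride)) == expected

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncat"):
            sched = snapshot_schedule(1, 1.0, 300.0)
        assert len(sched) == 3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            snapshot_schedule(0, 50.0, 50.0)
        with pytest.raises(ValueError):
            snapshot_schedule(1, -1.0, 50.0)
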