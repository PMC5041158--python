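import numpy as np
import pytest

from crossbeta import (
    ContactMap,
    Trajectory,
    TrajectorySpec,
    accumulate_map,
    detect_hbonds,
    detect_vdw,
    make_trajectory,
    map_overlap,
    select_strands,
    subsample_frames,
)
from helpers import toy_sites


def donor_acceptor_pair(distance):
    return toy_sites(
        [[0, 0, 0], [distance, 0, 0]],
        donors=[True, False],
        acceptors=[False, True],
        mols=[0, 1],
    )


class TestDetection:
    def test_strict_cutoff_boundary(self):
        inside = donor_acceptor_pair(2.9)
        assert len(detect_hbonds(inside, [0], [1])) == 1
        at_cutoff = donor_acceptor_pair(3.0)
        assert detect_hbonds(at_cutoff, [0], [1]) == []

    def test_hbond_takes_priority_over_vdw(self):
        frame = donor_acceptor_pair(2.2)
        assert len(detect_hbonds(frame, [0], [1])) == 1
        assert detect_vdw(frame, [0], [1]) == []

    def test_plain_pair_counts_as_vdw(self):
        frame = toy_sites([[0, 0, 0], [2.2, 0, 0]], mols=[0, 1])
        vdw = detect_vdw(frame, [0], [1])
        assert len(vdw) == 1 and vdw[0].kind == "vdw"

    def test_overlapping_groups_rejected(self):
        frame = donor_acceptor_pair(2.5)
        with pytest.raises(ValueError):
            detect_hbonds(frame, [0, 1], [1])

    def test_brute_force_oracle_equivalence(self, rng):
        """Detection equals an all-pairs loop with role filtering."""
        for _ in range(100):
            n = int(rng.integers(10, 31))
            frame = toy_sites(
                rng.uniform(-6, 6, size=(n, 3)),
                donors=rng.random(n) < 0.3,
                acceptors=rng.random(n) < 0.3,
                mols=[0] * (n // 2) + [1] * (n - n // 2),
            )
            ga = np.arange(n // 2)
            gb = np.arange(n // 2, n)
            got_hb = {(c.i, c.j) for c in detect_hbonds(frame, ga, gb)}
            got_vdw = {(c.i, c.j) for c in detect_vdw(frame, ga, gb)}
            exp_hb, exp_vdw = set(), set()
            for i in ga:
                for j in gb:
                    d = float(np.linalg.norm(frame.xyz[i] - frame.xyz[j]))
                    eligible = (frame.donor[i] and frame.acceptor[j]) or (
                        frame.acceptor[i] and frame.donor[j]
                    )
                    if eligible and d < 3.0:
                        exp_hb.add((i, j))
                    elif d < 2.3:
                        exp_vdw.add((i, j))
            assert got_hb == exp_hb
            assert got_vdw == exp_vdw

    def test_threshold_monotonicity(self, rng):
        """Shorter (stronger) cutoffs never find more contacts."""
        n = 40
        frame = toy_sites(
            rng.uniform(-6, 6, size=(n, 3)),
            donors=rng.random(n) < 0.5,
            acceptors=rng.random(n) < 0.5,
            mols=[0] * 20 + [1] * 20,
        )
        ga, gb = np.arange(20), np.arange(20, 40)
        counts = [
            len(detect_hbonds(frame, ga, gb, cutoff=c)) for c in (1.5, 2.3, 3.0, 4.0)
        ]
        assert counts == sorted(counts)


@pytest.fixture(scope="module")
def planted_traj(core):
    spec = TrajectorySpec(
        base=core,
        n_frames=50,
        seed=7,
        sigma=0.3,
        planted=[(s, 13, "sheet2", "hbond") for s in "ABCD"],
        fraction=1.0,
    )
    return make_trajectory(spec)


class TestAccumulate:
    def test_single_frame_equals_detection(self, planted_traj):
        top = planted_traj.topology
        ga = select_strands(top, "ABCD")
        gb = select_strands(top, "EFGH")
        one = Trajectory(topology=top, coords=planted_traj.coords[:1])
        cmap = accumulate_map(one, ga, gb)
        per_frame = len(detect_hbonds(one.frame(0), ga, gb)) + len(
            detect_vdw(one.frame(0), ga, gb)
        )
        assert cmap.total == per_frame

    def test_identical_frames_scale_linearly(self, planted_traj):
        top = planted_traj.topology
        ga = select_strands(top, "ABCD")
        gb = select_strands(top, "EFGH")
        one = Trajectory(topology=top, coords=planted_traj.coords[:1])
        k = 4
        rep = Trajectory(topology=top, coords=np.repeat(planted_traj.coords[:1], k, axis=0))
        assert np.array_equal(
            accumulate_map(rep, ga, gb).counts, k * accumulate_map(one, ga, gb).counts
        )

    def test_planted_arginine_ladder_dominates(self, planted_traj):
        """An enforced Arg13-Arg13' ladder shows up as the argmax cell."""
        top = planted_traj.topology
        cmap = accumulate_map(
            planted_traj, select_strands(top, "ABCD"), select_strands(top, "EFGH")
        )
        assert cmap.argmax_cell("hbond")[1] == 13
        for s in "ABCD":
            assert cmap.cell(s, 13, "hbond") >= 50

    def test_sheet_sheet_symmetry(self, planted_traj):
        top = planted_traj.topology
        ga = select_strands(top, "ABCD")
        gb = select_strands(top, "EFGH")
        assert accumulate_map(planted_traj, ga, gb).total == accumulate_map(
            planted_traj, gb, ga
        ).total

    def test_conservation_over_frames(self, planted_traj):
        top = planted_traj.topology
        ga = select_strands(top, "ABCD")
        gb = select_strands(top, "EFGH")
        cmap = accumulate_map(planted_traj, ga, gb)
        per_frame = sum(
            len(detect_hbonds(planted_traj.frame(i), ga, gb))
            + len(detect_vdw(planted_traj.frame(i), ga, gb))
            for i in range(planted_traj.n_frames)
        )
        assert cmap.total == per_frame


class TestSubsample:
    @pytest.mark.parametrize("n,stride,expected", [(200, 10, 20), (7, 3, 2), (5, 1, 5)])
    def test_counts(self, ba2_sheet, n, stride, expected):
        traj = make_trajectory(TrajectorySpec(base=ba2_sheet, n_frames=n, seed=1, sigma=0.0))
        assert subsample_frames(traj, stride).n_frames == expected

    def test_stride_one_is_identity(self, ba2_sheet):
        traj = make_trajectory(TrajectorySpec(base=ba2_sheet, n_frames=5, seed=1, sigma=0.1))
        assert np.array_equal(subsample_frames(traj, 1).coords, traj.coords)

    def test_bad_stride_rejected(self, ba2_sheet):
        traj = make_trajectory(TrajectorySpec(base=ba2_sheet, n_frames=5, seed=1))
        with pytest.raises(ValueError):
            subsample_frames(traj, 0)


def _map_from(cells, strands=("A",), length=4):
    counts = np.zeros((len(strands), length, 2), dtype=int)
    for (s, pos, kind), v in cells.items():
        counts[strands.index(s), pos - 1, ContactMap.type_index(kind)] = v
    return ContactMap(strands=tuple(strands), length=length, counts=counts)


class TestMapOverlap:
    def test_self_overlap_is_one(self):
        m = _map_from({("A", 1, "hbond"): 3, ("A", 2, "vdw"): 1})
        assert map_overlap(m, m) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a = _map_from({("A", 1, "hbond"): 5})
        b = _map_from({("A", 2, "hbond"): 5})
        assert map_overlap(a, b) == 0.0

    def test_all_zero_map_gives_zero(self):
        a = _map_from({})
        b = _map_from({("A", 1, "hbond"): 5})
        assert map_overlap(a, b) == 0.0

    def test_hand_computed_example(self):
        # vectors (3,4) and (4,3) over two cells: cos = 24/25
        a = _map_from({("A", 1, "hbond"): 3, ("A", 2, "hbond"): 4})
        b = _map_from({("A", 1, "hbond"): 4, ("A", 2, "hbond"): 3})
        assert map_overlap(a, b) == pytest.approx(24.0 / 25.0)

    def test_shape_mismatch_rejected(self):
        a = _map_from({})
        b = _map_from({}, length=6)
        with pytest.raises(ValueError):
            map_overlap(a, b)
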