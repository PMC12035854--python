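"""Brownian-dynamics pulling: integrator physics, determinism, telemetry
and transition classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fibrinpull import pulling, sop, synthetic
from fibrinpull.constants import KJ_MOL_ANG_TO_PN
from fibrinpull.pulling import PullProtocol, RegionDef, SimConfig, Trajectory
from fibrinpull.sop import SOPParams, SOPTopology, build_topology
from fibrinpull.structure import CAStructure, make_toy_chain


def _bare_topology(n: int) -> SOPTopology:
    """n beads with no interactions at all (free diffusion)."""
    empty = np.empty((0, 2), dtype=np.int64)
    return SOPTopology(
        n_residues=n,
        bonds=empty, bond_r0=np.empty(0),
        angles=empty, angle_r0=np.empty(0),
        native=empty, native_r0=np.empty(0), native_eps=np.empty(0),
        exclusion=np.ones((n, n), dtype=bool),  # no repulsion either
    )


def _dimer() -> tuple[CAStructure, SOPTopology]:
    st = CAStructure(np.array(["A", "A"]), np.array([1, 2]),
                     np.array([[0.0, 0, 0], [3.8, 0, 0]]))
    topo = SOPTopology(
        n_residues=2,
        bonds=np.array([[0, 1]]), bond_r0=np.array([3.8]),
        angles=np.empty((0, 2), dtype=np.int64), angle_r0=np.empty(0),
        native=np.empty((0, 2), dtype=np.int64),
        native_r0=np.empty(0), native_eps=np.empty(0),
        exclusion=np.ones((2, 2), dtype=bool),
    )
    return st, topo


class TestProtocol:
    def test_loading_rate_identity(self):
        p = PullProtocol(frozenset({0}), frozenset({1}))
        assert p.loading_rate == pytest.approx(110.0, abs=1e-9)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PullProtocol(frozenset({0, 1}), frozenset({1}))

    def test_transverse_direction_perpendicular(self):
        st = make_toy_chain(12, "linear")
        p = PullProtocol(frozenset({0}), frozenset({6}), direction="transverse")
        d = p.resolve_direction(st.coords)
        e2e = st.coords[-1] - st.coords[0]
        assert abs(d @ e2e) < 1e-9
        assert np.linalg.norm(d) == pytest.approx(1.0)


class TestIntegrator:
    def test_unstable_timestep_rejected(self, two_strand20):
        st, topo = two_strand20
        proto = PullProtocol(frozenset({0}), frozenset({19}), speed=1e6)
        with pytest.raises(ValueError, match="timestep"):
            pulling.run_pull(st, topo, proto, SimConfig(timestep=0.5))

    def test_fene_dimer_matches_analytic_force_curve(self):
        # zero temperature, quasi-static: spring force vs extension must
        # follow the closed-form FENE force to 1% up to 0.9 R0
        st, topo = _dimer()
        proto = PullProtocol(
            constrained=frozenset({0}), pulled=frozenset({1}),
            direction=np.array([1.0, 0, 0]), spring_k=2e4, speed=5e4,
        )
        cfg = SimConfig(
            temperature=0.0, timestep=0.015, max_extension=0.18,
            output_stride=50, seed=0,
        )
        traj = pulling.run_pull(st, topo, proto, cfg)
        d = traj.extension_nm * 10.0  # A of bond stretch
        keep = (d > 0.2) & (d < 1.8)  # up to 0.9 R0
        k = SOPParams().k_fene_internal
        analytic = k * d[keep] / (1.0 - (d[keep] / 2.0) ** 2) * KJ_MOL_ANG_TO_PN
        assert np.allclose(traj.force_pN[keep], analytic, rtol=0.01)

    def test_same_seed_bit_identical(self, two_strand20):
        st, topo = two_strand20
        proto = PullProtocol(frozenset({0, 9}), frozenset({19}), speed=2e6)
        cfg = SimConfig(max_extension=3.0, output_stride=100, seed=7)
        a = pulling.run_pull(st, topo, proto, cfg)
        b = pulling.run_pull(st, topo, proto, cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.force_pN, b.force_pN)

    def test_constrained_beads_immobile(self, two_strand20):
        st, topo = two_strand20
        proto = PullProtocol(frozenset({0, 9}), frozenset({19}), speed=2e6)
        traj = pulling.run_pull(
            st, topo, proto, SimConfig(max_extension=3.0, output_stride=100, seed=1)
        )
        for i in (0, 9):
            drift = np.abs(traj.coords[:, i, :] - st.coords[i]).max()
            assert drift < 1e-9

    def test_free_bead_diffusion(self):
        # MSD per dimension of a free bead = 2 (kT/gamma) t within 5%
        n, runs, steps = 4, 200, 400
        st = CAStructure(
            np.array(["A"] * n), np.arange(1, n + 1),
            np.array([[50.0 * i, 0, 0] for i in range(n)]),
        )
        topo = _bare_topology(n)
        cfg0 = SimConfig(timestep=0.02, output_stride=steps, max_steps=steps + 1)
        proto = PullProtocol(
            constrained=frozenset(), pulled=frozenset({0}),
            direction=np.array([1.0, 0, 0]), spring_k=1e-9, speed=1e-6,
        )
        disp = []
        for seed in range(runs):
            cfg = SimConfig(
                timestep=cfg0.timestep, output_stride=steps,
                max_steps=steps + 1, seed=seed, max_extension=1e9,
            )
            traj = pulling.run_pull(st, topo, proto, cfg)
            disp.append((traj.coords[-1] - traj.coords[0]).ravel())
        disp = np.concatenate(disp)  # runs * n * 3 independent samples
        t_total = steps * cfg0.timestep
        expected = 2.0 * cfg0.kt / cfg0.friction * t_total
        assert disp.var() == pytest.approx(expected, rel=0.05)

    def test_two_strand_rupture_gives_force_drop(self, two_strand20):
        # pull strand B's far end while strand A is anchored: the load
        # crosses the interstrand contacts, whose rupture drops the force
        st, topo = two_strand20
        proto = PullProtocol(
            constrained=frozenset({0, 9}), pulled=frozenset({19}),
            direction=np.array([1.0, 0, 0]), speed=2e6,
        )
        cfg = SimConfig(max_extension=6.0, output_stride=200, seed=3)
        traj = pulling.run_pull(st, topo, proto, cfg)
        intact = traj.contact_intact.sum(axis=1)
        assert intact[0] == topo.n_native
        assert intact[-1] < intact[0]  # contacts ruptured
        peak = int(np.argmax(traj.force_pN))
        after = traj.force_pN[peak:]
        assert after.min() < 0.6 * traj.force_pN[peak]  # sawtooth drop
        # the force drop coincides with contact loss
        assert intact[peak:].min() < intact[:peak].max()


class TestFoldedStability:
    def test_native_rmsd_bounded_without_load(self, helix30):
        # low temperature, no pulling: the folded minimum is stable
        st, topo = helix30
        proto = PullProtocol(
            constrained=frozenset(), pulled=frozenset({29}),
            direction=np.array([1.0, 0, 0]), spring_k=1e-9, speed=1e-6,
        )
        cfg = SimConfig(
            temperature=50.0, max_steps=1_000_000, output_stride=100_000,
            max_extension=1e9, seed=5,
        )
        traj = pulling.run_pull(st, topo, proto, cfg)
        ref = st.coords - st.coords.mean(axis=0)
        for frame in traj.coords[1:]:
            mob = frame - frame.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, mob)
            rmsd = np.sqrt(((rot.apply(mob) - ref) ** 2).sum(axis=1).mean())
            assert rmsd < 2.0


def _scripted_trajectory(two_strand20, intact, force=None, ext=None) -> Trajectory:
    st, topo = two_strand20
    n_frames = intact.shape[0]
    return Trajectory(
        times_ps=np.arange(n_frames, dtype=float),
        force_pN=np.asarray(force) if force is not None else np.full(n_frames, 10.0),
        extension_nm=np.asarray(ext) if ext is not None else np.linspace(0, 10, n_frames),
        contact_intact=intact,
        coords=np.repeat(st.coords[None], n_frames, axis=0),
        structure=st,
        topology=topo,
        protocol=PullProtocol(frozenset({0}), frozenset({19})),
        config=SimConfig(),
    )


class TestClassifyTransitions:
    def test_single_region_step_gives_one_event(self, two_strand20):
        st, topo = two_strand20
        nc = topo.n_native
        intact = np.ones((20, nc), dtype=np.uint8)
        intact[10:] = 0  # every contact breaks at frame 10
        traj = _scripted_trajectory(two_strand20, intact)
        rep = pulling.classify_transitions(
            traj, [RegionDef(1, "A", ((1, 10),))]
        )
        assert len(rep.events) == 1
        ev = rep.events[0]
        assert ev.label == 1 and ev.strand == "A" and ev.time_ps == 10.0

    def test_two_strands_in_one_window_merge_to_type4(self, two_strand20):
        st, topo = two_strand20
        nc = topo.n_native
        intact = np.ones((20, nc), dtype=np.uint8)
        intact[10:] = 0
        traj = _scripted_trajectory(two_strand20, intact)
        rep = pulling.classify_transitions(
            traj,
            [RegionDef(1, "A", ((1, 10),)), RegionDef(2, "B", ((1, 10),))],
        )
        assert len(rep.events) == 1
        ev = rep.events[0]
        assert ev.label == 4 and ev.strand == "mixed"
        assert ev.constituents == (1, 2)
        assert rep.mixed_fraction == 1.0

    def test_alternating_sequence_scores_one(self, two_strand20):
        st, topo = two_strand20
        nc = topo.n_native
        # contacts touching A-side vs B-side regions break far apart in
        # extension so the fallback grouping keeps them separate
        natives = topo.native
        a_side = np.array(
            [
                (st.chain_ids[i] == "A" and st.res_ids[i] <= 5)
                or (st.chain_ids[j] == "A" and st.res_ids[j] <= 5)
                for i, j in natives
            ]
        )
        b_side = np.array(
            [
                (st.chain_ids[j] == "B" and st.res_ids[j] >= 6)
                for _, j in natives
            ]
        ) & ~a_side
        intact = np.ones((40, nc), dtype=np.uint8)
        intact[10:, a_side] = 0
        intact[30:, b_side] = 0
        traj = _scripted_trajectory(
            two_strand20, intact, ext=np.linspace(0, 40, 40)
        )
        rep = pulling.classify_transitions(
            traj,
            [RegionDef(0, "A", ((1, 5),)), RegionDef(3, "B", ((6, 10),))],
            merge_window_nm=2.0,
        )
        singles = [e for e in rep.events if e.strand != "mixed"]
        assert len(singles) == 2
        assert rep.alternation_score == 1.0

    def test_missing_telemetry_rejected(self, two_strand20):
        st, topo = two_strand20
        traj = _scripted_trajectory(
            two_strand20, np.ones((5, 0), dtype=np.uint8)
        )
        with pytest.raises(ValueError, match="telemetry"):
            pulling.classify_transitions(traj, [RegionDef(1, "A", ((1, 5),))])
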