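import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from chromofold.chain import BeadChain, GeometryParams
from chromofold.sampler import (
    AnnealSchedule,
    Move,
    accept,
    anneal_subchain,
    apply_move,
    derive_seed,
    propose_move,
    quat_from_axis_angle,
    quat_rotate,
    sample_ensemble,
)
from chromofold.score import PairSets, ScoreParams, select_pairs
from chromofold.sampler import initialize_chain
from conftest import random_chain


class TestQuaternions:
    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        angle = rng.uniform(0, np.pi)
        pts = rng.normal(size=(6, 3)) * 10
        q = quat_from_axis_angle(axis, angle)
        oracle = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis))
        np.testing.assert_allclose(quat_rotate(q, pts), oracle.apply(pts), atol=1e-9)

    def test_identity_quaternion(self):
        pts = np.arange(9.0).reshape(3, 3)
        np.testing.assert_array_equal(quat_rotate(np.array([1.0, 0, 0, 0]), pts), pts)

    def test_unit_norm_enforced_by_move(self):
        with pytest.raises(ValueError):
            Move(pivot_index=1, segment="downstream", rotation=np.array([1.0, 1.0, 0, 0]))


class TestProposeMove:
    def test_zero_max_angle_gives_identity_rotation(self):
        chain = random_chain(5, 0)
        move = propose_move(chain, np.random.default_rng(0), max_angle=0.0)
        np.testing.assert_array_equal(move.rotation, [1.0, 0, 0, 0])

    def test_deterministic_sequence_for_fixed_seed(self):
        chain = random_chain(6, 1)
        a = [propose_move(chain, np.random.default_rng(3), np.pi) for _ in range(5)]
        b = [propose_move(chain, np.random.default_rng(3), np.pi) for _ in range(5)]
        for ma, mb in zip(a, b):
            assert ma.pivot_index == mb.pivot_index and ma.segment == mb.segment
            np.testing.assert_array_equal(ma.rotation, mb.rotation)

    def test_pivot_distribution_uniform_over_interior(self):
        chain = random_chain(7, 2)  # interior pivots: 1..5
        rng = np.random.default_rng(4)
        counts = np.zeros(7)
        n_prop = 10_000
        for _ in range(n_prop):
            counts[propose_move(chain, rng, np.pi).pivot_index] += 1
        assert counts[0] == 0 and counts[6] == 0
        stat, p = chisquare(counts[1:6])
        assert p > 1e-4  # consistent with uniform

    def test_too_short_chain_rejected(self):
        chain = random_chain(2, 0)
        with pytest.raises(ValueError):
            propose_move(chain, np.random.default_rng(0), np.pi)


class TestApplyMove:
    def test_identity_move_leaves_chain_unchanged(self):
        chain = random_chain(6, 5)
        move = Move(pivot_index=3, segment="downstream", rotation=np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(
            apply_move(chain, move).positions, chain.positions, atol=1e-12
        )

    def test_half_turn_applied_twice_is_identity(self):
        chain = random_chain(6, 6)
        q = quat_from_axis_angle(np.array([0.3, -1.0, 0.5]), np.pi)
        move = Move(pivot_index=2, segment="downstream", rotation=q)
        back = apply_move(apply_move(chain, move), move)
        np.testing.assert_allclose(back.positions, chain.positions, atol=1e-9)

    @pytest.mark.parametrize("segment", ["downstream", "upstream"])
    def test_segment_internal_distances_preserved(self, segment):
        chain = random_chain(8, 7)
        q = quat_from_axis_angle(np.random.default_rng(1).normal(size=3), 1.1)
        move = Move(pivot_index=4, segment=segment, rotation=q)
        moved = apply_move(chain, move)
        for group in (range(0, 4), range(5, 8)):
            idx = np.array(list(group))
            before = np.linalg.norm(
                chain.positions[idx][:, None] - chain.positions[idx][None], axis=-1
            )
            after = np.linalg.norm(
                moved.positions[idx][:, None] - moved.positions[idx][None], axis=-1
            )
            np.testing.assert_allclose(after, before, atol=1e-9)

    def test_distances_across_pivot_preserved(self):
        # the pivot is the rotation center, so its distances to the rotated
        # segment are invariant (jitter disabled)
        chain = random_chain(7, 8)
        q = quat_from_axis_angle(np.array([1.0, 2.0, -1.0]), 0.7)
        move = Move(pivot_index=3, segment="downstream", rotation=q)
        moved = apply_move(chain, move)
        for j in range(4, 7):
            before = np.linalg.norm(chain.positions[j] - chain.positions[3])
            after = np.linalg.norm(moved.positions[j] - moved.positions[3])
            assert after == pytest.approx(before, abs=1e-9)

    def test_matches_rotation_matrix_oracle(self):
        chain = random_chain(6, 9)
        axis = np.array([0.2, 0.5, -1.0])
        angle = 0.9
        q = quat_from_axis_angle(axis, angle)
        move = Move(pivot_index=2, segment="downstream", rotation=q)
        moved = apply_move(chain, move)
        R = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis)).as_matrix()
        center = chain.positions[2]
        expected = chain.positions.copy()
        expected[3:] = (expected[3:] - center) @ R.T + center
        np.testing.assert_allclose(moved.positions, expected, atol=1e-9)

    def test_jitter_moves_pivot_bead_only(self):
        chain = random_chain(5, 10)
        move = Move(
            pivot_index=2, segment="downstream",
            rotation=np.array([1.0, 0, 0, 0]),
            translation_jitter=np.array([1.0, -2.0, 0.5]),
        )
        moved = apply_move(chain, move)
        np.testing.assert_allclose(
            moved.positions[2], chain.positions[2] + [1.0, -2.0, 0.5]
        )
        np.testing.assert_array_equal(
            np.delete(moved.positions, 2, axis=0), np.delete(chain.positions, 2, axis=0)
        )


class TestAccept:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(accept(-1.0, t, rng) for t in (0.01, 1.0, 100.0))

    def test_zero_delta_accepted(self):
        assert accept(0.0, 1.0, np.random.default_rng(0))

    def test_empirical_rate_at_ln2(self):
        # delta = T ln 2 -> acceptance probability exactly 1/2
        rng = np.random.default_rng(12)
        T = 3.7
        n = 100_000
        hits = sum(accept(T * np.log(2.0), T, rng) for _ in range(n))
        assert hits / n == pytest.approx(0.5, abs=0.01)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            accept(1.0, 0.0, np.random.default_rng(0))


class TestAnneal:
    def _toy_inputs(self, n=6, seed=0, dominant=(1, 4)):
        rng = np.random.default_rng(seed)
        m = rng.poisson(1, (n, n)).astype(float)
        m = np.triu(m, 1)
        m[dominant] = 40.0
        m = m + m.T
        radii = np.full(n, 4.0)
        sets = PairSets(L=select_pairs(m, 0))
        return m, radii, sets

    def test_zero_iterations_returns_input(self):
        m, radii, sets = self._toy_inputs()
        chain = initialize_chain(6, radii, seed=3)
        sched = AnnealSchedule(t_initial=10.0, n_temps=0, iters_per_temp=0, seed=1)
        out, trace = anneal_subchain(chain, m, sets, ScoreParams(), GeometryParams(), sched)
        np.testing.assert_array_equal(out.positions, chain.positions)
        assert trace == []

    def test_deterministic_for_fixed_seed(self):
        m, radii, sets = self._toy_inputs()
        chain = initialize_chain(6, radii, seed=3)
        sched = AnnealSchedule(n_temps=10, iters_per_temp=30, seed=5)
        out1, tr1 = anneal_subchain(chain, m, sets, ScoreParams(), GeometryParams(), sched)
        out2, tr2 = anneal_subchain(chain, m, sets, ScoreParams(), GeometryParams(), sched)
        np.testing.assert_array_equal(out1.positions, out2.positions)
        assert tr1 == tr2

    def test_dominant_pair_driven_toward_touching(self):
        m, radii, sets = self._toy_inputs()
        i, j = 1, 4
        target = radii[i] + radii[j]
        wins = 0
        trials = 25
        for k in range(trials):
            seed = derive_seed(42, k)
            chain = initialize_chain(6, radii, seed=seed)
            before = np.linalg.norm(chain.positions[i] - chain.positions[j])
            sched = AnnealSchedule(n_temps=30, iters_per_temp=60, seed=seed)
            out, _ = anneal_subchain(chain, m, sets, ScoreParams(), GeometryParams(), sched)
            after = np.linalg.norm(out.positions[i] - out.positions[j])
            wins += abs(after - target) < abs(before - target)
        assert wins >= 23  # stochastic improvement on nearly every seeded run

    def test_best_score_trace_non_increasing(self):
        m, radii, sets = self._toy_inputs(seed=2)
        chain = initialize_chain(6, radii, seed=1)
        sched = AnnealSchedule(n_temps=20, iters_per_temp=40, seed=9)
        _, trace = anneal_subchain(chain, m, sets, ScoreParams(), GeometryParams(), sched)
        bests = [b for _, _, b in trace]
        assert all(b2 <= b1 for b1, b2 in zip(bests[:-1], bests[1:]))
        assert bests[-1] < bests[0]

    def test_two_bead_problem_converges_to_touching(self):
        # single contact, no features: optimum near d = r1 + r2
        contacts = np.array([[0.0, 5.0], [5.0, 0.0]])
        radii = np.array([4.0, 5.0])
        sets = PairSets(L=np.array([[0, 1]]))
        ok = 0
        trials = 20
        for k in range(trials):
            seed = derive_seed(5, k)
            chain = initialize_chain(2, radii, seed=seed)
            sched = AnnealSchedule(n_temps=40, iters_per_temp=60, seed=seed)
            out, _ = anneal_subchain(
                chain, contacts, sets, ScoreParams(), GeometryParams(), sched
            )
            d = np.linalg.norm(out.positions[0] - out.positions[1])
            ok += abs(d - radii.sum()) / radii.sum() < 0.05
        assert ok >= 19


class TestEnsemble:
    def _inputs(self):
        m, radii, sets = TestAnneal()._toy_inputs()
        chain = initialize_chain(6, radii, seed=0)
        sched = AnnealSchedule(t_initial=50.0, n_temps=4, iters_per_temp=20, seed=7)
        return chain, m, sets, sched

    def test_singleton_ensemble(self):
        chain, m, sets, sched = self._inputs()
        out = sample_ensemble(chain, m, sets, ScoreParams(), GeometryParams(), sched, 1)
        assert len(out) == 1

    def test_requested_size_returned(self):
        chain, m, sets, sched = self._inputs()
        out = sample_ensemble(chain, m, sets, ScoreParams(), GeometryParams(), sched, 8)
        assert len(out) == 8

    def test_members_are_distinct(self):
        chain, m, sets, sched = self._inputs()
        out = sample_ensemble(chain, m, sets, ScoreParams(), GeometryParams(), sched, 4)
        assert any(
            not np.allclose(out[0].positions, ch.positions) for ch in out[1:]
        )

    def test_fully_reproducible(self):
        chain, m, sets, sched = self._inputs()
        a = sample_ensemble(chain, m, sets, ScoreParams(), GeometryParams(), sched, 3)
        b = sample_ensemble(chain, m, sets, ScoreParams(), GeometryParams(), sched, 3)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.positions, cb.positions)


class TestDeriveSeed:
    def test_below_31_bits_and_deterministic(self):
        seeds = {derive_seed(123, k) for k in range(1000)}
        assert len(seeds) == 1000  # no collisions on a small stream
        assert all(0 <= s < 2**31 for s in seeds)
        assert derive_seed(123, 5) == derive_seed(123, 5)


def test_write_trace_emits_tsv(tmp_path):
    from chromofold.sampler import write_trace

    trace = [(0, 100.0, 50.0), (1, 85.0, 42.0)]
    p = tmp_path / "trace.tsv"
    write_trace(trace, p)
    lines = p.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["stage", "temperature", "best_score"]
    assert len(lines) == 3
    assert lines[1].split("\t")[0] == "0"
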