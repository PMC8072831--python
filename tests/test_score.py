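import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromofold.chain import BeadChain, GeometryParams, d_max, d_min
from chromofold.score import (
    PairSets,
    ScoreContext,
    ScoreParams,
    phi_chip,
    phi_hic,
    phi_rna,
    psi,
    select_pairs,
    xi,
)
from conftest import random_chain


def pair_chain(d, r1=1.0, r2=1.0):
    return BeadChain.from_arrays(
        np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), np.array([r1, r2])
    )


class TestSelectPairs:
    def test_percentile_zero_keeps_all_nonzero(self):
        m = np.array([[0, 1, 0], [1, 0, 2], [0, 2, 0]], dtype=float)
        L = select_pairs(m, 0)
        assert {tuple(p) for p in L} == {(0, 1), (1, 2)}

    def test_median_cut(self):
        # nonzero upper-triangle values {1,2,3,4}; 50th pct = 2.5 -> keep 3, 4
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1
        m[0, 2] = m[2, 0] = 2
        m[0, 3] = m[3, 0] = 3
        m[1, 2] = m[2, 1] = 4
        L = select_pairs(m, 50)
        assert {tuple(p) for p in L} == {(0, 3), (1, 2)}

    def test_all_zero_block_empty(self):
        assert select_pairs(np.zeros((5, 5)), 75).size == 0

    def test_constant_nonzero_block_keeps_everything(self):
        m = np.ones((4, 4)) - np.eye(4)
        assert len(select_pairs(m, 75)) == 6


class TestPhiHic:
    def test_touching_pairs_score_zero(self):
        chain = pair_chain(2.0)
        contacts = np.array([[0, 7.0], [7.0, 0]])
        assert phi_hic(chain, contacts, np.array([[0, 1]])) == 0.0

    def test_hand_computed_value(self):
        # n=2, r_i=r_j=1, d=3: 2*(3-2)^2 = 2
        chain = pair_chain(3.0)
        contacts = np.array([[0, 2.0], [2.0, 0]])
        assert phi_hic(chain, contacts, np.array([[0, 1]])) == pytest.approx(2.0)

    def test_finite_value_at_coincident_centers(self):
        # d=0: the term caps at n_ij (r_i+r_j)^2 = 2*4 = 8
        chain = BeadChain.from_arrays(
            np.zeros((2, 3)), np.array([1.0, 1.0])
        )
        contacts = np.array([[0, 2.0], [2.0, 0]])
        assert phi_hic(chain, contacts, np.array([[0, 1]])) == pytest.approx(8.0)

    def test_empty_pair_set(self):
        assert phi_hic(pair_chain(5.0), np.zeros((2, 2)), np.empty((0, 2))) == 0.0

    def test_monotone_decrease_toward_touching(self):
        contacts = np.array([[0, 3.0], [3.0, 0]])
        L = np.array([[0, 1]])
        vals = [phi_hic(pair_chain(d), contacts, L) for d in (6.0, 5.0, 4.0, 3.0, 2.0)]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))


class TestPhiChipRna:
    def chain4(self, scale=4.0):
        pos = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float) * scale
        return BeadChain.from_arrays(pos, np.full(4, 0.8))

    def test_inactive_blocks_score_zero(self):
        assert phi_chip(self.chain4(), False, 5.0) == 0.0
        assert phi_rna(self.chain4(), False, 5.0) == 0.0

    def test_chip_zero_at_dmin(self):
        chain = self.chain4()
        iu, ju = np.triu_indices(4, 1)
        d = np.linalg.norm(chain.positions[iu] - chain.positions[ju], axis=1)
        max_nonadj = d[(ju - iu) > 1].max()
        assert phi_chip(chain, True, float(max_nonadj)) == pytest.approx(0.0)

    def test_chip_quadratic_penalty(self):
        chain = self.chain4()
        iu, ju = np.triu_indices(4, 1)
        d = np.linalg.norm(chain.positions[iu] - chain.positions[ju], axis=1)
        max_nonadj = d[(ju - iu) > 1].max()
        assert phi_chip(chain, True, float(max_nonadj) - 3.0) == pytest.approx(9.0)

    def test_rna_zero_at_dmax_and_quadratic_below(self):
        chain = self.chain4()
        iu, ju = np.triu_indices(4, 1)
        d = np.linalg.norm(chain.positions[iu] - chain.positions[ju], axis=1)
        min_nonadj = d[(ju - iu) > 1].min()
        assert phi_rna(chain, True, float(min_nonadj)) == pytest.approx(0.0)
        assert phi_rna(chain, True, float(min_nonadj) + 2.0) == pytest.approx(4.0)

    def test_adjacent_pairs_excluded(self):
        # squeeze an adjacent pair: must not affect either term
        pos = np.array([[0, 0, 0], [0.5, 0, 0], [10, 0, 0], [20, 0, 0]], dtype=float)
        chain = BeadChain.from_arrays(pos, np.full(4, 0.4))
        iu, ju = np.triu_indices(4, 1)
        d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        nonadj = d[(ju - iu) > 1]
        assert phi_rna(chain, True, 5.0) == pytest.approx((nonadj.min() - 5.0) ** 2)


class TestPsi:
    def test_value_at_contact_distance(self):
        # braces vanish at d = r_i + r_j: psi = (2)/(2*2) = 0.5
        val = psi(pair_chain(2.0), ScoreParams(c=1.0, b=3))
        assert val == pytest.approx(0.5)

    def test_hand_computed_tail_value(self):
        # r=1, c=1, b=1, d=4: x = 2, 0.25 * (1 - 2/(1+2)) = 1/12
        val = psi(pair_chain(4.0), ScoreParams(c=1.0, b=1))
        assert val == pytest.approx(1.0 / 12.0)

    def test_vanishes_at_large_distance(self):
        val = psi(pair_chain(200.0), ScoreParams(c=1.0, b=3))
        assert abs(val) < 1e-3

    def test_diverges_toward_coincidence(self):
        params = ScoreParams(c=1.0, b=3)
        assert psi(pair_chain(1e-4), params) > psi(pair_chain(1e-2), params) > 50

    def test_coincident_centers_rejected(self):
        chain = BeadChain.from_arrays(np.zeros((2, 3)), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            psi(chain, ScoreParams(c=1.0, b=3))

    def test_positive_for_interpenetrating_pair(self):
        assert psi(pair_chain(1.0), ScoreParams(c=1.0, b=3)) > 0

    def test_larger_b_sharpens_transition(self):
        # inside the transition zone (|x| < 1) a larger odd exponent keeps the
        # barrier higher; outside it (|x| > 1) it cuts the tail harder — i.e.
        # the transition around |x| = 1 gets steeper with b
        inside = 2.5   # x = 0.5
        outside = 3.5  # x = 1.5
        for b_lo, b_hi in ((1, 3), (3, 9)):
            lo_in = psi(pair_chain(inside), ScoreParams(c=1.0, b=b_lo))
            hi_in = psi(pair_chain(inside), ScoreParams(c=1.0, b=b_hi))
            lo_out = psi(pair_chain(outside), ScoreParams(c=1.0, b=b_lo))
            hi_out = psi(pair_chain(outside), ScoreParams(c=1.0, b=b_hi))
            assert hi_in > lo_in
            assert hi_out < lo_out

    def test_even_or_nonnatural_b_rejected(self):
        with pytest.raises(ValueError):
            ScoreParams(b=2)
        with pytest.raises(ValueError):
            ScoreParams(b=0)


class TestXi:
    def _inputs(self, n=5, seed=3):
        chain = random_chain(n, seed)
        rng = np.random.default_rng(seed + 1)
        m = rng.poisson(5, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        sets = PairSets(L=select_pairs(m, 50), chip_active=True, rna_active=True)
        return chain, m, sets

    def test_weights_annihilate_terms(self):
        chain, m, sets = self._inputs()
        geom = GeometryParams()
        only_hic = ScoreParams(mu1=0, mu2=0, lam=0)
        assert xi(chain, m, sets, only_hic, geom) == pytest.approx(
            phi_hic(chain, m, sets.L)
        )

    def test_pure_psi_with_zero_contacts(self):
        chain = random_chain(4, 7)
        m = np.zeros((4, 4))
        sets = PairSets(L=select_pairs(m, 75))
        params = ScoreParams(lam=1.0, c=1.0)
        geom = GeometryParams()
        assert xi(chain, m, sets, params, geom) == pytest.approx(psi(chain, params))

    def test_opposing_terms_both_active_and_finite(self):
        chain, m, sets = self._inputs()
        geom = GeometryParams()
        params = ScoreParams(c=1.0)
        total = xi(chain, m, sets, params, geom)
        assert np.isfinite(total)
        assert phi_chip(chain, True, d_min(geom)) > 0
        assert phi_rna(chain, True, d_max(geom)) > 0

    def test_additivity_of_terms(self):
        chain, m, sets = self._inputs(n=6, seed=11)
        geom = GeometryParams()
        params = ScoreParams(mu1=2.0, mu2=3.0, lam=0.5, c=1.0)
        expected = (
            phi_hic(chain, m, sets.L)
            + 2.0 * phi_chip(chain, True, d_min(geom))
            + 3.0 * phi_rna(chain, True, d_max(geom))
            + 0.5 * psi(chain, params)
        )
        assert xi(chain, m, sets, params, geom) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        chain, m, sets = self._inputs(n=6, seed=seed % 1000)
        geom = GeometryParams()
        params = ScoreParams(c=1.0)
        before = xi(chain, m, sets, params, geom)
        rng = np.random.default_rng(seed)
        # random rotation via QR + random translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = chain.with_positions(chain.positions @ q.T + rng.normal(scale=50, size=3))
        after = xi(moved, m, sets, params, geom)
        assert after == pytest.approx(before, rel=1e-9)


class TestScoreContext:
    def test_fast_path_matches_reference_implementation(self):
        chain = random_chain(7, 21)
        rng = np.random.default_rng(5)
        m = rng.poisson(6, (7, 7)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        sets = PairSets(L=select_pairs(m, 60), chip_active=True, rna_active=True)
        params = ScoreParams(c=0.2, mu1=1.5, mu2=0.5, lam=2.0)
        geom = GeometryParams()
        ctx = ScoreContext.build(chain.radii, m, sets, params, geom)
        assert ctx.evaluate(chain.positions) == pytest.approx(
            xi(chain, m, sets, params, geom), rel=1e-12
        )

    def test_coincident_centers_give_infinite_score(self):
        chain = BeadChain.from_arrays(
            np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]]), np.full(3, 1.0)
        )
        sets = PairSets(L=np.empty((0, 2)))
        ctx = ScoreContext.build(chain.radii, np.zeros((3, 3)), sets, ScoreParams(c=1.0), GeometryParams())
        assert ctx.evaluate(chain.positions) == np.inf
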