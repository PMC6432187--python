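"""Pair potentials, total-energy assembly and periodic geometry."""

import numpy as np
import pytest

import semiflex as sf
from semiflex.fixtures import initial_conformation, rod


@pytest.fixture
def stick():
    return sf.bead_stick_spec()


@pytest.fixture
def spring():
    return sf.bead_spring_spec()


class TestLennardJones:
    def test_minimum_depth_unshifted(self, stick):
        assert sf.lj_pair_energy(2 ** (1 / 6), stick,
                                 shifted=False) == pytest.approx(-1.0)

    def test_zero_at_cutoff(self, stick):
        assert sf.lj_pair_energy(2.5, stick) == 0.0
        assert sf.lj_pair_energy(3.7, stick) == 0.0

    def test_shifted_minimum(self, stick):
        # oracle: -1 minus the unshifted potential at rc = 2.5
        v_rc = 4 * (2.5 ** -12 - 2.5 ** -6)
        assert sf.lj_pair_energy(2 ** (1 / 6), stick) == pytest.approx(
            -1.0 - v_rc, abs=1e-12)

    def test_cutoff_continuity(self, stick):
        for delta in (1e-3, 1e-6, 1e-9):
            assert abs(sf.lj_pair_energy(2.5 - delta, stick)) < 10 * delta

    def test_zero_distance_rejected(self, stick):
        with pytest.raises(ValueError):
            sf.lj_pair_energy(0.0, stick)
        with pytest.raises(ValueError):
            sf.lj_pair_energy(np.nan, stick)


class TestBendFene:
    @pytest.mark.parametrize("theta,kappa,expected", [
        (0.0, 5.0, 0.0),
        (np.pi / 2, 5.0, 5.0),
        (np.pi, 5.0, 10.0),
    ])
    def test_bend_values(self, theta, kappa, expected):
        assert sf.bend_energy(theta, kappa) == pytest.approx(expected)

    def test_bend_monotone(self):
        th = np.linspace(0, np.pi, 50)
        e = [sf.bend_energy(t, 2.0) for t in th]
        assert np.all(np.diff(e) > 0)

    def test_fene_minimum(self, spring):
        assert sf.fene_bond_energy(0.7, spring) == 0.0

    def test_fene_value(self, spring):
        # oracle: -(K/2) R^2 ln(1 - (0.15/0.3)^2) = -20*0.09*ln(0.75)
        assert sf.fene_bond_energy(0.85, spring) == pytest.approx(
            -20 * 0.09 * np.log(0.75), rel=1e-12)

    def test_fene_diverges_at_bounds(self, spring):
        assert sf.fene_bond_energy(1.0, spring) == np.inf   # r0 + R
        assert sf.fene_bond_energy(0.39, spring) == np.inf  # below r0 - R
        assert sf.fene_bond_energy(1.2, spring) == np.inf


class TestTotalEnergy:
    def test_straight_trimer_single_pair(self, stick):
        # straight rod: no bending, one non-bonded pair at r = 2
        conf = sf.Conformation(rod(3), 3, 1)
        eb = sf.total_energy(conf, stick.with_kappa(1.0))
        assert eb.ebend == pytest.approx(0.0, abs=1e-12)
        assert eb.efene == 0.0
        assert eb.ep == pytest.approx(sf.lj_pair_energy(2.0, stick),
                                      abs=1e-12)

    def test_isolated_beads_zero(self, stick):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        conf = sf.Conformation(pos, 1, 2)
        assert sf.total_energy(conf, stick).ep == 0.0

    def test_extensivity_far_duplicate(self, spring):
        one = initial_conformation(spring, 10, seed=3)
        e1 = sf.total_energy(one, spring).ep
        dup = np.vstack([one.positions, one.positions + [500.0, 0, 0]])
        two = sf.Conformation(dup, 10, 2)
        assert sf.total_energy(two, spring).ep == pytest.approx(2 * e1,
                                                                rel=1e-12)

    def test_rigid_motion_invariance(self, spring):
        conf = initial_conformation(spring, 12, seed=4)
        e0 = sf.total_energy(conf, spring.with_kappa(3.0)).ep
        rng = np.random.default_rng(0)
        from semiflex.moves import _rotation_matrix
        Rm = _rotation_matrix(rng.normal(size=3), 1.234)
        moved = sf.Conformation(conf.positions @ Rm.T + [3.0, -2.0, 7.0],
                                12, 1)
        e1 = sf.total_energy(moved, spring.with_kappa(3.0)).ep
        assert abs(e1 - e0) <= 1e-10 * max(1.0, abs(e0))

    def test_overlap_flagged_non_finite(self, spring):
        pos = np.zeros((2, 3))
        pos[1] = [0.7, 0.0, 0.0]
        pos = np.vstack([pos, pos])  # exactly overlapping second chain
        conf = sf.Conformation(pos, 2, 2)
        assert not sf.total_energy(conf, spring).finite


class TestGeometry:
    def test_minimal_image_examples(self):
        L = 10.0
        assert np.allclose(sf.minimal_image([9.0, 0, 0], L), [-1.0, 0, 0])
        assert np.allclose(sf.minimal_image([0.0, 0, 0], L), 0.0)
        # half-open convention: +L/2 maps to -L/2, -L/2 stays
        assert np.allclose(sf.minimal_image([5.0, -5.0, 0], L),
                           [-5.0, -5.0, 0])

    def test_box_from_density(self):
        assert sf.box_from_density(13, 4, 1e-3) == pytest.approx(
            52000 ** (1 / 3), rel=1e-12)
        assert sf.box_from_density(1, 1, 1.0) == pytest.approx(1.0)
        rhos = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        Ls = [sf.box_from_density(10, 2, r) for r in rhos]
        assert np.all(np.diff(Ls) < 0)

    def test_conformation_validation(self, stick, spring):
        good = sf.Conformation(rod(5), 5, 1)
        good.validate(stick)
        bad = sf.Conformation(rod(5, spacing=1.1), 5, 1)
        with pytest.raises(ValueError):
            bad.validate(stick)
        with pytest.raises(ValueError):
            sf.Conformation(rod(5, spacing=1.1), 5, 1).validate(spring)


class TestIncrementalEnergy:
    def test_incremental_matches_full_after_many_moves(self, spring):
        """Running energy after >1e4 accepted moves equals a fresh total."""
        spec = spring.with_kappa(2.0)
        box = sf.box_from_density(8, 2, 1e-3)
        conf = initial_conformation(spec, 8, 2, box, seed=9)
        res = sf.run_canonical(conf, spec, 1.5, 1200, seed=11,
                               resync_every=0)  # no mid-run resync
        n_acc = sum(a for a, _ in res.acceptance.values())
        assert n_acc > 10_000
        fresh = sf.total_energy(res.conf, spec)
        assert res.energy.ep == pytest.approx(fresh.ep, abs=1e-8)
        assert res.energy.elj == pytest.approx(fresh.elj, abs=1e-8)
        assert res.energy.ebend == pytest.approx(fresh.ebend, abs=1e-8)
        assert res.energy.efene == pytest.approx(fresh.efene, abs=1e-8)
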