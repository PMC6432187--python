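"""Shape and aggregation observables, including their sampling laws."""

import numpy as np
import pytest

import semiflex as sf
from semiflex.fixtures import (aligned_bundle, initial_conformation,
                               random_bundle, rod)
from semiflex.observables import energy_histogram_2d, measure


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        assert sf.radius_of_gyration_sq(np.zeros((7, 3))) == 0.0

    def test_rod_closed_form(self):
        # oracle for a unit-spaced rod: (N^2 - 1) / 12
        assert sf.radius_of_gyration_sq(rod(28)) == pytest.approx(65.25)

    def test_rotation_invariance(self):
        from semiflex.moves import _rotation_matrix
        pts = np.random.default_rng(1).normal(size=(20, 3))
        Rm = _rotation_matrix([1.0, 2.0, 3.0], 0.77)
        assert sf.radius_of_gyration_sq(pts @ Rm.T) == pytest.approx(
            sf.radius_of_gyration_sq(pts), abs=1e-12)


class TestEndToEnd:
    def test_rod(self):
        ree, unit = sf.end_to_end(rod(28))
        assert ree == pytest.approx(27.0)
        assert np.allclose(np.abs(unit), [1.0, 0.0, 0.0])

    def test_closed_loop_undefined_direction(self):
        loop = np.vstack([rod(5), rod(5)[::-1] + [0, 1e-15, 0]])
        ree, unit = sf.end_to_end(loop)
        assert ree < 1e-12
        assert unit is None

    def test_reflection_flips_direction(self):
        pts = np.random.default_rng(2).normal(size=(9, 3))
        _, u = sf.end_to_end(pts)
        refl = pts * np.array([-1.0, 1.0, 1.0])
        _, ur = sf.end_to_end(refl)
        assert np.allclose(ur, u * [-1.0, 1.0, 1.0])


class TestEndToEndCorrelation:
    def test_aligned_is_one(self):
        u = np.array([0.0, 0.0, 1.0])
        assert sf.end_to_end_correlation([u] * 4) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert sf.end_to_end_correlation(
            [[1.0, 0, 0], [0, 1.0, 0]]) == pytest.approx(0.0)

    def test_uniform_law_one_third(self):
        """i.i.d. uniform unit vectors give <CR> = 1/3."""
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(20_000):
            v = rng.normal(size=(4, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            vals.append(sf.end_to_end_correlation(list(v)))
        vals = np.asarray(vals)
        sem = vals.std() / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(1 / 3, abs=3 * sem)

    def test_undefined_vectors_excluded(self):
        u = np.array([0.0, 0.0, 1.0])
        v = np.array([1.0, 0.0, 0.0])
        # one undefined chain: only the (u, v) pair remains
        assert sf.end_to_end_correlation([u, None, v]) == pytest.approx(0.0)
        assert np.isnan(sf.end_to_end_correlation([u, None]))

    def test_sign_invariance_per_chain(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(5, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        flipped = v * np.array([1, -1, 1, -1, 1])[:, None]
        assert sf.end_to_end_correlation(list(flipped)) == pytest.approx(
            sf.end_to_end_correlation(list(v)))


class TestPhaseSeparation:
    def test_coincident_coms(self):
        assert sf.phase_separation(np.zeros((4, 3)), 10.0) == 0.0

    def test_two_chain_closed_form(self):
        # ordered-pair convention: Gamma2 = d^2 / 4 for two chains
        coms = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert sf.phase_separation(coms, 10.0) == pytest.approx(9.0 / 4)

    def test_translation_invariance_mod_L(self):
        rng = np.random.default_rng(5)
        coms = rng.uniform(0, 8.0, size=(5, 3))
        g0 = sf.phase_separation(coms, 8.0)
        g1 = sf.phase_separation((coms + [13.0, -4.0, 8.0]) % 8.0, 8.0)
        assert g1 == pytest.approx(g0, rel=1e-10)

    def test_minimal_image_upper_bound(self):
        rng = np.random.default_rng(6)
        L, M = 6.0, 5
        bound = 0.75 * (L / 2) ** 2 * (M - 1) / M
        for _ in range(50):
            coms = rng.uniform(0, L, size=(M, 3))
            assert sf.phase_separation(coms, L) <= bound + 1e-12


class TestKernelConsistency:
    def test_series_observables_match_reference_implementation(self):
        """The compiled per-sweep measurement agrees with the numpy one."""
        spec = sf.bead_spring_spec(1.0)
        box = sf.box_from_density(8, 3, 1e-3)
        conf = initial_conformation(spec, 8, 3, box, seed=7)
        res = sf.run_canonical(conf, spec, 2.0, 50, seed=8)
        ref = measure(res.conf)
        last = res.series[-1]
        cols = res.columns
        assert last[cols.index("rg2")] == pytest.approx(ref["rg2"], rel=1e-10)
        assert last[cols.index("ree")] == pytest.approx(ref["ree"], rel=1e-10)
        assert last[cols.index("cr")] == pytest.approx(ref["cr"], rel=1e-10)
        assert last[cols.index("gamma2")] == pytest.approx(ref["gamma2"],
                                                           rel=1e-10)
        eb = sf.total_energy(res.conf, spec)
        assert last[cols.index("ep")] == pytest.approx(eb.ep, abs=1e-8)


class TestEnergyHistogram2D:
    def test_delta_input_single_bin(self):
        H, *_ = energy_histogram_2d(np.full(50, 1.0), np.full(50, 2.0),
                                    bins=5)
        assert (H > 0).sum() == 1
        assert H.sum() == 50

    def test_projection_conserves_weight(self):
        rng = np.random.default_rng(9)
        elj = rng.normal(size=400)
        ebend = rng.normal(size=400)
        w = rng.uniform(0.5, 2.0, size=400)
        H, _, _, proj = energy_histogram_2d(elj, ebend, weights=w, bins=12,
                                            kappa=3.0)
        assert H.sum() == pytest.approx(w.sum())
        assert proj[0].sum() == pytest.approx(w.sum())

    def test_antidiagonal_mixture_bimodal_2d_unimodal_projection(self):
        """Two phases separated along the anti-diagonal of (ELJ, EBend)
        coexist in the 2D histogram yet project onto a single peak in
        p(E): the mechanism that hides phase coexistence from p(E)."""
        rng = np.random.default_rng(10)
        kappa = 1.0
        n = 4000
        a = np.column_stack([rng.normal(-8, 0.5, n),
                             rng.normal(8, 0.5, n)])   # phase 1
        b = np.column_stack([rng.normal(-2, 0.5, n),
                             rng.normal(2, 0.5, n)])   # phase 2; same E sum
        elj = np.concatenate([a[:, 0], b[:, 0]])
        ebend = np.concatenate([a[:, 1], b[:, 1]])
        H, _, _, (pE, _) = energy_histogram_2d(elj, ebend, bins=30,
                                               kappa=kappa)
        # 2D: two separated occupied clusters
        occupied = H > H.max() * 0.1
        rows = np.nonzero(occupied.any(axis=1))[0]
        assert rows.max() - rows.min() > 10  # spread across the plane
        # projection: single mode (no double peak in p(E))
        from semiflex.reweighting import scan_peaks
        centers = np.arange(len(pE), dtype=float)
        peaks = scan_peaks(centers, pE.astype(float),
                           prominence=0.1 * pE.max())
        assert len(peaks) == 1
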