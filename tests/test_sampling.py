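"""Sampling machinery: determinism, weight tables, muca iteration,
microcanonical weights and parallel tempering."""

import numpy as np
import pytest

import semiflex as sf
from semiflex.fixtures import initial_conformation, rod
from semiflex.sampling import _update_weights


class TestDeterminism:
    def test_equal_seeds_bitwise_identical(self):
        spec = sf.bead_spring_spec(1.0)
        runs = []
        for _ in range(2):
            conf = initial_conformation(spec, 10, seed=3)
            runs.append(sf.run_canonical(conf, spec, 1.5, 500, seed=99))
        assert np.array_equal(runs[0].series, runs[1].series,
                              equal_nan=True)
        assert np.array_equal(runs[0].conf.positions, runs[1].conf.positions)

    def test_different_seeds_differ(self):
        spec = sf.bead_spring_spec(1.0)
        a = sf.run_canonical(initial_conformation(spec, 10, seed=3),
                             spec, 1.5, 500, seed=1)
        b = sf.run_canonical(initial_conformation(spec, 10, seed=3),
                             spec, 1.5, 500, seed=2)
        assert not np.array_equal(a.series, b.series)


class TestWeightTable:
    def test_lookup_and_out_of_range(self):
        tab = sf.WeightTable(np.array([0.0, 1.0, 2.0]), np.array([1.5, -2.0]))
        assert tab.lookup(0.5) == 1.5
        assert tab.lookup(1.0) == -2.0  # half-open bins
        assert tab.lookup(-0.1) == -np.inf
        assert tab.lookup(2.0) == -np.inf

    def test_tsv_round_trip_bit_exact(self, tmp_path):
        tab = sf.WeightTable.uniform(-3.0, 7.0, 0.5)
        tab.lnw[:] = np.random.default_rng(1).normal(size=tab.nbins)
        path = tmp_path / "w.tsv"
        tab.to_tsv(path)
        back = sf.WeightTable.from_tsv(path)
        assert np.array_equal(back.edges, tab.edges)
        assert np.array_equal(back.lnw, tab.lnw)

    def test_histogram_tsv_round_trip(self, tmp_path):
        h = sf.HistogramRecord(np.arange(6.0), np.array([0, 3, 5, 2, 1]), 11)
        path = tmp_path / "h.tsv"
        h.to_tsv(path)
        back = sf.HistogramRecord.from_tsv(path)
        assert np.array_equal(back.edges, h.edges)
        assert np.array_equal(back.counts, h.counts)
        assert back.total_sweeps == 11


class TestMucaUpdate:
    def test_flat_density_of_states_converges_immediately(self):
        """If the sampled histogram is already flat (flat true Omega under
        flat weights), the update changes lnW only by a constant."""
        tab = sf.WeightTable.uniform(0.0, 10.0, 1.0)
        counts = np.full(tab.nbins, 500)
        new = _update_weights(tab, counts, smooth_window=0)
        assert np.allclose(new - new[0], 0.0, atol=1e-12)

    def test_update_divides_out_histogram(self):
        tab = sf.WeightTable.uniform(0.0, 4.0, 1.0)
        counts = np.array([100, 200, 400, 800])
        new = _update_weights(tab, counts, smooth_window=0)
        # lnW differences must equal -ln H differences
        dlnw = np.diff(new)
        assert np.allclose(dlnw, -np.diff(np.log(counts)), atol=1e-12)

    def test_unvisited_ratios_carried_forward(self):
        tab = sf.WeightTable.uniform(0.0, 10.0, 1.0)
        rng = np.random.default_rng(3)
        tab.lnw[:] = -np.cumsum(rng.uniform(0.5, 1.5, 10))
        r_before = np.diff(tab.lnw)
        counts = np.zeros(10, np.int64)
        counts[4:8] = [100, 150, 220, 330]
        new = _update_weights(tab, counts, smooth_window=0)
        r_after = np.diff(new)
        # pairs with an unvisited member keep their log-weight ratio
        untouched = [0, 1, 2, 3, 7, 8]
        assert np.allclose(r_after[untouched], r_before[untouched],
                           atol=1e-12)
        # visited pairs absorb the full -dlnH correction
        assert np.allclose(r_after[4:7], r_before[4:7]
                           - np.diff(np.log(counts[4:8])), atol=1e-12)

    def test_damping_accumulates_statistics(self):
        tab = sf.WeightTable.uniform(0.0, 3.0, 1.0)
        gsum = np.zeros(2)
        counts = np.array([100, 100, 100], np.int64)
        _update_weights(tab, counts, gsum=gsum, smooth_window=0)
        g_first = gsum.copy()
        _update_weights(tab, counts, gsum=gsum, smooth_window=0)
        assert np.allclose(gsum, 2 * g_first)


class TestMucaPipeline:
    def test_small_chain_flat_histogram_and_consistency(self):
        """Weight iteration on a short flexible chain reaches the flatness
        criterion and the reweighted energy matches a direct run."""
        spec = sf.bead_spring_spec(0.0)
        conf = initial_conformation(spec, 8, seed=1)
        muca = sf.iterate_muca_weights(conf, spec, -25.0, 25.0, de=0.5,
                                       seed=2, sweeps_init=3000,
                                       sweeps_max=20_000, max_iter=25,
                                       beta_max=1.0, t_hot=3.0)
        assert muca.converged
        series, run = sf.muca_production(muca.conf, spec, muca.weights,
                                         40_000, seed=3)
        assert run.hist.flatness(muca.window) >= 0.5
        direct = sf.run_canonical(initial_conformation(spec, 8, seed=4),
                                  spec, 2.0, 40_000, discard=4000, seed=5)
        v_mu, e_mu = sf.jackknife(
            series, lambda s: sf.reweight(s, 0.5, s.ep).value, 20)
        tagged = sf.TaggedSeries.from_run(direct, 0.5)
        v_di, e_di = sf.jackknife(tagged, lambda s: s.ep.mean(), 20)
        comb = np.hypot(e_mu, e_di)
        assert abs(v_mu - v_di) < 3 * comb

    def test_parallel_walkers_equivalent(self):
        """Two walkers converge to weights consistent with one walker and
        keep independent final conformations."""
        spec = sf.bead_spring_spec(0.0)
        conf = initial_conformation(spec, 8, seed=1)
        muca2 = sf.parallel_muca(conf, spec, -25.0, 25.0, 2, de=0.5,
                                 seed=2, sweeps_init=3000,
                                 sweeps_max=20_000, max_iter=25,
                                 beta_max=1.0, t_hot=3.0)
        assert muca2.converged
        assert len(muca2.confs) == 2
        assert not np.array_equal(muca2.confs[0].positions,
                                  muca2.confs[1].positions)


class TestMicrocanonicalWeight:
    def test_closed_form_values(self):
        assert sf.microcanonical_weight(0.0, 2.0, 4) == pytest.approx(2.0)
        # Ndof = 2: exponent zero, weight 1 for every Ep < E
        for ep in (-5.0, 0.0, 0.9):
            assert sf.microcanonical_weight(ep, 1.0, 2) == 1.0
        assert sf.microcanonical_weight(3.0, 2.0, 4) == 0.0

    def test_exponent_counts_momentum_degrees_of_freedom(self):
        # 4 chains of 13 beads: Ndof = 3 * 52 = 156, exponent 77
        ndof = 3 * 13 * 4
        w = sf.microcanonical_weight(-1.0, 1.0, ndof)
        assert w == pytest.approx(2.0 ** 77)

    def test_weight_table_rejects_above_total_energy(self):
        tab = sf.nve_weight_table(5.0, 30, -10.0, 10.0, 0.5)
        assert np.all(np.isinf(tab.lnw[tab.centers >= 5.0]))
        assert np.all(np.isfinite(tab.lnw[tab.centers < 5.0]))


class TestParallelTempering:
    def test_equal_temperatures_always_swap(self):
        spec = sf.bead_stick_spec(1.0, eps=0.0)
        conf = sf.Conformation(rod(3), 3, 1)
        _, stats = sf.parallel_tempering(conf, spec, [1.0, 1.0], 600,
                                         swap_interval=100, seed=4)
        assert stats["attempts"][0] > 0
        assert stats["accepts"][0] == stats["attempts"][0]

    def test_disabled_swaps_are_independent_runs(self):
        spec = sf.bead_stick_spec(1.0, eps=0.0)
        conf = sf.Conformation(rod(3), 3, 1)
        _, stats = sf.parallel_tempering(conf, spec, [1.0, 2.0], 500,
                                         swap_interval=0, seed=4)
        assert sum(stats["attempts"].values()) == 0

    def test_swaps_preserve_per_temperature_ensembles(self):
        """With swaps on, each ladder rung still samples its own Boltzmann
        ensemble (bending trimer vs the Langevin closed form)."""
        spec = sf.bead_stick_spec(1.0, eps=0.0)
        conf = sf.Conformation(rod(3), 3, 1)
        temps = [1.0, 2.0]
        series, stats = sf.parallel_tempering(conf, spec, temps, 30_000,
                                              swap_interval=50, seed=8,
                                              discard=3000)
        assert stats["accepts"][0] > 0
        ix = sf.RunResult.columns.index("ebend")
        for T, s in zip(temps, series):
            cos = 1.0 - s[:, ix]
            x = 1.0 / T
            target = 1.0 / np.tanh(x) - 1.0 / x
            sem = cos.std() / np.sqrt(len(cos) / 20)  # crude blocking
            assert abs(cos.mean() - target) < 4 * sem
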