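"""Generator: founder, drift/selection mechanics, mutation influx, sequencing."""

import numpy as np
import pytest

from mitolineage import calling
from mitolineage.simulate import (
    CellState,
    MutationSiteIndex,
    SimulationConfig,
    Variant,
    acquire_mutations,
    divide,
    run_simulation,
    sequence_cell,
    sequence_all,
    simulate_founder,
    synthetic_reference,
)


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(
        seed=11,
        n_cells={"ctrl.ipsc": 4, "ctrl.astroglia": 4},
        genome_length=1000,
        t_expansion=5,
        t_differentiation=5,
        mu={"default": 0.1},
    )


@pytest.fixture(scope="module")
def small_ref():
    return synthetic_reference(1000, seed=3)


@pytest.fixture(scope="module")
def site_index(small_ref):
    return MutationSiteIndex(small_ref)


class TestFounder:
    def test_zero_variants_empty_genotype(self, small_ref, site_index):
        cfg = SimulationConfig(n_founder_variants=0, genome_length=1000)
        founder, meta = simulate_founder(
            cfg, small_ref, np.random.default_rng(0), site_index
        )
        assert founder.genotype == {} and meta == {}

    def test_exact_hf_quantization(self, small_ref, site_index):
        cfg = SimulationConfig(
            n_founder_variants=1, founder_hf=[0.5],
            copy_number={"ipsc": 100}, genome_length=1000,
        )
        founder, _ = simulate_founder(
            cfg, small_ref, np.random.default_rng(0), site_index
        )
        assert list(founder.genotype.values()) == [50]

    def test_out_of_range_hf_rejected(self, small_ref, site_index):
        cfg = SimulationConfig(
            n_founder_variants=1, founder_hf=[1.5], genome_length=1000
        )
        with pytest.raises(ValueError):
            simulate_founder(cfg, small_ref, np.random.default_rng(0), site_index)

    def test_same_seed_identical_founder(self, small_ref, site_index):
        cfg = SimulationConfig(genome_length=1000)
        f1, _ = simulate_founder(cfg, small_ref, np.random.default_rng(5), site_index)
        f2, _ = simulate_founder(cfg, small_ref, np.random.default_rng(5), site_index)
        assert f1.genotype == f2.genotype


class TestDivide:
    def _cell(self, k, N=500):
        v = Variant(10, "A", "G")
        return CellState("c", "ipsc", "ctrl", N, {v: k}), v

    def test_fixed_variant_absorbing(self):
        cell, v = self._cell(500)
        out = divide(cell, {}, np.random.default_rng(0))
        assert out.genotype[v] == 500

    def test_lethal_selection_lost_in_one_division(self):
        cell, v = self._cell(300)
        out = divide(cell, {"founder": -1 + 1e-12}, np.random.default_rng(0),
                     classes={v: "founder"})
        # weight ~0: resampling probability ~0
        assert v not in out.genotype

    def test_neutral_mean_and_variance_match_binomial(self):
        """Monte-Carlo vs the closed-form Binomial(N, p) resampling law."""
        N, p0, reps = 500, 0.3, 10_000
        rng = np.random.default_rng(99)
        cell, v = self._cell(int(p0 * N), N)
        ps = np.array([
            divide(cell, {}, rng).genotype.get(v, 0) / N for _ in range(reps)
        ])
        se_mean = np.sqrt(p0 * (1 - p0) / N / reps)
        assert abs(ps.mean() - p0) < 3 * se_mean
        assert ps.var() == pytest.approx(p0 * (1 - p0) / N, rel=0.1)

    def test_selection_shifts_expected_frequency(self):
        """E[p'] = p(1+s)/(1+ps) under weighted resampling."""
        N, p0, s, reps = 500, 0.3, -0.2, 10_000
        rng = np.random.default_rng(7)
        cell, v = self._cell(int(p0 * N), N)
        ps = np.array([
            divide(cell, {"founder": s}, rng, classes={v: "founder"})
            .genotype.get(v, 0) / N
            for _ in range(reps)
        ])
        expected = p0 * (1 + s) / (1 + p0 * s)
        se = np.sqrt(expected * (1 - expected) / N / reps)
        assert abs(ps.mean() - expected) < 3 * se

    def test_copy_number_transition(self):
        cell, v = self._cell(250, N=500)
        out = divide(cell, {}, np.random.default_rng(1), N_new=1000)
        assert out.N == 1000
        assert 0 < out.genotype[v] <= 1000


class TestAcquireMutations:
    def test_mu_zero_unchanged(self, small_ref, site_index):
        cfg = SimulationConfig(genome_length=1000)
        cell = CellState("c", "ipsc", "ctrl", 500, {})
        meta = {}
        out = acquire_mutations(cell, 0.0, cfg, site_index,
                                np.random.default_rng(0), meta, "post-founder")
        assert out.genotype == {} and meta == {}

    def test_poisson_mean_recovered(self, small_ref, site_index):
        cfg = SimulationConfig(genome_length=1000)
        rng = np.random.default_rng(2)
        mu, reps = 2.0, 2000
        counts = []
        for _ in range(reps):
            cell = CellState("c", "ipsc", "ctrl", 500, {})
            out = acquire_mutations(cell, mu, cfg, site_index, rng, {},
                                    "post-founder")
            counts.append(len(out.genotype))
        se = np.sqrt(mu / reps)
        assert abs(np.mean(counts) - mu) < 3 * se

    def test_concentrated_weights_single_class(self, small_ref, site_index):
        w = np.zeros(96)
        # pick a class that has candidate sites on this genome
        cls = next(i for i in range(96) if site_index.sites[i])
        w[cls] = 1.0
        cfg = SimulationConfig(signature_weights=w, genome_length=1000)
        cell = CellState("c", "ipsc", "ctrl", 500, {})
        meta = {}
        out = acquire_mutations(cell, 5.0, cfg, site_index,
                                np.random.default_rng(3), meta, "post-founder")
        assert all(info.class96 == cls for info in meta.values())
        assert all(k == 1 for k in out.genotype.values())

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(signature_weights=np.zeros(96))


class TestRunSimulation:
    def test_no_divisions_no_mutation_cells_equal_founder(self, small_ref):
        cfg = SimulationConfig(
            seed=1, n_cells={"ctrl.ipsc": 3}, t_expansion=0,
            t_differentiation=0, mu={"default": 0.0}, genome_length=1000,
        )
        res = run_simulation(cfg, ref=small_ref)
        genos = [c.genotype for c in res.cells]
        assert all(g == genos[0] for g in genos)
        assert all(o == "founder" for o in res.truth["origin"])

    def test_bit_reproducible_under_seed(self, small_config):
        r1 = run_simulation(small_config)
        r2 = run_simulation(small_config)
        assert r1.truth.equals(r2.truth)
        assert r1.reference.sequence == r2.reference.sequence
        t1 = sequence_all(r1)
        t2 = sequence_all(r2)
        for cid in t1:
            for a, b in zip(t1[cid], t2[cid]):
                assert a.counts.equals(b.counts)

    def test_truth_origins_consistent(self, small_config):
        res = run_simulation(small_config)
        ipsc = res.truth[res.truth["cell_type"] == "ipsc"]
        assert set(ipsc["origin"]) <= {"founder", "post-founder"}

    def test_negative_selection_lowers_differentiated_hf(self):
        base = dict(
            n_cells={"ctrl.ipsc": 2, "ctrl.astroglia": 40},
            genome_length=1000, t_expansion=0, t_differentiation=15,
            mu={"default": 0.0}, founder_hf=[0.3] * 4, n_founder_variants=4,
            copy_number={"default": 300},
        )
        sel = run_simulation(SimulationConfig(seed=5, s={"founder": -0.15}, **base))
        neu = run_simulation(SimulationConfig(seed=5, s={"founder": 0.0}, **base))

        def mean_hf(res):
            t = res.truth
            return t[(t["cell_type"] == "astroglia")
                     & (t["origin"] == "founder")]["true_hf"].mean()

        assert mean_hf(sel) < mean_hf(neu)
        assert mean_hf(sel) < 0.3


class TestSequencing:
    def _fixed_cell(self, small_ref, hf=1.0, N=100):
        pos = 17
        ref_base = small_ref.base(pos)
        alt = "G" if ref_base != "G" else "T"
        v = Variant(pos, ref_base, alt)
        cell = CellState("c", "ipsc", "ctrl", N, {v: int(hf * N)})
        return cell, v

    def test_error_free_fixed_variant_all_alt(self, small_ref):
        cell, v = self._fixed_cell(small_ref, hf=1.0)
        cfg = SimulationConfig(error_rate=0.0, depth_mean=200,
                               depth_sdlog=1e-9, genome_length=1000)
        tables = sequence_cell(cell, small_ref, cfg, np.random.default_rng(0))
        assert len(tables) == 2
        for t in tables:
            row = t.counts[t.counts["pos"] == v.pos].iloc[0]
            depth = sum(row[b] for b in "ACGT")
            assert row[v.alt] == depth > 0

    def test_error_free_no_variants_all_reference(self, small_ref):
        cell = CellState("c", "ipsc", "ctrl", 100, {})
        cfg = SimulationConfig(error_rate=0.0, depth_mean=100,
                               depth_sdlog=1e-9, genome_length=1000)
        (t, _) = sequence_cell(cell, small_ref, cfg, np.random.default_rng(0))
        counts = t.counts
        for b in "ACGT":
            off_ref = counts.loc[counts["ref"] != b, b]
            assert (off_ref == 0).all()

    def test_observed_alt_fraction_matches_error_mixture(self, small_ref):
        """Closed form: q_alt = p(1-e) + (1-p) e/3 at a heteroplasmic site."""
        p, e = 0.05, 1e-3
        cell, v = self._fixed_cell(small_ref, hf=p, N=1000)
        cfg = SimulationConfig(error_rate=e, depth_mean=2500,
                               depth_sdlog=1e-9, genome_length=1000, n_runs=1)
        rng = np.random.default_rng(123)
        alt_total, depth_total = 0, 0
        for _ in range(200):
            (t,) = sequence_cell(cell, small_ref, cfg, rng)
            row = t.counts[t.counts["pos"] == v.pos].iloc[0]
            alt_total += int(row[v.alt])
            depth_total += int(sum(row[b] for b in "ACGT"))
        q = p * (1 - e) + (1 - p) * e / 3
        se = np.sqrt(q * (1 - q) / depth_total)
        assert abs(alt_total / depth_total - q) < 3 * se

    def test_runs_are_independent_draws(self, small_ref):
        cell, v = self._fixed_cell(small_ref, hf=0.5, N=100)
        cfg = SimulationConfig(error_rate=1e-3, depth_mean=500,
                               depth_sdlog=1e-9, genome_length=1000)
        t1, t2 = sequence_cell(cell, small_ref, cfg, np.random.default_rng(5))
        assert not t1.counts.equals(t2.counts)


def test_neutral_drift_is_martingale():
    """Grand mean HF conserved under s=0 across the whole simulated run."""
    cfg = SimulationConfig(
        seed=21, n_cells={"ctrl.ipsc": 60}, founder_hf=[0.4] * 3,
        n_founder_variants=3, t_expansion=12, t_differentiation=0,
        mu={"default": 0.0}, s={}, genome_length=1000,
        copy_number={"default": 400},
    )
    res = run_simulation(cfg)
    hf = []
    founder_vars = list(res.founders["ctrl"].genotype)
    for cell in res.cells:
        for v in founder_vars:
            hf.append(cell.hf(v))
    hf = np.asarray(hf)
    se = hf.std(ddof=1) / np.sqrt(len(hf))
    assert abs(hf.mean() - 0.4) < 3 * se


def test_neutral_drift_variance_law_small():
    """Var(HF) ~ p0(1-p0)(1-(1-1/N)^t) (scaled-down check of the law)."""
    N, t, p0, n_cells = 300, 10, 0.3, 400
    rng = np.random.default_rng(17)
    v = Variant(5, "A", "G")
    ps = []
    for _ in range(n_cells):
        cell = CellState("c", "ipsc", "ctrl", N, {v: int(p0 * N)})
        for _ in range(t):
            cell = divide(cell, {}, rng)
        ps.append(cell.hf(v))
    expected = p0 * (1 - p0) * (1 - (1 - 1 / N) ** t)
    assert np.var(ps) == pytest.approx(expected, rel=0.25)
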