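"""One-sample gene-level inference: statistic, Monte-Carlo null, p-values."""

import math

import numpy as np
import pytest
from scipy import stats

from asekit.distributions import ft_backtransform, ft_transform
from asekit.onesample import (
    AseUnit,
    ModelParams,
    NullModel,
    gene_statistic,
    p_values,
    run_one_sample,
    simulate_null,
)
from asekit.phasing import SnvCount, pseudo_phase


def unit(ase_id, counts, labels=None):
    labels = labels or [None] * len(counts)
    return AseUnit(
        ase_id=ase_id,
        snvs=tuple(
            SnvCount(locus_id=f"l{i}", ref_count=r, alt_count=a, hap1_is_ref=h)
            for i, ((r, a), h) in enumerate(zip(counts, labels))
        ),
    )


class TestGeneStatistic:
    def test_single_snv_is_ft_roundtrip(self):
        phased = pseudo_phase([SnvCount("l", 15, 5)])
        t, q = gene_statistic(phased, ModelParams())
        assert t == pytest.approx(ft_backtransform(ft_transform(15, 20).z))
        assert 15 / 21 <= t <= 16 / 21
        assert q == 0.0

    def test_balanced_identical_snvs_give_half(self):
        phased = pseudo_phase([SnvCount("a", 10, 10), SnvCount("b", 10, 10)])
        t, q = gene_statistic(phased, ModelParams())
        assert t == pytest.approx(0.5)
        assert q == pytest.approx(0.0)

    def test_discordant_snvs_have_positive_q(self):
        phased = pseudo_phase([SnvCount("a", 20, 0), SnvCount("b", 10, 10)])
        _, q = gene_statistic(phased, ModelParams())
        assert q > 0.0

    def test_bias_inversion_reports_transcript_scale(self):
        # observed 60% reference under f = 0.6 means balanced transcription
        phased = pseudo_phase([SnvCount("l", 120, 80)])
        t, _ = gene_statistic(phased, ModelParams(f_ref_null=0.6))
        assert t == pytest.approx(0.5, abs=0.01)


class TestSimulateNull:
    def test_single_snv_null_matches_enumeration(self):
        """Empirical null CDF vs exhaustive 21-outcome binomial enumeration."""
        n = 20
        model = NullModel(totals=(n,), rho=0.0, n_sim=100_000, seed=2, hap1_f=(0.5,))
        null = simulate_null(model)
        # exact null: T(x) determined by major count; weights binomial
        maj = np.maximum(np.arange(n + 1), n - np.arange(n + 1))
        t_exact = np.array([ft_backtransform(ft_transform(int(m), n).z) for m in maj])
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        for m in range(n // 2, n + 1):
            t_thresh = ft_backtransform(ft_transform(m, n).z)
            exact = pmf[t_exact >= t_thresh - 1e-12].sum()
            sim = (null.t_null >= t_thresh - 1e-12).mean()
            se = math.sqrt(max(exact * (1 - exact), 1e-12) / model.n_sim)
            assert abs(sim - exact) <= 3 * se + 1e-9

    def test_extreme_tail_probability(self):
        model = NullModel(totals=(20,), rho=0.0, n_sim=200_000, seed=4, hap1_f=(0.5,))
        null = simulate_null(model)
        p_max = (null.t_null >= null.t_null.max() - 1e-12).mean()
        assert p_max < 1e-4  # exact value 2 * 0.5^20 ~ 1.9e-6

    def test_bit_identical_reruns(self):
        model = NullModel(totals=(25, 30), rho=0.004, n_sim=5000, seed=9, hap1_f=(0.5, 0.5))
        a = simulate_null(model)
        b = simulate_null(model)
        assert np.array_equal(a.t_null, b.t_null)
        assert np.array_equal(a.q_null, b.q_null)

    def test_pseudo_phasing_inflates_null_median(self):
        model = NullModel(
            totals=(50, 50, 50), rho=0.0, n_sim=20_000, seed=1, hap1_f=(0.5,) * 3
        )
        null = simulate_null(model)
        assert np.median(null.t_null) > 0.5

    def test_small_n_sim_warns(self):
        model = NullModel(totals=(20,), rho=0.0, n_sim=50, seed=0, hap1_f=(0.5,))
        with pytest.warns(UserWarning):
            simulate_null(model)


class TestPValues:
    def test_balanced_observation_not_significant(self):
        model = NullModel(totals=(30, 30), rho=0.0, n_sim=10_000, seed=3, hap1_f=(0.5, 0.5))
        null = simulate_null(model)
        p_ase, _ = p_values((0.5, 0.0), null, k=2)
        assert p_ase == pytest.approx(1.0, abs=1e-9)

    def test_floor_when_above_all_draws(self):
        model = NullModel(totals=(30,), rho=0.0, n_sim=1000, seed=3, hap1_f=(0.5,))
        null = simulate_null(model)
        p_ase, _ = p_values((1.1, 0.0), null, k=1)
        assert p_ase == pytest.approx(1.0 / 1001.0)

    def test_single_snv_k1_has_no_heterogeneity_p(self):
        model = NullModel(totals=(30,), rho=0.0, n_sim=1000, seed=3, hap1_f=(0.5,))
        null = simulate_null(model)
        _, p_het = p_values((0.6, 0.0), null, k=1)
        assert p_het is None

    def test_monoallelic_10_of_10_near_exact_binomial(self):
        res = run_one_sample([unit("g", [(10, 0)])], ModelParams(), n_sim=200_000, seed=8)
        exact = 2 / 1024  # two-sided exact binomial at p = 0.5
        se = math.sqrt(exact * (1 - exact) / 200_000)
        assert abs(res[0].p_ase - exact) <= 3 * se


class TestRunOneSample:
    def test_monoallelic_gene(self):
        res = run_one_sample(
            [unit("g", [(30, 0), (28, 0)])], ModelParams(), n_sim=20_000, seed=1
        )
        assert res[0].maf_estimate > 0.95
        assert res[0].p_ase <= 2e-4

    def test_identical_genes_identical_results(self):
        genes = [unit("g1", [(18, 6), (20, 5)]), unit("g2", [(18, 6), (20, 5)])]
        res = run_one_sample(genes, ModelParams(), n_sim=5000, seed=7)
        assert res[0].maf_estimate == res[1].maf_estimate
        assert res[0].p_ase == res[1].p_ase
        assert res[0].p_heterogeneity == res[1].p_heterogeneity

    def test_gene_order_does_not_change_results(self):
        genes = [unit("a", [(18, 6)]), unit("b", [(40, 9), (33, 30)])]
        res_fwd = run_one_sample(genes, ModelParams(), n_sim=5000, seed=7)
        res_rev = run_one_sample(genes[::-1], ModelParams(), n_sim=5000, seed=7)
        by_id_fwd = {r.ase_id: r.p_ase for r in res_fwd}
        by_id_rev = {r.ase_id: r.p_ase for r in res_rev}
        assert by_id_fwd == by_id_rev

    def test_known_phase_path_swaps_to_major(self):
        res = run_one_sample(
            [unit("g", [(2, 20), (3, 22)], labels=[True, True])],
            ModelParams(),
            n_sim=5000,
            seed=2,
        )
        assert res[0].maf_estimate > 0.8  # hap2 is major after the swap
        assert res[0].phase.phase_source == "known"

    def test_failing_gene_flagged_not_raised(self):
        good = unit("ok", [(15, 5)])
        bad = AseUnit(ase_id="bad", snvs=(SnvCount("l", 0, 0),))
        res = run_one_sample([good, bad], ModelParams(), n_sim=2000, seed=1)
        assert res[0].error is None
        assert res[1].error is not None
        assert math.isnan(res[1].p_ase)

    def test_maf_estimate_consistency(self):
        """At 5 SNVs x 200 reads, true MAF 0.8: mean estimate within 0.02."""
        rng = np.random.default_rng(21)
        params = ModelParams()
        estimates = []
        for _ in range(500):
            counts = rng.binomial(200, 0.8, size=5)
            phased = pseudo_phase(
                [SnvCount(f"l{i}", int(c), 200 - int(c)) for i, c in enumerate(counts)]
            )
            estimates.append(gene_statistic(phased, params)[0])
        assert abs(np.mean(estimates) - 0.8) < 0.02
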