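"""Two-sample differential ASE: PD scores, pooled null, calibration."""

import numpy as np
import pytest

from asekit.onesample import ModelParams
from asekit.phasing import SnvCount, phase_by_other_sample
from asekit.simulation import SimConfig, StratumSpec, generate_dataset
from asekit.twosample import GenePair, estimate_null_p, pd_score, run_two_sample


def snv(ref, alt, locus="l"):
    return SnvCount(locus_id=locus, ref_count=ref, alt_count=alt)


class TestPdScore:
    def test_hand_evaluation(self):
        z, v = pd_score(18, 20, 10, 20, 0.7)
        assert z == pytest.approx(0.4)
        assert v == pytest.approx(0.21 / 20 + 0.21 / 20)

    def test_identical_proportions_zero(self):
        z, _ = pd_score(10, 20, 10, 20, 0.3)
        assert z == 0.0

    def test_maximal_difference(self):
        z, _ = pd_score(20, 20, 0, 20, 0.5)
        assert z == 1.0

    def test_overdispersion_inflates_variance(self):
        _, v0 = pd_score(10, 20, 10, 40, 0.5)
        _, v1 = pd_score(10, 20, 10, 40, 0.5, rho=0.01)
        assert v1 == pytest.approx(
            0.25 / 20 * (0.01 * 19 + 1) + 0.25 / 40 * (0.01 * 39 + 1)
        )
        assert v1 > v0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pd_score(0, 0, 5, 10, 0.5)
        with pytest.raises(ValueError):
            pd_score(25, 20, 5, 10, 0.5)
        with pytest.raises(ValueError):
            pd_score(5, 20, 5, 10, 1.0)


class TestEstimateNullP:
    def test_pooled_counts(self):
        pair = phase_by_other_sample([snv(18, 2)], [snv(10, 10)])
        assert estimate_null_p(pair) == pytest.approx(28 / 40)

    def test_balanced(self):
        pair = phase_by_other_sample([snv(10, 10)], [snv(10, 10)])
        assert estimate_null_p(pair) == pytest.approx(0.5)

    def test_clipping_keeps_strictly_inside(self):
        pair = phase_by_other_sample([snv(20, 0)], [snv(20, 0)])
        p = estimate_null_p(pair)
        assert p == pytest.approx(1.0 - 1.0 / 42.0)
        assert p < 1.0


class TestRunTwoSample:
    def test_strong_tumor_specific_signal(self):
        pairs = [
            GenePair(
                "g",
                (snv(20, 0, "1"), snv(20, 0, "2")),
                (snv(10, 10, "1"), snv(10, 10, "2")),
            )
        ]
        res = run_two_sample(pairs, ModelParams(), n_sim=20_000, seed=3)
        assert res[0].maf_difference == pytest.approx(0.5)
        assert res[0].p_ase < 0.01

    def test_identical_samples_null(self):
        counts = [(12, 8, "1"), (9, 11, "2")]
        pairs = [
            GenePair(
                "g",
                tuple(snv(r, a, l) for r, a, l in counts),
                tuple(snv(r, a, l) for r, a, l in counts),
            )
        ]
        res = run_two_sample(pairs, ModelParams(), n_sim=20_000, seed=3)
        assert res[0].maf_difference == pytest.approx(0.0)
        assert res[0].p_ase > 0.5

    def test_swapping_roles_negates_difference_under_fixed_anchor(self):
        from asekit.twosample import _pair_statistic

        interest = (snv(18, 2, "1"), snv(16, 5, "2"))
        other = (snv(10, 10, "1"), snv(11, 10, "2"))
        anchored, imposed = phase_by_other_sample(interest, other)
        mu = np.full(2, estimate_null_p((anchored, imposed)))
        t_fwd, q_fwd = _pair_statistic(anchored, imposed, mu, rho=0.0)
        t_rev, q_rev = _pair_statistic(imposed, anchored, mu, rho=0.0)
        assert t_fwd == pytest.approx(-t_rev)
        assert q_fwd == pytest.approx(q_rev)
        assert t_fwd > 0

    def test_locus_mismatch_flagged_per_gene(self):
        bad = GenePair.__new__(GenePair)  # bypass validation to hit runtime check
        object.__setattr__(bad, "ase_id", "bad")
        object.__setattr__(bad, "snvs_interest", (snv(5, 5, "x"),))
        object.__setattr__(bad, "snvs_other", (snv(5, 5, "y"),))
        good = GenePair("ok", (snv(15, 5, "1"),), (snv(10, 10, "1"),))
        res = run_two_sample([good, bad], ModelParams(), n_sim=1000, seed=1)
        assert res[0].error is None
        assert res[1].error is not None

    def test_null_p_values_near_uniform_or_conservative(self):
        cfg = SimConfig(tp_fraction=0.0, rho=0.004, mode="two_sample", seed=9)
        units, _ = generate_dataset(
            [StratumSpec("2", "20-30", 150), StratumSpec("3", "30-40", 150)],
            cfg,
            rng=np.random.default_rng(9),
        )
        res = run_two_sample(units, ModelParams(rho=0.004), n_sim=4000, seed=9)
        p = np.array([r.p_ase for r in res])
        for alpha in (0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / len(p))
            assert (p <= alpha).mean() <= alpha + 3 * se

    def test_two_sample_power_below_one_sample_at_matched_design(self):
        """The extra normal-sample noise costs power at equal coverage/effect."""
        from asekit.onesample import run_one_sample

        cfg = SimConfig(
            tp_fraction=1.0, maf_signal=0.8, rho=0.004, mode="two_sample", seed=14
        )
        units, _ = generate_dataset(
            [StratumSpec("2", "20-30", 120)], cfg, rng=np.random.default_rng(14)
        )
        res2 = run_two_sample(units, ModelParams(rho=0.004), n_sim=4000, seed=14)
        from asekit.onesample import AseUnit

        res1 = run_one_sample(
            [AseUnit(u.ase_id, u.snvs_interest) for u in units],
            ModelParams(rho=0.004),
            n_sim=4000,
            seed=14,
        )
        power2 = np.mean([r.p_ase <= 0.05 for r in res2])
        power1 = np.mean([r.p_ase <= 0.05 for r in res1])
        assert power2 <= power1 + 0.02
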