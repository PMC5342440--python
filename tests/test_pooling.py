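"""Fixed/random pooling, heterogeneity, model selection, subgroup and
leave-one-out analyses, with brute-force and external (metafor) oracles."""

import shutil
import subprocess

import numpy as np
import pytest

from snpmeta import (
    EffectEstimate,
    TwoByTwo,
    dersimonian_laird,
    leave_one_out,
    pool,
    pool_fixed_iv,
    pool_fixed_mh,
    select_model,
    subgroup_pool,
    woolf_estimate,
)


def est(theta, se, study_id=None):
    z = theta / se
    return EffectEstimate(
        log_or=theta, se=se, or_=float(np.exp(theta)),
        ci_low=float(np.exp(theta - 1.96 * se)),
        ci_high=float(np.exp(theta + 1.96 * se)),
        z=z, p=1.0, study_id=study_id,
    )


def random_estimates(rng, k):
    return [est(float(t), float(s)) for t, s in
            zip(rng.normal(0, 0.5, k), rng.uniform(0.05, 0.6, k))]


class TestPoolFixedIV:
    def test_two_study_allele_pool_matches_printed_row(self, table1):
        res = pool(table1, "rs1563828", "allele", method="fixed_iv")
        assert round(res.pooled_or, 2) == 0.95
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.75, 1.20)
        assert round(res.p, 3) == 0.658
        assert round(res.p_het, 3) == 0.928
        assert res.i2 == 0.0

    def test_single_estimate_passes_through(self):
        e = est(0.3, 0.12)
        res = pool_fixed_iv([e])
        assert res.pooled_or == pytest.approx(e.or_, rel=1e-12)
        assert (res.q, res.i2, res.p_het) == (0.0, 0.0, 1.0)

    def test_homogeneous_estimates_have_zero_q(self):
        res = pool_fixed_iv([est(0.2, 0.1)] * 7)
        assert res.log_or == pytest.approx(0.2, abs=1e-14)
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pool_fixed_iv([])

    def test_matches_brute_force_weighted_mean(self):
        """Oracle: 200 random estimate sets against an independent
        elementwise weighted-mean/Q computation."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            k = int(rng.integers(2, 12))
            ests = random_estimates(rng, k)
            res = pool_fixed_iv(ests)
            num = den = 0.0
            for e in ests:
                num += e.log_or / e.se**2
                den += 1.0 / e.se**2
            mean = num / den
            q = sum((e.log_or - mean) ** 2 / e.se**2 for e in ests)
            assert res.log_or == pytest.approx(mean, rel=1e-10, abs=1e-12)
            assert res.se == pytest.approx(den**-0.5, rel=1e-10)
            assert res.q == pytest.approx(q, rel=1e-10, abs=1e-12)

    def test_pooled_se_not_above_best_study_se(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            ests = random_estimates(rng, int(rng.integers(1, 10)))
            assert pool_fixed_iv(ests).se <= min(e.se for e in ests) + 1e-12


class TestPoolFixedMH:
    def test_single_table_equals_crude_or(self):
        t = TwoByTwo(133, 287, 132, 268)
        res = pool_fixed_mh([t])
        assert res.pooled_or == pytest.approx(woolf_estimate(t).or_, rel=1e-12)

    def test_close_to_iv_on_balanced_data(self, table1):
        iv = pool(table1, "rs1563828", "allele", method="fixed_iv")
        mh = pool(table1, "rs1563828", "allele", method="fixed_mh")
        assert abs(mh.pooled_or - iv.pooled_or) < 0.01

    def test_degenerate_tables_inestimable(self):
        with pytest.raises(ValueError, match="inestimable"):
            pool_fixed_mh([TwoByTwo(1, 0, 0, 1), TwoByTwo(2, 0, 0, 2)])


class TestDerSimonianLaird:
    def test_truncates_to_fixed_when_q_small(self):
        ests = [est(0.20, 0.1), est(0.21, 0.1), est(0.19, 0.1)]
        dl = dersimonian_laird(ests)
        iv = pool_fixed_iv(ests)
        assert dl.tau2 == 0.0
        assert dl.pooled_or == pytest.approx(iv.pooled_or, rel=1e-12)
        assert dl.se == pytest.approx(iv.se, rel=1e-12)

    def test_hand_computed_tau2(self):
        # theta = 0, 1 with se^2 = 0.1: Q = 5, C = 10, tau2 = 0.4
        ests = [est(0.0, np.sqrt(0.1)), est(1.0, np.sqrt(0.1))]
        dl = dersimonian_laird(ests)
        assert dl.q == pytest.approx(5.0, rel=1e-12)
        assert dl.tau2 == pytest.approx(0.4, rel=1e-12)

    def test_asian_allele_pool_equals_fixed_at_zero_i2(self, asian_rs4245739):
        dl = pool(asian_rs4245739, "rs4245739", "allele", method="random_dl")
        iv = pool(asian_rs4245739, "rs4245739", "allele", method="fixed_iv")
        assert dl.i2 == 0.0
        assert dl.pooled_or == pytest.approx(iv.pooled_or, rel=1e-12)
        assert round(dl.pooled_or, 2) == 0.53
        assert (round(dl.ci_low, 2), round(dl.ci_high, 2)) == (0.45, 0.62)

    def test_ci_never_narrower_than_fixed(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ests = random_estimates(rng, int(rng.integers(2, 10)))
            dl, iv = dersimonian_laird(ests), pool_fixed_iv(ests)
            width_dl = np.log(dl.ci_high) - np.log(dl.ci_low)
            width_iv = np.log(iv.ci_high) - np.log(iv.ci_low)
            assert width_dl >= width_iv - 1e-12
            assert dl.tau2 >= 0.0
            assert 0.0 <= dl.i2 <= 100.0


class TestSelectModel:
    @pytest.mark.parametrize(
        "p_het,i2,expected",
        [
            (0.928, 0.0, "fixed_iv"),
            (0.0005, 90.6, "random_dl"),
            (0.05, 10.0, "random_dl"),
            (0.5, 60.0, "random_dl"),
            (0.11, 50.0, "fixed_iv"),
        ],
    )
    def test_conventional_rule(self, p_het, i2, expected):
        assert select_model(0.0, 5, p_het, i2) == expected


class TestPoolDriver:
    def test_asian_dominant_pool(self, asian_rs4245739):
        res = pool(asian_rs4245739, "rs4245739", "dominant")
        assert round(res.pooled_or, 2) == 0.51
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.43, 0.60)
        assert res.k == 7

    def test_asian_recessive_zero_cell_bookkeeping(self, asian_rs4245739):
        res = pool(asian_rs4245739, "rs4245739", "recessive", zero_policy="drop")
        assert res.k == 3
        assert set(res.excluded_ids) == {"Gao2015b", "Fan2014", "Liu2013a", "Liu2013b"}
        assert set(res.contributing_ids) == {"Gao2015a", "Zhou2013a", "Zhou2013b"}
        assert round(res.pooled_or, 2) == 1.20

    def test_rs1563828_homozygote(self, table1):
        res = pool(table1, "rs1563828", "homozygote")
        assert round(res.pooled_or, 2) == 0.86
        assert round(res.p, 3) == 0.566

    def test_unknown_snp_raises(self, table1):
        with pytest.raises(ValueError, match="rs000"):
            pool(table1, "rs000", "allele")

    def test_haldane_policy_keeps_all_asian_recessive_studies(self, asian_rs4245739):
        res = pool(asian_rs4245739, "rs4245739", "recessive", zero_policy="haldane")
        assert res.k == 7
        assert res.excluded_ids == ()


class TestSubgroupPool:
    def test_ethnicity_subgroups(self, table1):
        groups = subgroup_pool(table1, "rs4245739", "allele", by="ethnicity")
        assert set(groups) == {"Asian", "Caucasian"}
        assert round(groups["Asian"].pooled_or, 2) == 0.53
        assert groups["Asian"].k == 7
        assert groups["Caucasian"] is not None  # present though incomplete source

    def test_single_group_matches_plain_pool(self, asian_rs4245739):
        groups = subgroup_pool(asian_rs4245739, "rs4245739", "allele", by="ethnicity")
        plain = pool(asian_rs4245739, "rs4245739", "allele")
        assert groups["Asian"].pooled_or == pytest.approx(plain.pooled_or, rel=1e-12)

    def test_singleton_groups_equal_their_study_estimate(self, table1):
        groups = subgroup_pool(table1, "rs1563828", "allele", by="cancer_type")
        assert len(groups) == 2
        for res in groups.values():
            assert res.k == 1
            assert res.q == 0.0

    def test_unknown_field_raises(self, table1):
        with pytest.raises(KeyError):
            subgroup_pool(table1, "rs1563828", "allele", by="blood_type")


class TestLeaveOneOut:
    def test_two_study_identity(self, table1):
        results = dict(leave_one_out(table1, "rs1563828", "allele"))
        # omitting Zhang leaves Song's own estimate and vice versa
        assert set(results) == {"Zhang2012", "Song2012"}
        for omitted, res in results.items():
            assert res.k == 1
            remaining = ({"Zhang2012", "Song2012"} - {omitted}).pop()
            assert res.contributing_ids == (remaining,)

    def test_asian_allele_all_subsets_stay_protective(self, asian_rs4245739):
        results = leave_one_out(asian_rs4245739, "rs4245739", "allele")
        assert len(results) == 7
        for _, res in results:
            assert res.pooled_or < 1.0
            assert res.ci_high < 1.0  # CI excludes the null in every subset

    def test_single_study_raises(self, table1):
        from snpmeta import StudyTable, filter_table
        single = filter_table(table1, {"study_id": "Zhang2012"})
        with pytest.raises(ValueError):
            leave_one_out(single, "rs1563828", "allele")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestMetaforCrossCheck:
    """Independent oracle: the same pool computed by R's metafor package."""

    def test_fixed_effect_pool_matches_metafor(self, table1, tmp_path):
        res = pool(table1, "rs1563828", "allele", method="fixed_iv")
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            "d <- escalc(measure='OR', ai=c(133,85), bi=c(287,163),"
            " ci=c(132,71), di=c(268,131))\n"
            "f <- rma(yi, vi, data=d, method='FE')\n"
            "cat(sprintf('%.10f %.10f %.10f\\n', as.numeric(f$b), f$se, f$QE))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        b, se, qe = map(float, out.stdout.split())
        assert res.log_or == pytest.approx(b, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        assert res.q == pytest.approx(qe, abs=1e-8)
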