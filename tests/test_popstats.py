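"""Heterozygosity, Weir-Cockerham F-statistics, F_ST categories, t-test."""
import numpy as np
import pytest

from colonykin import (
    ColonyConfig,
    classify_fst,
    f_statistics,
    heterozygosity,
    make_population_model,
    one_sample_ttest,
    simulate_study,
)
from colonykin.popstats import PopStatsError
from conftest import make_table


def singles_study(model, n_per_site, seed):
    design = {s: [ColonyConfig(n_workers=1)] * n_per_site for s in model.site_names}
    return simulate_study(model, design, seed=seed)


class TestHeterozygosity:
    def test_all_homozygotes(self):
        t = make_table(
            [(f"w{i}", "c", "K", "worker", 2, {"L01": (1, 1)}) for i in range(4)], ["L01"]
        )
        assert heterozygosity(t).ho == 0.0

    def test_single_heterozygote_unbiased_formula(self):
        # n = 1, p = (0.5, 0.5): He = (2/1) * (1 - 0.5) = 1
        t = make_table([("w", "c", "K", "worker", 2, {"L01": (1, 2)})], ["L01"])
        h = heterozygosity(t)
        assert h.ho == 1.0 and h.he == pytest.approx(1.0)

    def test_haploids_do_not_contribute(self):
        t = make_table(
            [
                ("w", "c", "K", "worker", 2, {"L01": (1, 2)}),
                ("m", "c", "K", "male", 1, {"L01": (3,)}),
            ],
            ["L01"],
        )
        assert heterozygosity(t).per_locus.loc["L01", "n"] == 1


class TestWeirCockerham:
    def test_null_theta_near_zero(self):
        thetas = []
        for i in range(8):
            m = make_population_model(12, 20, n_sites=2, divergence=0.0, seed=500 + i)
            st = singles_study(m, 40, seed=500 + i)
            thetas.append(f_statistics(st.table, "site").theta)
        assert abs(np.mean(thetas)) < 0.01

    def test_theta_monotone_in_simulated_divergence(self):
        means = []
        for F in (0.02, 0.05, 0.1, 0.2):
            vals = []
            for i in range(6):
                m = make_population_model(
                    12, 20, n_sites=2, divergence=F, seed=600 + i
                )
                st = singles_study(m, 40, seed=700 + i)
                vals.append(f_statistics(st.table, "site").theta)
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_fis_near_zero_under_random_mating(self, model12x20):
        st = singles_study(model12x20, 200, seed=8)
        ps = f_statistics(st.table, "site")
        assert abs(ps.fis) < 0.05
        assert ps.theta is None  # single population: no among-site component

    def test_sib_mating_produces_positive_fis(self, model12x20):
        # offspring of sister x brother matings: inbreeding coefficient 1/4
        rng = np.random.default_rng(9)
        labels, p = model12x20.allele_labels, model12x20.site_frequencies[0]
        rows = []
        for i in range(200):
            calls = {}
            for l, locus in enumerate(model12x20.loci):
                q = rng.choice(labels[l], size=2, p=p[l])       # grandmother
                f = rng.choice(labels[l], p=p[l])               # grandfather
                dam = (q[rng.integers(2)], f)                   # their daughter
                sire = q[rng.integers(2)]                       # their son
                calls[locus] = (int(dam[rng.integers(2)]), int(sire))
            rows.append((f"w{i}", f"c{i}", "K", "worker", 2, calls))
        t = make_table(rows, list(model12x20.loci))
        ps = f_statistics(t, "site")
        assert ps.fis > 0.1
        h = heterozygosity(t)
        assert h.he > h.ho

    def test_theta_invariant_to_relabeling_and_symmetric(self):
        m = make_population_model(4, 6, n_sites=3, divergence=0.1, seed=77)
        st = singles_study(m, 25, seed=77)
        ps = f_statistics(st.table, "site")
        fst = ps.pairwise_fst
        for a in ps.populations:
            for b in ps.populations:
                if a != b:
                    assert fst.loc[a, b] == fst.loc[b, a]
        # relabel alleles by an order-breaking bijection: theta unchanged
        relabeled = st.table.alleles.copy()
        relabeled[relabeled > 0] = 1000 - relabeled[relabeled > 0]
        t2 = type(st.table)(st.table.meta, st.table.loci, relabeled)
        assert f_statistics(t2, "site").theta == pytest.approx(ps.theta)

    def test_undersized_population_rejected(self):
        t = make_table(
            [
                ("a", "c1", "K", "worker", 2, {"L01": (1, 2)}),
                ("b", "c2", "S", "worker", 2, {"L01": (1, 3)}),
                ("c", "c3", "S", "worker", 2, {"L01": (2, 3)}),
            ],
            ["L01"],
        )
        with pytest.raises(PopStatsError, match="K"):
            f_statistics(t, "site")


class TestFstClassification:
    @pytest.mark.parametrize(
        "value,category",
        [
            (-0.01, "low"),
            (0.02, "low"),
            (0.0499, "low"),
            (0.05, "medium"),
            (0.10, "medium"),
            (0.1499, "medium"),
            (0.15, "high"),
            (0.25, "high"),
            (0.2500001, "very_high"),
            (0.63, "very_high"),
        ],
    )
    def test_threshold_semantics(self, value, category):
        assert classify_fst(value) == category

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_fst(float("nan"))


class TestOneSampleTTest:
    def test_symmetric_sample_gives_t_zero(self):
        res = one_sample_ttest([0.70, 0.75, 0.80], 0.75)
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_degenerate_sample_equal_to_mu(self):
        res = one_sample_ttest([0.75, 0.75, 0.75], 0.75)
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_away_from_mu_rejected(self):
        with pytest.raises(PopStatsError):
            one_sample_ttest([0.8, 0.8, 0.8], 0.75)

    def test_published_scale_p_value(self):
        # n = 29 sample built to have mean 0.77 and t = 0.333 against 0.75:
        # the two-sided p from the t distribution (df = 28) prints as 0.741
        n, mu, mean, t_target = 29, 0.75, 0.77, 0.333
        sd = (mean - mu) * np.sqrt(n) / t_target
        base = np.arange(n, dtype=float)
        base = (base - base.mean()) / base.std(ddof=1)
        values = mean + sd * base
        res = one_sample_ttest(values, mu)
        assert res.t == pytest.approx(0.333, abs=1e-9)
        assert res.df == 28
        assert res.p == pytest.approx(0.741, abs=1e-3)

    def test_matches_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x = rng.normal(0.7, 0.1, 20)
        res = one_sample_ttest(x, 0.75)
        ref = stats.ttest_1samp(x, 0.75)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
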