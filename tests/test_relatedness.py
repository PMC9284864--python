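"""Allele frequencies, Queller-Goodnight and ML relatedness estimators."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colonykin import (
    AlleleFrequencies,
    ColonyConfig,
    estimate_allele_frequencies,
    mean_within_group_relatedness,
    ml_pairwise,
    qg_pairwise,
    simulate_colony,
)
from colonykin.relatedness import FrequencyError, pair_mode_probabilities
from conftest import make_table

ABC = AlleleFrequencies({"L01": {1: 0.5, 2: 0.25, 3: 0.25}}, provenance="fixed")


def geno(call):
    return {"L01": call}


class TestAlleleFrequencies:
    def test_diploid_counting(self):
        t = make_table(
            [
                ("a", "c", "K", "worker", 2, {"L01": (1, 1)}),
                ("b", "c", "K", "worker", 2, {"L01": (1, 2)}),
            ],
            ["L01"],
        )
        f = estimate_allele_frequencies(t)
        assert f.frequencies["L01"] == {1: 0.75, 2: 0.25}

    def test_mixed_ploidy_copy_counting(self):
        t = make_table(
            [
                ("m", "c", "K", "male", 1, {"L01": (1,)}),
                ("w", "c", "K", "worker", 2, {"L01": (2, 2)}),
            ],
            ["L01"],
        )
        f = estimate_allele_frequencies(t)
        assert f.frequencies["L01"] == pytest.approx({1: 1 / 3, 2: 2 / 3})

    def test_locus_without_data_raises(self):
        t = make_table([("a", "c", "K", "worker", 2, {"L01": None})], ["L01"])
        with pytest.raises(FrequencyError, match="L01"):
            estimate_allele_frequencies(t)

    def test_unseen_allele_floored_and_renormalised(self):
        f = AlleleFrequencies({"L01": {1: 1.0}}, n_reference=10)
        p = f.locus_frequencies("L01", observed=(1, 7))
        assert p[7] == pytest.approx(1 / 21)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_per_colony_one_worker_selector_recovers_uniform(self, model12x20):
        from colonykin import simulate_study

        design = {"site1": [ColonyConfig(n_workers=4)] * 250}
        study = simulate_study(model12x20, design, seed=3)
        f = estimate_allele_frequencies(study.table, "per-colony-one-worker", seed=5)
        p = np.array(list(f.frequencies["L01"].values()))
        assert abs(p.max() - 0.05) < 0.03 and abs(p.min() - 0.05) < 0.03


class TestQuellerGoodnight:
    def test_self_identity(self):
        est = qg_pairwise(geno((1, 2)), geno((1, 2)), ABC)
        assert est.defined and est.r == pytest.approx(1.0)

    def test_hand_computed_negative_pair(self):
        # x={A,B}, y={A,C}, p=(0.5,0.25,0.25): both directions give -0.25/0.25
        est = qg_pairwise(geno((1, 2)), geno((1, 3)), ABC)
        assert est.r == pytest.approx(-1.0)
        assert est.per_locus["L01"] == (pytest.approx(-0.5), pytest.approx(0.5))

    def test_zero_denominator_is_signalled_not_raised(self):
        # both heterozygous {A,B} at p = (0.5, 0.5): numerator and denominator
        # vanish in every direction
        f = AlleleFrequencies({"L01": {1: 0.5, 2: 0.5}})
        est = qg_pairwise(geno((1, 2)), geno((1, 2)), f)
        assert not est.defined and np.isnan(est.r)

    def test_haploid_enters_as_pseudo_homozygote(self):
        est_h = qg_pairwise(geno((1,)), geno((1, 2)), ABC)
        est_d = qg_pairwise(geno((1, 1)), geno((1, 2)), ABC)
        assert est_h.r == pytest.approx(est_d.r)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_property(self, data):
        k = data.draw(st.integers(3, 6))
        raw = data.draw(st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k))
        p = np.array(raw) / np.sum(raw)
        freqs = AlleleFrequencies({"L01": {i + 1: float(x) for i, x in enumerate(p)}})
        gx = tuple(sorted(data.draw(st.tuples(st.integers(1, k), st.integers(1, k)))))
        gy = tuple(sorted(data.draw(st.tuples(st.integers(1, k), st.integers(1, k)))))
        a = qg_pairwise(geno(gx), geno(gy), freqs)
        b = qg_pairwise(geno(gy), geno(gx), freqs)
        if a.defined:
            assert a.r == pytest.approx(b.r, abs=1e-12)
        else:
            assert not b.defined

    def test_full_sister_calibration(self, model12x20, true_freqs):
        vals = []
        for s in np.random.SeedSequence(61).spawn(120):
            tbl, _ = simulate_colony(model12x20, 0, ColonyConfig(n_workers=8), seed=s)
            gs = [tbl.genotype(i) for i in tbl.ids]
            vals.extend(
                qg_pairwise(gs[a], gs[b], true_freqs).r
                for a, b in itertools.combinations(range(8), 2)
            )
        assert abs(np.mean(vals) - 0.75) < 0.02

    def test_queen_daughter_calibration(self, model12x20, true_freqs):
        vals = []
        cfg = ColonyConfig(n_workers=2, include_queen_genotype=True)
        for i, s in enumerate(np.random.SeedSequence(62).spawn(400)):
            tbl, _ = simulate_colony(model12x20, 0, cfg, seed=s, colony_id=f"c{i}")
            vals.append(
                qg_pairwise(tbl.genotype(f"c{i}_q1"), tbl.genotype(f"c{i}_w1"), true_freqs).r
            )
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_unrelated_pairs_centre_on_zero(self, model12x20, true_freqs):
        vals = []
        for i, s in enumerate(np.random.SeedSequence(63).spawn(300)):
            tbl, _ = simulate_colony(
                model12x20, 0, ColonyConfig(n_workers=2, n_aliens=1), seed=s
            )
            # w1 is the queen's offspring, w2 the alien: unrelated
            vals.append(qg_pairwise(tbl.genotype(tbl.ids[0]), tbl.genotype(tbl.ids[1]), true_freqs).r)
        assert abs(np.mean(vals)) < 0.02


class TestGroupRelatedness:
    def test_identical_heterozygotes(self):
        t = make_table(
            [
                ("a", "c", "K", "worker", 2, {"L01": (1, 2)}),
                ("b", "c", "K", "worker", 2, {"L01": (1, 2)}),
            ],
            ["L01"],
        )
        g = mean_within_group_relatedness(t, "c", ABC)
        assert g.mean == pytest.approx(1.0) and g.n_pairs == 1

    def test_single_member_group_rejected(self):
        t = make_table([("a", "c", "K", "worker", 2, {"L01": (1, 2)})], ["L01"])
        with pytest.raises(ValueError):
            mean_within_group_relatedness(t, "c", ABC)

    def test_skewed_polyandrous_colony_mean(self, model12x20, true_freqs):
        # 14:2 patrilines: pair-weighted mean of full-sister (r=0.75, 92 pairs)
        # and paternal half-sister (r=0.25, 28 pairs) expectations = 0.6333
        cfg = ColonyConfig(n_workers=16, n_fathers_per_queen=2, paternity_counts=(14, 2))
        means = [
            mean_within_group_relatedness(
                simulate_colony(model12x20, 0, cfg, seed=s, colony_id="c")[0], "c", true_freqs
            ).mean
            for s in np.random.SeedSequence(64).spawn(80)
        ]
        assert abs(np.mean(means) - (92 * 0.75 + 28 * 0.25) / 120) < 0.02


class TestMaximumLikelihood:
    def test_mode_probabilities_are_joint_distributions(self):
        # each IBD mode defines a distribution over unordered genotype pairs
        p = {1: 0.5, 2: 0.3, 3: 0.2}
        pairs = list(itertools.combinations_with_replacement(p, 2))
        totals = np.zeros(3)
        for gx in pairs:
            for gy in pairs:
                totals += pair_mode_probabilities(gx, gy, p)
        assert totals == pytest.approx(np.ones(3))

    def test_disjoint_pair_is_unrelated(self):
        f = AlleleFrequencies({f"L{i}": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25} for i in range(12)})
        gx = {f"L{i}": (1, 2) for i in range(12)}
        gy = {f"L{i}": (3, 4) for i in range(12)}
        res = ml_pairwise(gx, gy, f)
        assert res.k0 > 0.99 and res.r < 0.01

    def test_shared_rare_homozygotes_force_high_r(self):
        f = AlleleFrequencies(
            {f"L{i}": {1: 0.05, **{j: 0.95 / 19 for j in range(2, 21)}} for i in range(10)}
        )
        g = {f"L{i}": (1, 1) for i in range(10)}
        res = ml_pairwise(g, g, f)
        assert res.r >= 0.9

    def test_r_bounded_and_simplex(self, model12x20, true_freqs):
        rng_pairs = []
        for s in np.random.SeedSequence(65).spawn(20):
            tbl, _ = simulate_colony(model12x20, 0, ColonyConfig(n_workers=2), seed=s)
            rng_pairs.append((tbl.genotype(tbl.ids[0]), tbl.genotype(tbl.ids[1])))
        for gx, gy in rng_pairs:
            res = ml_pairwise(gx, gy, true_freqs)
            assert 0.0 <= res.r <= 1.0
            assert res.k0 + res.k1 + res.k2 == pytest.approx(1.0, abs=1e-9)
            back = ml_pairwise(gy, gx, true_freqs)
            assert back.r == pytest.approx(res.r, abs=1e-9)

    def test_refinement_dominates_grid(self, model12x20, true_freqs):
        for s in np.random.SeedSequence(66).spawn(10):
            tbl, _ = simulate_colony(model12x20, 0, ColonyConfig(n_workers=2), seed=s)
            gx, gy = (tbl.genotype(i) for i in tbl.ids)
            coarse = ml_pairwise(gx, gy, true_freqs, refine=False)
            fine = ml_pairwise(gx, gy, true_freqs, refine=True)
            assert fine.log_likelihood >= coarse.log_likelihood - 1e-9

    def test_sister_pairs_near_three_quarters(self, model12x20, true_freqs):
        vals = []
        for s in np.random.SeedSequence(67).spawn(150):
            tbl, _ = simulate_colony(model12x20, 0, ColonyConfig(n_workers=2), seed=s)
            vals.append(ml_pairwise(tbl.genotype(tbl.ids[0]), tbl.genotype(tbl.ids[1]), true_freqs).r)
        assert abs(np.mean(vals) - 0.75) < 0.04
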