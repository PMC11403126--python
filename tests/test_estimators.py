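"""Breeder-number estimator and reproductive-statistic tests."""

import numpy as np
import pytest

import kinbreed as kb
from kinbreed.estimators import (coancestry, nb_ld, nb_sibship, ns_chao,
                                 offspring_per_parent, pairwise_r2_matrix,
                                 rarefied_rs, theta_from_counts)
from kinbreed.kinship import (InferredPedigree, SibshipPartition,
                              true_inferred, true_sibship)
from kinbreed.matrix import MISSING

from conftest import make_matrix


def partition_from_counts(q_fs, q_hs, n=100):
    """Synthetic partition with given pair frequencies (approximately)."""
    part = SibshipPartition(families=[[f"x{i}"] for i in range(n)],
                            hs_edges={})
    part.q_fs, part.q_hs = q_fs, q_hs
    return part


class TestNbSibship:
    def test_single_monogamous_pair(self):
        part = SibshipPartition(families=[[f"o{i}" for i in range(10)]])
        part.q_fs, part.q_hs = 1.0, 0.0
        nb = nb_sibship(part, n_boot=10, seed=0)
        assert nb.point == pytest.approx(2.0)

    def test_half_sib_only(self):
        nb = nb_sibship(partition_from_counts(0.0, 0.5), n_boot=10, seed=0)
        assert nb.point == pytest.approx(8.0)

    def test_no_sibs_gives_infinity(self):
        part = SibshipPartition(families=[["a"], ["b"], ["c"]])
        part.q_fs = part.q_hs = 0.0
        nb = nb_sibship(part, n_boot=20, seed=0)
        assert np.isinf(nb.point)
        assert np.isfinite(nb.ci[0])

    def test_recovers_ne_50(self):
        """Point estimate within 20% of Ne = 4NmNf/(Nm+Nf) = 50 for a
        25 x 25 random-mating pedigree with 300 offspring."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(400 + rep)
            ped = kb.simulate_random_mating(25, 25, 300, rng)
            nb = nb_sibship(true_sibship(ped), n_boot=20, seed=rep)
            hits += abs(nb.point - 50) / 50 <= 0.2
        assert hits >= 16

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(1)
        part = true_sibship(kb.simulate_random_mating(10, 10, 80, rng))
        a = nb_sibship(part, n_boot=100, seed=7)
        b = nb_sibship(part, n_boot=100, seed=7)
        assert a.ci == b.ci


class TestNbLd:
    def test_matches_brute_force_r2(self):
        """Vectorized mean r^2 equals a direct double loop over locus
        pairs (pairwise-complete individuals) to 1e-10."""
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
        g[rng.uniform(size=g.shape) < 0.1] = MISSING
        r2, n = pairwise_r2_matrix(g)
        for a in range(0, 30, 7):
            for b in range(a + 1, 30, 5):
                both = (g[:, a] != MISSING) & (g[:, b] != MISSING)
                x, y = g[both, a].astype(float), g[both, b].astype(float)
                if len(x) < 2 or x.std() == 0 or y.std() == 0:
                    assert np.isnan(r2[a, b])
                else:
                    expect = np.corrcoef(x, y)[0, 1] ** 2
                    assert r2[a, b] == pytest.approx(expect, abs=1e-10)

    def test_single_chromosome_is_error(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        gm = make_matrix(g, chroms=["chr1"] * 10)
        with pytest.raises(ValueError, match="single"):
            nb_ld(gm)

    def test_recovers_ideal_population(self):
        """Nb within a factor 1.5 of 50 on an equilibrium drift
        population (25 dams x 25 sires), S=100, 500 unlinked loci."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            gm = kb.simulate_drift_population(25, 25, 500, 100, rng)
            nb = nb_ld(gm)
            hits += 50 / 1.5 <= nb.point <= 50 * 1.5
        assert hits >= 8

    def test_null_limit_infinite(self):
        # independent loci, no drift LD: r2' hovers at 0 -> huge/infinite Nb
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.2, 0.5, 200)
        g = rng.binomial(2, freqs, size=(500, 200)).astype(np.int8)
        gm = make_matrix(g, chroms=[f"chr{j % 10}" for j in range(200)])
        nb = nb_ld(gm)
        assert nb.point > 500 or np.isinf(nb.point)


class TestNsChao:
    def test_no_singletons_no_correction(self):
        # every parent seen in >= 3 offspring: estimate equals observed
        off = {f"o{i}": (f"D{i % 3}", f"S{i % 3}") for i in range(9)}
        ped = InferredPedigree(offspring=off,
                               slot_offspring={"D0": 3, "D1": 3, "D2": 3,
                                               "S0": 3, "S1": 3, "S2": 3})
        est = ns_chao(ped, n_orderings=10, seed=0)
        assert est.a1 == 0 and est.a2 == 0
        assert est.chao == est.ns

    def test_formula_spot_check(self):
        """Ns=10, a1=4, a2=1, m=100 gives the bias-corrected Chao2 value
        10 + (99/100) * (4*3) / (2*2) = 12.97."""
        # 100 offspring over 10 parents: 4 singles, 1 double, rest heavy.
        # Build an explicit incidence pattern matching those counts.
        off = {}
        parents = [f"P{k}" for k in range(10)]
        # parents P0..P3 in exactly 1 offspring, P4 in exactly 2
        quota = [1, 1, 1, 1, 2] + [200] * 5
        counts = {p: 0 for p in parents}
        k = 0
        for i in range(100):
            pair = []
            for _ in range(2):
                while counts[parents[k]] >= quota[k]:
                    k = (k + 1) % 10
                p = parents[k]
                # avoid duplicate slot within one offspring
                if pair and p == pair[0]:
                    k2 = (k + 1) % 10
                    while counts[parents[k2]] >= quota[k2] or parents[k2] == pair[0]:
                        k2 = (k2 + 1) % 10
                    p = parents[k2]
                pair.append(p)
                counts[p] += 1
            off[f"o{i:03d}"] = tuple(pair)
        ped = InferredPedigree(offspring=off, slot_offspring=counts)
        est = ns_chao(ped, n_orderings=5, seed=0)
        assert (est.ns, est.a1, est.a2, est.m) == (10, 4, 1, 100)
        assert est.chao == pytest.approx(12.97, abs=0.005)

    def test_curve_monotone_and_chao_at_least_observed(self):
        rng = np.random.default_rng(5)
        ped = true_inferred(kb.simulate_random_mating(15, 5, 60, rng))
        est = ns_chao(ped, n_orderings=30, seed=1)
        assert est.chao >= est.ns
        assert np.all(np.diff(est.curve) >= -1e-12)
        assert est.curve[-1] == est.ns

    def test_unsaturated_curve_under_skew(self):
        """With many true parents barely sampled, the accumulation curve
        is still rising at the full sample and Chao exceeds observed."""
        rng = np.random.default_rng(6)
        ped = true_inferred(kb.simulate_random_mating(60, 60, 50, rng))
        est = ns_chao(ped, n_orderings=30, seed=2)
        assert est.chao > est.ns
        assert est.curve[-1] - est.curve[-6] > 0  # final slope positive


class TestRarefiedRS:
    def test_all_unique_parents_rs_one(self):
        off = {f"o{i}": (f"D{i}", f"S{i}") for i in range(80)}
        counts = {s: 1 for pair in off.values() for s in pair}
        ped = InferredPedigree(offspring=off, slot_offspring=counts)
        rs = rarefied_rs(ped, n_sub=75, reps=50, seed=0)
        assert rs.mean == 1.0 and rs.sd == 0.0

    def test_single_pair_rs_equals_subsample(self):
        off = {f"o{i}": ("D0", "S0") for i in range(80)}
        ped = InferredPedigree(offspring=off,
                               slot_offspring={"D0": 80, "S0": 80})
        rs = rarefied_rs(ped, n_sub=75, reps=20, seed=0)
        assert rs.mean == 75.0

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(7)
        ped = true_inferred(kb.simulate_random_mating(20, 20, 100, rng))
        a = rarefied_rs(ped, n_sub=75, reps=200, seed=3)
        b = rarefied_rs(ped, n_sub=75, reps=200, seed=3)
        assert (a.mean, a.sd, a.ci) == (b.mean, b.sd, b.ci)
        assert a.ci[0] <= a.mean <= a.ci[1]

    def test_too_few_offspring_raises(self):
        ped = InferredPedigree(offspring={"o1": ("D", "S")},
                               slot_offspring={"D": 1, "S": 1})
        with pytest.raises(ValueError, match="n_sub"):
            rarefied_rs(ped, n_sub=75, reps=10, seed=0)


class TestCoancestry:
    def test_all_full_sibs(self):
        part = SibshipPartition(families=[[f"o{i}" for i in range(6)]])
        assert coancestry(part).theta == pytest.approx(0.25)

    def test_all_unrelated(self):
        part = SibshipPartition(families=[[f"o{i}"] for i in range(6)])
        assert coancestry(part).theta == 0.0

    def test_formula_arithmetic(self):
        assert theta_from_counts(10, 10, 80) == pytest.approx(0.0375)

    def test_counts_partition_all_pairs(self):
        rng = np.random.default_rng(8)
        part = true_sibship(kb.simulate_random_mating(10, 10, 50, rng))
        res = coancestry(part)
        assert res.n_fs + res.n_hs + res.n_u == 50 * 49 // 2


class TestOffspringPerParent:
    @pytest.mark.parametrize("n_off,ns,expect", [
        (118, 113, 2.088), (147, 41, 7.171), (50, 100, 1.0)])
    def test_values(self, n_off, ns, expect):
        assert offspring_per_parent(n_off, ns) == pytest.approx(expect,
                                                                abs=5e-3)

    def test_zero_parents_rejected(self):
        with pytest.raises(ValueError):
            offspring_per_parent(10, 0)
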