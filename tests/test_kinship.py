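"""Kinship, classification, sibship, parent-slot, and paternity tests."""

import numpy as np
import pandas as pd
import pytest

import kinbreed as kb
from kinbreed.kinship import (build_sibship, classify_pair, classify_pairs,
                              count_sires, infer_parents, king_matrix,
                              king_phi, true_inferred, true_sibship)
from kinbreed.matrix import MISSING
from kinbreed.simulate import simulate_clutch, _locus_table

from conftest import make_matrix


def hwe_genotypes(rng, n, freqs):
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)


def add_error(g, eps, rng):
    down = rng.binomial(g, eps)
    up = rng.binomial(2 - g, eps)
    return np.clip(g - down + up, 0, 2).astype(np.int8)


class TestKingPhi:
    def test_self_kinship_is_half(self):
        rng = np.random.default_rng(0)
        g = hwe_genotypes(rng, 1, np.full(500, 0.3))[0]
        assert king_phi(g, g) == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g = hwe_genotypes(rng, 2, rng.uniform(0.05, 0.5, 300))
        assert king_phi(g[0], g[1]) == king_phi(g[1], g[0])

    def test_unrelated_pairs_near_zero(self):
        rng = np.random.default_rng(2)
        g = hwe_genotypes(rng, 40, np.full(2000, 0.3))
        phi = king_matrix(g)
        iu = np.triu_indices(40, 1)
        assert np.all(np.abs(phi[iu]) < 0.03 + 3 * phi[iu].std())
        assert abs(phi[iu].mean()) < 0.03

    def test_parent_offspring_quarter(self):
        rng = np.random.default_rng(3)
        freqs = np.full(2000, 0.3)
        dams = hwe_genotypes(rng, 30, freqs)
        sires = hwe_genotypes(rng, 30, freqs)
        kids = np.empty_like(dams)
        for i in range(30):
            kids[i] = kb.simulate.mendelian_drop(dams[i], sires[i],
                                                 np.random.default_rng(100 + i))
        vals = [king_phi(dams[i], kids[i]) for i in range(30)]
        assert abs(np.mean(vals) - 0.25) < 0.03

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(4)
        g = hwe_genotypes(rng, 8, rng.uniform(0.1, 0.5, 200))
        g[g > 5] = MISSING  # no-op, keep dtype
        g[rng.uniform(size=g.shape) < 0.1] = MISSING
        phi = king_matrix(g)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = king_phi(g[i], g[j])
                if np.isnan(expect):
                    assert np.isnan(phi[i, j])
                else:
                    assert phi[i, j] == pytest.approx(expect)


class TestClassification:
    def test_opposing_homozygotes_reject_close_kin(self):
        # many AA vs aa loci: full sibs are overwhelmingly unlikely
        L = 200
        g = np.zeros((2, L), dtype=np.int8)
        g[1, :] = 2
        gm = make_matrix(g, tags=[f"t{j}" for j in range(L)])
        call = classify_pair(gm, 0, 1,
                             allele_freqs=np.full(L, 0.5), eps=0.01,
                             min_shared_loci=50)
        assert call.assigned == "U"
        assert call.loglik["U"] > call.loglik["FS"]
        assert call.loglik["U"] > call.loglik["PO"]

    def test_identical_genotypes_called_full_sib(self):
        rng = np.random.default_rng(5)
        L = 400
        g0 = hwe_genotypes(rng, 1, np.full(L, 0.4))[0]
        gm = make_matrix(np.vstack([g0, g0]),
                         tags=[f"t{j}" for j in range(L)])
        call = classify_pair(gm, 0, 1, allele_freqs=np.full(L, 0.4),
                             eps=0.01, min_shared_loci=50)
        # the k2-heavy class dominates for identical genotype vectors
        assert call.assigned == "FS"
        assert call.loglik["FS"] > call.loglik["U"]

    def test_fs_vs_unrelated_accuracy(self):
        """>= 95% of simulated full-sib and unrelated pairs are assigned
        correctly at 500 loci with 1% genotyping error."""
        rng = np.random.default_rng(6)
        L = 500
        freqs = rng.uniform(0.05, 0.5, L)
        n_pairs = 150
        rows = []
        truth = []
        for k in range(n_pairs):
            dam = rng.binomial(2, freqs).astype(np.int8)
            sire = rng.binomial(2, freqs).astype(np.int8)
            a = kb.simulate.mendelian_drop(dam, sire, rng)
            b = kb.simulate.mendelian_drop(dam, sire, rng)
            rows += [a, b]
            truth.append("FS")
        for k in range(n_pairs):
            rows += list(hwe_genotypes(rng, 2, freqs))
            truth.append("U")
        g = add_error(np.vstack(rows), 0.01, rng)
        gm = make_matrix(g, tags=[f"t{j}" for j in range(L)])
        pairs = [(2 * k, 2 * k + 1) for k in range(2 * n_pairs)]
        calls = classify_pairs(gm, pairs, allele_freqs=freqs, eps=0.01)
        pred = ["FS" if a in ("FS", "PO") else a
                for a in calls["assigned"]]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.95

    def test_uncallable_below_min_shared(self):
        g = np.array([[0, 1, 2, MISSING], [MISSING, 1, 0, 1]], dtype=np.int8)
        gm = make_matrix(g)
        calls = classify_pairs(gm, [(0, 1)], eps=0.01, min_shared_loci=100)
        assert calls["assigned"].iloc[0] == "uncallable"

    def test_finite_loglik_with_error(self):
        # opposing homozygotes under PO have probability zero only at eps=0
        g = np.array([[0] * 120, [2] * 120], dtype=np.int8)
        gm = make_matrix(g)
        calls = classify_pairs(gm, [(0, 1)],
                               allele_freqs=np.full(120, 0.5), eps=0.01,
                               min_shared_loci=50)
        assert np.isfinite(calls[["ll_U", "ll_HS", "ll_FS", "ll_PO"]]
                           .to_numpy()).all()


def _calls_from_classes(classes: dict, margin=5.0):
    rows = []
    for (a, b), v in classes.items():
        rows.append({"i": 0, "j": 0, "id_i": a, "id_j": b,
                     "ll_U": 0.0, "ll_HS": 0.0, "ll_FS": 0.0, "ll_PO": 0.0,
                     "n_shared": 500, "assigned": v,
                     "margin": margin if not isinstance(margin, dict)
                     else margin[(a, b)]})
    return pd.DataFrame(rows)


class TestBuildSibship:
    def test_all_unrelated_gives_singletons(self):
        classes = {(a, b): "U" for a, b in
                   [("x", "y"), ("x", "z"), ("y", "z")]}
        part = build_sibship(_calls_from_classes(classes))
        assert sorted(map(len, part.families)) == [1, 1, 1]
        assert part.q_fs == 0 and part.q_hs == 0

    def test_triangle_of_full_sibs(self):
        classes = {(a, b): "FS" for a, b in
                   [("x", "y"), ("x", "z"), ("y", "z")]}
        part = build_sibship(_calls_from_classes(classes))
        assert len(part.families) == 1
        assert part.q_fs == 1.0

    def test_transitivity_repair_drops_weakest_edge(self):
        # x-y FS (weak), y-z FS (strong), x-z U: drop x-y
        classes = {("x", "y"): "FS", ("y", "z"): "FS", ("x", "z"): "U"}
        margins = {("x", "y"): 1.0, ("y", "z"): 9.0, ("x", "z"): 9.0}
        part = build_sibship(_calls_from_classes(classes, margins))
        fams = {tuple(f) for f in part.families}
        assert ("y", "z") in fams and ("x",) in fams

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        cfg = kb.SimConfig(n_males=10, n_females=10, n_loci=400, seed=30)
        ped = kb.simulate_breeding(cfg)
        gm = kb.simulate_genotypes(ped, cfg)
        juv = gm.select_ids(list(ped.offspring["id"]))
        calls = classify_pairs(juv, eps=0.01)
        p1 = build_sibship(calls)
        p2 = build_sibship(calls.sample(frac=1.0, random_state=1))
        assert p1.families == p2.families
        assert p1.hs_edges.keys() == p2.hs_edges.keys()

    def test_partition_recovery_ari(self):
        """Partition matches truth (ARI >= 0.95) on 20 families x 5
        offspring at 500 loci and 1% error."""
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(8)
        L = 500
        freqs = rng.uniform(0.05, 0.5, L)
        rows, labels, ids = [], [], []
        for fam in range(20):
            dam = rng.binomial(2, freqs).astype(np.int8)
            sire = rng.binomial(2, freqs).astype(np.int8)
            for k in range(5):
                rows.append(kb.simulate.mendelian_drop(dam, sire, rng))
                labels.append(fam)
                ids.append(f"f{fam:02d}o{k}")
        g = add_error(np.vstack(rows), 0.01, rng)
        gm = make_matrix(g, ids=ids, tags=[f"t{j}" for j in range(L)])
        calls = classify_pairs(gm, allele_freqs=freqs, eps=0.01)
        part = build_sibship(calls)
        ari = adjusted_rand_score(labels, part.labels(ids))
        assert ari >= 0.95


class TestInferParents:
    def test_two_families_without_hs(self):
        part = kb.SibshipPartition(families=[["a", "b"], ["c", "d"]])
        ped = infer_parents(part)
        assert ped.ns == 4

    def test_one_hs_edge_shares_one_slot(self):
        part = kb.SibshipPartition(families=[["a", "b"], ["c", "d"]],
                                   hs_edges={(0, 1): 3.0})
        ped = infer_parents(part)
        assert ped.ns == 3
        shared = set(ped.offspring["a"]) & set(ped.offspring["c"])
        assert len(shared) == 1
        assert ped.slot_offspring[shared.pop()] == 4

    def test_slot_count_bounds(self):
        """Ns = 2 * #families with no half-sib merges; below that (but
        >= 2) once merging occurs, with any two families sharing at most
        one slot."""
        rng = np.random.default_rng(9)
        ped = kb.simulate_random_mating(8, 8, 60, rng)
        part = true_sibship(ped)
        inf = infer_parents(part)
        nf = len(part.families)
        if part.hs_edges:
            assert 2 <= inf.ns <= 2 * nf - 1
        else:
            assert inf.ns == 2 * nf
        slot_pairs = [set(inf.offspring[f[0]]) for f in part.families]
        for i in range(nf):
            assert len(slot_pairs[i]) == 2  # family slots stay distinct
            for j in range(i + 1, nf):
                assert len(slot_pairs[i] & slot_pairs[j]) <= 1

    def test_recovers_true_parent_count(self):
        """Slot count within 15% of the true number of contributing
        parents on a two-cohort carryover scenario (true partition)."""
        cfg = kb.load_scenario("hotel1_like")
        cfg.seed = 31
        ped = kb.simulate_breeding(cfg)
        part = true_sibship(ped)
        inf = infer_parents(part)
        n_true = len(ped.contributing_parents())
        assert abs(inf.ns - n_true) / n_true <= 0.15


class TestCountSires:
    @staticmethod
    def clutch_matrix(n, shares, L, eps, rng):
        freqs = rng.uniform(0.05, 0.5, L)
        mom, child, sidx = simulate_clutch(n, shares, freqs, rng)
        obs = add_error(child, eps, rng) if eps > 0 else child
        gm = make_matrix(obs, ids=[f"o{i}" for i in range(n)],
                         tags=[f"t{j}" for j in range(L)])
        return mom, gm, sidx, freqs

    def test_single_sire_single_cluster(self):
        rng = np.random.default_rng(10)
        mom, gm, sidx, freqs = self.clutch_matrix(20, (1.0,), 400, 0.0, rng)
        part = count_sires(mom, gm, allele_freqs=freqs, eps=0.01)
        assert part.n_sires == 1

    def test_three_sires_recovered(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            mom, gm, sidx, freqs = self.clutch_matrix(30, (0.6, 0.3, 0.1),
                                                      500, 0.01, rng)
            part = count_sires(mom, gm, allele_freqs=freqs, eps=0.01)
            hits += part.n_sires == len(set(sidx))
        assert hits >= 18

    def test_disjoint_clutches_counted_independently(self):
        rng = np.random.default_rng(12)
        m1, g1, s1, f1 = self.clutch_matrix(15, (0.5, 0.5), 400, 0.0, rng)
        m2, g2, s2, f2 = self.clutch_matrix(15, (1.0,), 400, 0.0, rng)
        p1 = count_sires(m1, g1, allele_freqs=f1, eps=0.01)
        p2 = count_sires(m2, g2, allele_freqs=f2, eps=0.01)
        assert p1.n_sires == len(set(s1))
        assert p2.n_sires == 1

    def test_maternity_suspect_flagged(self):
        rng = np.random.default_rng(13)
        L = 400
        freqs = rng.uniform(0.3, 0.5, L)  # informative opposing-homozygote loci
        mom, child, sidx = simulate_clutch(10, (1.0,), freqs, rng)
        gm = make_matrix(child, ids=[f"o{i}" for i in range(10)],
                         tags=[f"t{j}" for j in range(L)])
        # replace one offspring with an unrelated individual
        gm.dosage[0] = rng.binomial(2, freqs).astype(np.int8)
        part = count_sires(mom, gm, allele_freqs=freqs, eps=0.01)
        assert "o0" in part.suspect
        assert all("o0" not in c for c in part.clusters)


class TestParameterRecovery:
    def test_q_frequencies_within_25pct(self):
        """Inferred Q_FS and Q_HS within 25% relative error of the
        pedigree truth on the default polygamous scenario."""
        cfg = kb.SimConfig(n_males=50, n_females=50, n_loci=930,
                           clutch_size_mean=8.0, error_rate=0.01,
                           missing_rate=0.02, seed=32)
        rng = cfg.rng()
        ped = kb.simulate_breeding(cfg, rng)
        # cap at 400 offspring as in the reference design
        keep = ped.offspring["id"][:400]
        gm = kb.simulate_genotypes(ped, cfg, rng)
        obs = kb.apply_observation_model(gm, cfg, rng)
        juv = obs.select_ids(list(keep))
        calls = classify_pairs(juv, eps=cfg.error_rate)
        part = build_sibship(calls)
        truth = true_sibship(ped, offspring_ids=list(keep))
        assert part.q_fs == pytest.approx(truth.q_fs, rel=0.25)
        assert part.q_hs == pytest.approx(truth.q_hs, rel=0.25)
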