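"""Effective / successful breeder estimators and pedigree-derived
reproductive statistics.

Two effective-number-of-breeders estimators are provided: the
sibship-frequency estimator (Wang-style; Nb = 4 / (2*Q_FS + Q_HS) under
random mating without inbreeding) and the linkage-disequilibrium
estimator (Waples-style; mean squared dosage correlation over
between-chromosome locus pairs, bias-adjusted for sample size).  The
number of successfully breeding adults is reported as the observed count
of reconstructed parental genotypes (Ns) and its Chao2 asymptote from a
parentage accumulation curve.  Rarefied reproductive success and mean
offspring coancestry round out the per-cohort summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import InferredPedigree, SibshipPartition
from .matrix import MISSING, GenotypeMatrix

__all__ = ["NbEstimate", "NsEstimate", "RSResult", "CoancestryResult",
           "nb_sibship", "nb_ld", "ns_chao", "rarefied_rs", "coancestry",
           "theta_from_counts", "offspring_per_parent", "pairwise_r2_matrix"]


@dataclass
class NbEstimate:
    method: str  # "LD" or "sibship"
    point: float  # may be +inf
    ci: tuple[float, float]
    n_offspring: int
    n_used: int  # loci (LD) or pairs (sibship)
    detail: dict = field(default_factory=dict)


@dataclass
class NsEstimate:
    ns: int
    chao: float
    se: float
    a1: int
    a2: int
    m: int
    curve: np.ndarray  # mean distinct parents at offspring subsample 1..m


@dataclass
class RSResult:
    counts: dict[str, int]  # per-parent offspring counts (full data)
    mean: float
    sd: float
    ci: tuple[float, float]
    n_sub: int
    reps: int
    seed: int


@dataclass
class CoancestryResult:
    theta: float
    n_fs: int
    n_hs: int
    n_u: int


# ---------------------------------------------------------------------------
# sibship-frequency Nb
# ---------------------------------------------------------------------------

def _wang_nb(q_fs: float, q_hs: float, alpha: float = 0.0) -> float:
    denom = (1.0 + 3.0 * alpha) * (2.0 * q_fs + q_hs)
    if denom <= 0:
        return float("inf")
    return 4.0 / denom


def nb_sibship(partition: SibshipPartition, n_boot: int = 500,
               seed: int = 0, alpha: float = 0.0) -> NbEstimate:
    """Sibship-frequency estimator of the effective number of breeders.

    Nb = 4 / (2*Q_FS + Q_HS) with the sibling-pair frequencies taken
    from the reconstructed partition; ``alpha`` is the departure from
    Hardy-Weinberg among parents (0 = random mating, the default).  The
    95% CI is a percentile bootstrap over offspring: individuals are
    resampled, the pair frequencies recomputed on the resampled set
    (pairs of distinct individuals only), and the estimator re-evaluated.
    Q_FS = Q_HS = 0 yields +inf with the finite lower bound retained.
    """
    n = partition.n_offspring
    if n < 2:
        raise ValueError("at least 2 offspring required")
    point = _wang_nb(partition.q_fs, partition.q_hs, alpha)

    # per-individual family labels and family-level HS adjacency
    sizes = np.array([len(f) for f in partition.families])
    fam = np.repeat(np.arange(len(sizes)), sizes)
    nf = len(sizes)
    hs_adj = np.zeros((nf, nf), dtype=bool)
    for a, b in partition.hs_edges:
        hs_adj[a, b] = hs_adj[b, a] = True

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        take = fam[rng.integers(0, n, size=n)]
        cnt = np.bincount(take, minlength=nf).astype(float)
        tot = n * (n - 1) / 2.0
        fs = float((cnt * (cnt - 1) / 2.0).sum())
        hs = float((np.outer(cnt, cnt) * hs_adj).sum()) / 2.0
        boots.append(_wang_nb(fs / tot, hs / tot, alpha))
    boots = np.asarray(boots)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return NbEstimate(method="sibship", point=point, ci=(float(lo), float(hi)),
                      n_offspring=n, n_used=int(n * (n - 1) // 2),
                      detail={"q_fs": partition.q_fs, "q_hs": partition.q_hs,
                              "alpha": alpha})


# ---------------------------------------------------------------------------
# linkage-disequilibrium Nb
# ---------------------------------------------------------------------------

def pairwise_r2_matrix(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Pearson correlation of dosages for every locus pair using
    pairwise-complete individuals.

    Returns ``(r2, n)`` where both are (L, L); entries with fewer than 2
    complete individuals or zero variance are NaN.
    """
    G = np.asarray(G, dtype=np.float64)
    M = (G != MISSING).astype(np.float64)
    X = np.where(G == MISSING, 0.0, G)
    n = M.T @ M
    sx = X.T @ M          # sum of x over rows where y is present
    sxx = (X * X).T @ M
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        vary = varx.T
        r2 = (cov * cov) / (varx * vary)
        r2 = np.where((n >= 2) & (varx > 0) & (vary > 0), r2, np.nan)
    return r2, n


def _expected_r2(S: float) -> float:
    # sampling expectation of r^2 with no true LD (random-mating model)
    if S >= 30:
        return 1.0 / S + 3.19 / (S * S)
    return 0.0018 + 0.907 / S + 4.44 / (S * S)


def _nb_from_r2prime(r2p: float, S: float) -> float:
    if r2p <= 0:
        return float("inf")
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            return float("inf")
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308 ** 2 - 2.08 * r2p
    if disc < 0:
        return float("inf")
    return (0.308 + np.sqrt(disc)) / (2.0 * r2p)


def nb_ld(gm: GenotypeMatrix, chrom_map: dict[str, str] | None = None,
          mating: str = "random") -> NbEstimate:
    """Linkage-disequilibrium estimator of the effective number of
    breeders, restricted to between-chromosome locus pairs.

    The mean squared dosage correlation over all between-chromosome pairs
    (pairwise-complete individuals) is adjusted by the sampling
    expectation at the harmonic-mean sample size S, and Nb follows the
    random-mating quadratic: Nb = (1/3 + sqrt(1/9 - 2.76 r2'))/(2 r2')
    for S >= 30, with the small-S coefficient variant below that.  The CI
    is a leave-one-locus-out jackknife on the mean r2, transformed
    through the (monotone) Nb formula.

    ``chrom_map`` optionally remaps locus chromosome names (e.g. RAD tags
    to chromosomes); physically linked comparisons are thereby excluded
    without discarding loci.
    """
    if mating != "random":
        raise NotImplementedError("only the random-mating model is implemented")
    poly = gm.maf() > 0
    g = gm.take_loci(np.nan_to_num(poly, nan=False).astype(bool))
    if g.n_individuals < 10:
        raise ValueError("at least 10 individuals required")
    chroms = g.loci["chrom"].astype(str)
    if chrom_map is not None:
        chroms = chroms.map(lambda c: chrom_map.get(c, c))
    chroms = chroms.to_numpy()
    if len(np.unique(chroms)) < 2:
        raise ValueError("no between-chromosome pairs: loci on a single "
                         "chromosome only")

    r2, n = pairwise_r2_matrix(g.dosage)
    between = chroms[:, None] != chroms[None, :]
    use = between & np.isfinite(r2) & np.triu(np.ones_like(between), 1).astype(bool)
    if not use.any():
        raise ValueError("no usable between-chromosome pairs")
    vals = r2[use]
    ns = n[use]
    mean_r2 = float(vals.mean())
    S = float(len(ns) / (1.0 / ns).sum())  # harmonic mean sample size
    r2p = mean_r2 - _expected_r2(S)
    point = _nb_from_r2prime(r2p, S)

    # jackknife over loci on the mean r2
    L = g.n_loci
    use_full = between & np.isfinite(r2)
    row_sum = np.where(use_full, np.nan_to_num(r2), 0.0).sum(axis=1)
    row_cnt = use_full.sum(axis=1)
    tot = vals.sum()
    P = len(vals)
    jk = []
    for l in range(L):
        cnt = P - row_cnt[l]
        if cnt <= 0:
            continue
        jk.append((tot - row_sum[l]) / cnt)
    jk = np.asarray(jk)
    m = len(jk)
    var_jk = (m - 1) / m * ((jk - jk.mean()) ** 2).sum() if m > 1 else 0.0
    half = 1.96 * np.sqrt(var_jk)
    r2_lo, r2_hi = mean_r2 - half, mean_r2 + half
    # Nb is decreasing in r2: upper CI from the lower r2 bound
    ci = (_nb_from_r2prime(r2_hi - _expected_r2(S), S),
          _nb_from_r2prime(r2_lo - _expected_r2(S), S))
    return NbEstimate(method="LD", point=point, ci=ci,
                      n_offspring=g.n_individuals, n_used=L,
                      detail={"mean_r2": mean_r2, "r2_prime": r2p,
                              "harmonic_S": S, "n_pairs": P})


# ---------------------------------------------------------------------------
# Chao asymptotic breeder number
# ---------------------------------------------------------------------------

def ns_chao(pedigree: InferredPedigree, n_orderings: int = 100,
            seed: int = 0) -> NsEstimate:
    """Observed and Chao2-extrapolated number of successful breeders.

    Offspring are incidence samples and parent slots are "species".  With
    a1 / a2 the parents seen in exactly one / two offspring and m the
    number of offspring, the bias-corrected Chao2 estimate is

        Ns_hat = Ns + ((m - 1) / m) * a1 * (a1 - 1) / (2 * (a2 + 1)),

    with the classical incidence-based variance for the SE.  The
    accumulation curve is the mean number of distinct parents at each
    offspring-subsample size over ``n_orderings`` random orderings.
    """
    offs, slots, M = pedigree.incidence()
    m, ns = M.shape[0], M.shape[1]
    if m < 1:
        raise ValueError("at least 1 offspring required")
    inc = M.sum(axis=0)  # offspring per parent slot
    a1 = int((inc == 1).sum())
    a2 = int((inc == 2).sum())
    A = (m - 1) / m if m > 0 else 0.0
    chao = ns + A * a1 * (a1 - 1) / (2.0 * (a2 + 1))

    if a2 > 0:
        G = a1 / a2
        var = a2 * (A * G ** 2 / 2.0 + A ** 2 * G ** 3 + A ** 2 * G ** 4 / 4.0)
    elif a1 > 1:
        chao0 = ns + A * a1 * (a1 - 1) / 2.0
        var = (A * a1 * (a1 - 1) / 2.0
               + A ** 2 * a1 * (2 * a1 - 1) ** 2 / 4.0
               - A ** 2 * a1 ** 4 / (4.0 * chao0))
    else:
        var = 0.0
    se = float(np.sqrt(max(var, 0.0)))

    rng = np.random.default_rng(seed)
    curve = np.zeros(m)
    for _ in range(n_orderings):
        order = rng.permutation(m)
        seen = np.zeros(ns, dtype=bool)
        distinct = np.empty(m)
        cnt = 0
        for k, i in enumerate(order):
            new = M[i] & ~seen
            cnt += int(new.sum())
            seen |= M[i]
            distinct[k] = cnt
        curve += distinct
    curve /= n_orderings
    return NsEstimate(ns=ns, chao=float(chao), se=se, a1=a1, a2=a2, m=m,
                      curve=curve)


# ---------------------------------------------------------------------------
# rarefied reproductive success
# ---------------------------------------------------------------------------

def rarefied_rs(pedigree: InferredPedigree, n_sub: int = 75,
                reps: int = 1000, seed: int = 0) -> RSResult:
    """Rarefied mean reproductive success of contributing parents.

    Per replicate, ``n_sub`` offspring are drawn without replacement and
    RS is the mean offspring-per-parent among parents appearing in the
    subsample (only parents with offspring are observable in this
    design, so RS >= 1).  Reports mean, SD, and the percentile 95% CI
    over replicates.
    """
    offs = sorted(pedigree.offspring)
    m = len(offs)
    if m < n_sub:
        raise ValueError(f"only {m} offspring available; lower n_sub "
                         f"(requested {n_sub})")
    pairs = [pedigree.offspring[o] for o in offs]
    slots = sorted(pedigree.slot_offspring)
    sidx = {s: k for k, s in enumerate(slots)}
    link = np.array([[sidx[a], sidx[b]] for a, b in pairs])

    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        take = rng.choice(m, size=n_sub, replace=False)
        used = link[take].ravel()
        k = len(np.unique(used))
        vals[r] = len(used) / k  # = 2*n_sub / distinct parents
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return RSResult(counts=dict(pedigree.slot_offspring),
                    mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
                    ci=(float(lo), float(hi)), n_sub=n_sub, reps=reps,
                    seed=seed)


# ---------------------------------------------------------------------------
# coancestry and per-parent offspring counts
# ---------------------------------------------------------------------------

def theta_from_counts(n_fs: int, n_hs: int, n_u: int) -> float:
    """Theta = (0.25 n_FS + 0.125 n_HS) / (n_FS + n_HS + n_U): full sibs
    contribute coancestry 1/4, half sibs 1/8, unrelated pairs 0."""
    total = n_fs + n_hs + n_u
    if total < 1:
        raise ValueError("no pairs")
    return (0.25 * n_fs + 0.125 * n_hs) / total


def coancestry(partition: SibshipPartition) -> CoancestryResult:
    """Mean pairwise coancestry implied by the partition."""
    n = partition.n_offspring
    if n < 2:
        raise ValueError("at least 2 offspring required")
    total = n * (n - 1) // 2
    n_fs = sum(len(f) * (len(f) - 1) // 2 for f in partition.families)
    n_hs = sum(len(partition.families[a]) * len(partition.families[b])
               for a, b in partition.hs_edges)
    n_u = total - n_fs - n_hs
    return CoancestryResult(theta=theta_from_counts(n_fs, n_hs, n_u),
                            n_fs=n_fs, n_hs=n_hs, n_u=n_u)


def offspring_per_parent(n_offspring: int, ns: int) -> float:
    """Average offspring per reconstructed parent: each offspring carries
    two parent links, so the mean is 2 * n_offspring / Ns."""
    if ns < 1:
        raise ValueError("ns must be >= 1")
    return 2.0 * n_offspring / ns
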