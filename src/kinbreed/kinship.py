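"""Pairwise kinship, relationship classification, and sibship
reconstruction.

The centerpiece is a stand-in for full-likelihood sibship software: each
offspring pair is classified into unrelated / half-sib / full-sib /
parent-offspring by IBD-class likelihoods under a symmetric per-allele
genotyping-error model, full-sib families are the connected components of
the FS graph after a transitivity repair, half-sib links are aggregated
between families by majority vote, and latent parent "slots" are merged
across families along half-sib edges.  This pairwise + graph approach is
much faster than a full-likelihood MCMC but shares its outputs (families,
Q_FS/Q_HS pair frequencies, reconstructed parent count and per-parent
offspring counts); a Colony2 exporter elsewhere in the package preserves
the option of running the original tool.

KING-robust kinship (phi) is also provided: based on heterozygote
sharing and opposing-homozygote counts, it is robust to population
structure and is the statistic used for the group-relatedness
permutation test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["RelationshipCall", "SibshipPartition", "InferredPedigree",
           "king_phi", "king_matrix", "classify_pair", "classify_pairs",
           "build_sibship", "infer_parents", "count_sires", "SirePartition",
           "true_sibship", "true_inferred"]

CLASSES = ("U", "HS", "FS", "PO")
# IBD coefficients (k0, k1, k2) per class
IBD_K = {"U": (1.0, 0.0, 0.0), "HS": (0.5, 0.5, 0.0),
         "FS": (0.25, 0.5, 0.25), "PO": (0.0, 1.0, 0.0)}
MIN_SHARED_LOCI = 100
EDGE_MARGIN = 2.0  # log-likelihood units required to trust an edge in repair
_TINY = 1e-300


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

def king_phi(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust kinship for one pair of dosage vectors.

    phi = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j)) with all counts
    taken over loci called in both individuals.  Returns NaN when neither
    individual is heterozygous on the shared loci (undefined).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    shared = (gi != MISSING) & (gj != MISSING)
    hi = (gi == 1) & shared
    hj = (gj == 1) & shared
    hethet = int((hi & hj).sum())
    opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0)))[shared].sum())
    denom = int(hi.sum()) + int(hj.sum())
    if denom == 0:
        return float("nan")
    return (hethet - 2.0 * opp) / denom


def king_matrix(G: np.ndarray) -> np.ndarray:
    """All-pairs KING-robust phi for a dosage matrix (n x L, -1 missing).

    Vectorized via integer matrix products; the diagonal is 0.5 whenever
    the individual has at least one heterozygous call.
    """
    G = np.asarray(G)
    valid = (G != MISSING).astype(np.float64)
    het = (G == 1).astype(np.float64)
    aa = (G == 0).astype(np.float64)
    bb = (G == 2).astype(np.float64)
    hethet = het @ het.T
    opp = aa @ bb.T + bb @ aa.T
    het_shared = het @ valid.T  # het loci of i that are called in j
    denom = het_shared + het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (hethet - 2.0 * opp) / denom, np.nan)
    return phi


# ---------------------------------------------------------------------------
# IBD-class likelihoods
# ---------------------------------------------------------------------------

def _error_matrix(eps: float) -> np.ndarray:
    """P(observed dosage | true dosage) under independent per-allele flips."""
    e, f = eps, 1.0 - eps
    return np.array([
        [f * f, 2 * e * f, e * e],
        [e * f, f * f + e * e, e * f],
        [e * e, 2 * e * f, f * f],
    ])


def _true_joint_tables(p: np.ndarray) -> dict[int, np.ndarray]:
    """Per-locus joint genotype tables P(g1, g2 | IBD=m), shape (L, 3, 3).

    ALT frequency ``p``; HWE genotype probabilities for the non-shared
    alleles.  IBD=1 uses the shared-allele transition; IBD=2 is identity.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (L, 3)
    L = len(p)
    j0 = hwe[:, :, None] * hwe[:, None, :]
    # transition T1[g1, g2] = P(g2 | g1, share one allele)
    t1 = np.zeros((L, 3, 3))
    t1[:, 0, 0] = q
    t1[:, 0, 1] = p
    t1[:, 1, 0] = 0.5 * q
    t1[:, 1, 1] = 0.5
    t1[:, 1, 2] = 0.5 * p
    t1[:, 2, 1] = q
    t1[:, 2, 2] = p
    j1 = hwe[:, :, None] * t1
    j2 = np.zeros((L, 3, 3))
    j2[:, np.arange(3), np.arange(3)] = hwe
    return {0: j0, 1: j1, 2: j2}


def class_log_tables(freqs: np.ndarray, eps: float) -> np.ndarray:
    """Log observed-pair probabilities per locus and class.

    Returns an array of shape (L, 4, 10): classes ordered U, HS, FS, PO;
    the last axis indexes the observed genotype pair as ``3*g1 + g2``
    with slot 9 a zero entry used for missing data.
    """
    joints = _true_joint_tables(freqs)
    E = _error_matrix(eps)
    L = len(freqs)
    out = np.zeros((L, len(CLASSES), 10))
    for c, name in enumerate(CLASSES):
        k = IBD_K[name]
        jt = sum(k[m] * joints[m] for m in range(3) if k[m] > 0)
        jobs = np.einsum("ab,lbc,cd->lad", E.T, jt, E)
        out[:, c, :9] = np.log(np.maximum(jobs, _TINY)).reshape(L, 9)
    return out


@dataclass
class RelationshipCall:
    """Classification of one pair (a row of the ``classify_pairs`` table)."""

    id_i: str
    id_j: str
    king_phi: float
    loglik: dict[str, float]
    assigned: str
    margin: float
    n_shared_loci: int


def classify_pairs(gm: GenotypeMatrix, pairs=None,
                   allele_freqs: np.ndarray | None = None,
                   eps: float = 0.01,
                   min_shared_loci: int = MIN_SHARED_LOCI,
                   chunk: int = 2048) -> pd.DataFrame:
    """Classify pairs into U / HS / FS / PO by IBD-class log-likelihood.

    ``pairs`` is an iterable of index pairs (default: all unordered
    pairs).  Allele frequencies default to the full-sample estimate.
    Pairs sharing fewer than ``min_shared_loci`` called loci are assigned
    ``uncallable``.  Ties break toward the less-related class
    (U > HS > FS > PO).  Returns a DataFrame with one row per pair:
    ``i, j, id_i, id_j, ll_U, ll_HS, ll_FS, ll_PO, n_shared, phi,
    assigned, margin``.
    """
    G = gm.dosage
    if allele_freqs is None:
        allele_freqs = gm.alt_freq()
    freqs = np.clip(np.nan_to_num(allele_freqs, nan=0.5), 1e-6, 1 - 1e-6)
    logtab = class_log_tables(freqs, eps)  # (L, 4, 10)
    L = gm.n_loci

    if pairs is None:
        n = gm.n_individuals
        pairs = list(itertools.combinations(range(n), 2))
    pairs = np.asarray(list(pairs), dtype=np.int64)
    if pairs.size == 0:
        return pd.DataFrame(columns=["i", "j", "id_i", "id_j", "ll_U",
                                     "ll_HS", "ll_FS", "ll_PO", "n_shared",
                                     "phi", "assigned", "margin"])

    phi_full = None
    rows_ll = np.empty((len(pairs), 4))
    n_shared = np.empty(len(pairs), dtype=np.int64)
    lidx = np.arange(L)
    tabs = [logtab[:, c, :] for c in range(4)]  # each (L, 10)
    for start in range(0, len(pairs), chunk):
        block = pairs[start:start + chunk]
        g1 = G[block[:, 0]].astype(np.int64)
        g2 = G[block[:, 1]].astype(np.int64)
        bad = (g1 == MISSING) | (g2 == MISSING)
        idx = np.where(bad, 9, 3 * g1 + g2)
        n_shared[start:start + chunk] = (~bad).sum(axis=1)
        for c in range(4):
            rows_ll[start:start + chunk, c] = tabs[c][lidx[None, :], idx].sum(axis=1)

    # argmax with ties toward the less-related class: U first in CLASSES
    best = np.argmax(rows_ll, axis=1)
    sorted_ll = np.sort(rows_ll, axis=1)
    margin = sorted_ll[:, -1] - sorted_ll[:, -2]
    assigned = np.array(CLASSES, dtype=object)[best]
    assigned[n_shared < min_shared_loci] = "uncallable"

    ids = np.asarray(gm.ids, dtype=object)
    out = pd.DataFrame({
        "i": pairs[:, 0], "j": pairs[:, 1],
        "id_i": ids[pairs[:, 0]], "id_j": ids[pairs[:, 1]],
        "ll_U": rows_ll[:, 0], "ll_HS": rows_ll[:, 1],
        "ll_FS": rows_ll[:, 2], "ll_PO": rows_ll[:, 3],
        "n_shared": n_shared, "assigned": assigned, "margin": margin,
    })
    return out


def classify_pair(gm: GenotypeMatrix, i: int, j: int,
                  allele_freqs: np.ndarray | None = None,
                  eps: float = 0.01,
                  min_shared_loci: int = MIN_SHARED_LOCI) -> RelationshipCall:
    """Single-pair convenience wrapper around :func:`classify_pairs`."""
    row = classify_pairs(gm, [(i, j)], allele_freqs, eps,
                         min_shared_loci).iloc[0]
    return RelationshipCall(
        id_i=row["id_i"], id_j=row["id_j"],
        king_phi=king_phi(gm.dosage[i], gm.dosage[j]),
        loglik={c: float(row[f"ll_{c}"]) for c in CLASSES},
        assigned=row["assigned"], margin=float(row["margin"]),
        n_shared_loci=int(row["n_shared"]))


# ---------------------------------------------------------------------------
# sibship partitioning
# ---------------------------------------------------------------------------

@dataclass
class SibshipPartition:
    """Full-sib families plus aggregated half-sib links between them.

    ``families`` is a list of lists of offspring ids; ``hs_edges`` maps a
    family-index pair to the mean margin of its HS-classified cross
    pairs.  ``q_fs`` / ``q_hs`` are the frequencies of full- and half-sib
    pairs among all unordered offspring pairs implied by the partition.
    """

    families: list[list[str]]
    hs_edges: dict[tuple[int, int], float] = field(default_factory=dict)
    q_fs: float = 0.0
    q_hs: float = 0.0

    @property
    def n_offspring(self) -> int:
        return sum(len(f) for f in self.families)

    def family_of(self) -> dict[str, int]:
        return {x: i for i, fam in enumerate(self.families) for x in fam}

    def labels(self, ids: list[str]) -> np.ndarray:
        fam = self.family_of()
        return np.array([fam[x] for x in ids])


def _pair_q(families: list[list[str]],
            hs_edges: dict[tuple[int, int], float]) -> tuple[float, float]:
    n = sum(len(f) for f in families)
    total = n * (n - 1) / 2
    if total == 0:
        return 0.0, 0.0
    fs = sum(len(f) * (len(f) - 1) / 2 for f in families)
    hs = sum(len(families[a]) * len(families[b]) for a, b in hs_edges)
    return fs / total, hs / total


def build_sibship(calls: pd.DataFrame,
                  edge_margin: float = EDGE_MARGIN) -> SibshipPartition:
    """Partition offspring into full-sib families from pair calls.

    FS-classified pairs (PO calls among offspring are coerced to FS with
    a warning: a single juvenile cohort cannot contain its own parents)
    form a graph whose connected components are candidate families.
    Transitivity violations — A-B and B-C called FS while A-C is called
    something else — are repaired by iteratively dropping the
    FS edge with the smallest likelihood margin among those involved,
    until no violation remains.  Half-sib edges are then aggregated
    between families by majority vote over cross-family pair classes.
    The result is order-invariant: ties are broken on sorted ids.
    """
    ids = sorted(set(calls["id_i"]) | set(calls["id_j"]))
    cls: dict[tuple[str, str], str] = {}
    marg: dict[tuple[str, str], float] = {}
    for r in calls.itertuples(index=False):
        a, b = sorted((r.id_i, r.id_j))
        cls[(a, b)] = r.assigned
        marg[(a, b)] = float(r.margin)

    n_po = sum(1 for v in cls.values() if v == "PO")
    if n_po:
        log.warning("build_sibship: coercing %d PO calls among offspring "
                    "to FS (same-generation set)", n_po)
        cls = {k: ("FS" if v == "PO" else v) for k, v in cls.items()}

    G = nx.Graph()
    G.add_nodes_from(ids)
    for (a, b), v in cls.items():
        if v == "FS":
            G.add_edge(a, b, margin=marg[(a, b)])

    # transitivity repair
    while True:
        weakest: tuple[str, str] | None = None
        weakest_m = np.inf
        for b in sorted(G.nodes):
            nbrs = sorted(G.neighbors(b))
            for a, c in itertools.combinations(nbrs, 2):
                key = (a, c) if a < c else (c, a)
                v = cls.get(key)
                if v is None or v in ("FS", "uncallable"):
                    continue
                for e in ((a, b), (b, c)):
                    ek = e if e[0] < e[1] else (e[1], e[0])
                    m = G.edges[ek]["margin"]
                    if m < weakest_m:
                        weakest_m, weakest = m, ek
        if weakest is None:
            break
        G.remove_edge(*weakest)

    families = [sorted(c) for c in nx.connected_components(G)]
    families.sort(key=lambda f: f[0])
    fam_of = {x: i for i, f in enumerate(families) for x in f}

    # aggregate half-sib edges between families by majority vote
    votes: dict[tuple[int, int], list[str]] = {}
    margins: dict[tuple[int, int], list[float]] = {}
    for (a, b), v in cls.items():
        fa, fb = fam_of[a], fam_of[b]
        if fa == fb:
            continue
        key = (min(fa, fb), max(fa, fb))
        votes.setdefault(key, []).append(v)
        if v == "HS":
            margins.setdefault(key, []).append(marg[(a, b)])
    hs_edges = {}
    for key, vs in votes.items():
        n_hs = sum(1 for v in vs if v == "HS")
        if n_hs > len(vs) / 2:
            hs_edges[key] = float(np.mean(margins[key]))

    q_fs, q_hs = _pair_q(families, hs_edges)
    return SibshipPartition(families=families, hs_edges=hs_edges,
                            q_fs=q_fs, q_hs=q_hs)


# ---------------------------------------------------------------------------
# latent parent reconstruction
# ---------------------------------------------------------------------------

@dataclass
class InferredPedigree:
    """Latent parent slots per family and the offspring -> slots map.

    ``slots[k]`` is the canonical slot id; ``offspring`` maps each
    offspring id to its (slot1, slot2) pair; ``slot_offspring`` counts
    offspring per slot.  Ns (number of reconstructed parental genotypes)
    is the number of distinct slots.
    """

    offspring: dict[str, tuple[str, str]]
    slot_offspring: dict[str, int]
    run_id: int = 0

    @property
    def ns(self) -> int:
        return len(self.slot_offspring)

    def incidence(self) -> tuple[list[str], list[str], np.ndarray]:
        """Offspring x parent-slot incidence matrix (for accumulation /
        Chao analyses)."""
        offs = sorted(self.offspring)
        slots = sorted(self.slot_offspring)
        sidx = {s: k for k, s in enumerate(slots)}
        M = np.zeros((len(offs), len(slots)), dtype=bool)
        for i, o in enumerate(offs):
            for s in self.offspring[o]:
                M[i, sidx[s]] = True
        return offs, slots, M


def infer_parents(partition: SibshipPartition) -> InferredPedigree:
    """Assign latent parent slots to families by merging along half-sib
    edges.

    Each shared parent corresponds to a clique of families in the
    half-sib graph, so half-sib edges are grouped by triangle closure:
    two edges that share a family belong to the same parent whenever the
    remaining two families are themselves half sibs.  Connected
    components of this edge graph are parent groups; each group becomes
    one shared slot.  A family can hold at most two slots (its dam and
    sire) — if triangle closure puts it in more than two groups, it keeps
    the two with the largest size and mean edge weight and detaches from
    the rest.  Families keep fresh slots for parents not shared with any
    other family, so with no half-sib edges Ns = 2 * #families.
    """
    nf = len(partition.families)
    edges = sorted(partition.hs_edges)
    weight = dict(partition.hs_edges)
    hs = set(edges)

    # union-find over edges: same-parent when a triangle closes
    eidx = {e: k for k, e in enumerate(edges)}
    parent = list(range(len(edges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_family: dict[int, list[tuple[int, int]]] = {}
    for e in edges:
        for f in e:
            by_family.setdefault(f, []).append(e)
    for f, es in by_family.items():
        for e1, e2 in itertools.combinations(es, 2):
            b = e1[0] if e1[1] == f else e1[1]
            c = e2[0] if e2[1] == f else e2[1]
            key = (b, c) if b < c else (c, b)
            if key in hs:
                parent[find(eidx[e1])] = find(eidx[e2])

    groups: dict[int, set[int]] = {}
    gweight: dict[int, list[float]] = {}
    for e in edges:
        r = find(eidx[e])
        groups.setdefault(r, set()).update(e)
        gweight.setdefault(r, []).append(weight[e])

    # each family holds at most two shared slots
    fam_groups: dict[int, list[int]] = {f: [] for f in range(nf)}
    for g, members in groups.items():
        for f in members:
            fam_groups[f].append(g)
    for f, gs in fam_groups.items():
        if len(gs) > 2:
            gs.sort(key=lambda g: (-len(groups[g]),
                                   -float(np.mean(gweight[g])), g))
            for g in gs[2:]:
                groups[g].discard(f)
            fam_groups[f] = gs[:2]

    group_name = {g: f"P{k:04d}"
                  for k, g in enumerate(sorted(groups))}
    offspring: dict[str, tuple[str, str]] = {}
    slot_counts: dict[str, int] = {}
    fresh = len(group_name)
    for f, fam in enumerate(partition.families):
        names = [group_name[g] for g in fam_groups[f]]
        while len(names) < 2:
            names.append(f"P{fresh:04d}")
            fresh += 1
        for x in fam:
            offspring[x] = (names[0], names[1])
        for s in names:
            slot_counts[s] = slot_counts.get(s, 0) + len(fam)
    return InferredPedigree(offspring=offspring, slot_offspring=slot_counts)


# ---------------------------------------------------------------------------
# ground-truth adapters
# ---------------------------------------------------------------------------

def true_sibship(pedigree, offspring_ids=None) -> SibshipPartition:
    """Exact sibship partition implied by a true pedigree: families are
    (dam, sire) groups, HS edges join families sharing exactly one
    parent."""
    off = pedigree.offspring
    if offspring_ids is not None:
        wanted = set(offspring_ids)
        off = off[off["id"].isin(wanted)]
    groups: dict[tuple[str, str], list[str]] = {}
    for r in off.itertuples(index=False):
        groups.setdefault((r.dam, r.sire), []).append(r.id)
    keys = sorted(groups)
    families = [sorted(groups[k]) for k in keys]
    hs_edges = {}
    for a, b in itertools.combinations(range(len(keys)), 2):
        shared = len(set(keys[a]) & set(keys[b]))
        if shared == 1:
            hs_edges[(a, b)] = 1.0
    q_fs, q_hs = _pair_q(families, hs_edges)
    return SibshipPartition(families=families, hs_edges=hs_edges,
                            q_fs=q_fs, q_hs=q_hs)


def true_inferred(pedigree, offspring_ids=None) -> InferredPedigree:
    """InferredPedigree built from the truth, with real parent ids as
    slots (the oracle for slot-based estimators)."""
    off = pedigree.offspring
    if offspring_ids is not None:
        wanted = set(offspring_ids)
        off = off[off["id"].isin(wanted)]
    offspring = {r.id: (r.dam, r.sire) for r in off.itertuples(index=False)}
    counts: dict[str, int] = {}
    for d, s in offspring.values():
        counts[d] = counts.get(d, 0) + 1
        counts[s] = counts.get(s, 0) + 1
    return InferredPedigree(offspring=offspring, slot_offspring=counts)


# ---------------------------------------------------------------------------
# known-mother paternity clustering
# ---------------------------------------------------------------------------

@dataclass
class SirePartition:
    """Result of clustering a known mother's clutch by shared paternity."""

    clusters: list[list[str]]
    suspect: list[str]  # offspring Mendelian-inconsistent with the mother

    @property
    def n_sires(self) -> int:
        return len(self.clusters)


def _mendel_table() -> np.ndarray:
    """M[gm, gs, gc] = P(child dosage gc | mother gm, sire gs)."""
    M = np.zeros((3, 3, 3))
    for gm in range(3):
        for gs in range(3):
            pm = gm / 2.0  # P(maternal gamete = ALT)
            ps = gs / 2.0
            M[gm, gs, 0] = (1 - pm) * (1 - ps)
            M[gm, gs, 1] = pm * (1 - ps) + (1 - pm) * ps
            M[gm, gs, 2] = pm * ps
    return M


def count_sires(mother_g: np.ndarray, clutch: GenotypeMatrix,
                allele_freqs: np.ndarray | None = None, eps: float = 0.01,
                edge_margin: float = 0.0,
                maternity_tolerance: float = 0.05) -> SirePartition:
    """Partition a known mother's clutch into paternal sibships.

    For each offspring pair the likelihood of sharing the sire (full
    sibs) is compared with that of different sires (maternal half sibs),
    conditioning on the mother's genotype and marginalizing the unknown
    sire(s) over HWE allele frequencies; the same transitivity repair as
    the sibship builder turns pairwise decisions into clusters, whose
    count is the inferred number of sires.  Offspring showing
    opposing-homozygote conflicts with the mother at more than
    ``maternity_tolerance`` of shared loci are flagged as maternity
    suspects and excluded from clustering.
    """
    mother_g = np.asarray(mother_g)
    G = clutch.dosage
    n, L = G.shape
    if allele_freqs is None:
        allele_freqs = clutch.alt_freq()
    p = np.clip(np.nan_to_num(np.asarray(allele_freqs, float), nan=0.5),
                1e-6, 1 - 1e-6)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (L, 3) sire prior

    E = _error_matrix(eps)
    A = np.einsum("msk,ko->mso", _mendel_table(), E)  # P(obs child | gm, gs)

    # maternity screen on opposing homozygotes
    suspect = []
    keep = []
    m_called = mother_g != MISSING
    for i in range(n):
        shared = m_called & (G[i] != MISSING)
        ns = int(shared.sum())
        opp = int((((mother_g == 0) & (G[i] == 2))
                   | ((mother_g == 2) & (G[i] == 0)))[shared].sum())
        if ns > 0 and opp / ns > maternity_tolerance:
            suspect.append(clutch.ids[i])
        else:
            keep.append(i)

    ids = [clutch.ids[i] for i in keep]
    if len(keep) <= 1:
        return SirePartition(clusters=[[x] for x in ids], suspect=suspect)

    # per offspring-locus: P(obs child | gm, gs) for each sire genotype
    gm_idx = np.where(m_called, mother_g, 1)  # placeholder, masked later
    # lk[i, l, gs] for offspring i
    lk = np.empty((len(keep), L, 3))
    for k, i in enumerate(keep):
        gc = np.where(G[i] != MISSING, G[i], 0)
        lk[k] = A[gm_idx, :, gc]  # (L, 3)
    valid = np.stack([m_called & (G[i] != MISSING) for i in keep])  # (n, L)

    # marginal per offspring: B[i, l] = sum_gs hwe * lk
    B = np.einsum("lg,ilg->il", hwe, lk)
    logB = np.where(valid, np.log(np.maximum(B, _TINY)), 0.0)

    pairs = list(itertools.combinations(range(len(keep)), 2))
    rows = []
    for a, b in pairs:
        both = valid[a] & valid[b]
        joint = np.einsum("lg,lg,lg->l", hwe, lk[a], lk[b])
        ll_same = np.where(both, np.log(np.maximum(joint, _TINY)), 0.0).sum()
        ll_diff = (logB[a] * both).sum() + (logB[b] * both).sum()
        d = ll_same - ll_diff
        rows.append({
            "id_i": ids[a], "id_j": ids[b],
            "assigned": "FS" if d > edge_margin else "HS",
            "margin": abs(d), "i": a, "j": b,
            "ll_U": 0.0, "ll_HS": ll_diff, "ll_FS": ll_same, "ll_PO": -np.inf,
            "n_shared": int(both.sum()),
        })
    calls = pd.DataFrame(rows)
    part = build_sibship(calls)
    return SirePartition(clusters=part.families, suspect=suspect)
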