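"""Shared fixtures: small simulated datasets and hand-built matrices."""

import numpy as np
import pandas as pd
import pytest

from kinbreed.matrix import MISSING, GenotypeMatrix


def make_matrix(dosage, dp=None, ad_ref=None, ad_alt=None, qual=None,
                tags=None, chroms=None, ids=None, pos=None):
    """Build a GenotypeMatrix from plain lists (individuals x loci)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    loci = pd.DataFrame({
        "chrom": chroms if chroms is not None else ["chr1"] * L,
        "pos": pos if pos is not None else np.arange(1, L + 1) * 1000,
        "ref": "A",
        "alt": "T",
        "qual": qual if qual is not None else [50.0] * L,
        "tag": tags if tags is not None else [f"tag{j}" for j in range(L)],
    })
    return GenotypeMatrix(
        ids=ids if ids is not None else [f"ind{i}" for i in range(n)],
        loci=loci, dosage=dosage,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32))


@pytest.fixture
def six_site_matrix():
    """Six sites x four individuals built so the cascade removes exactly
    one site per rule (QUAL, MAC, call-rate-after-depth-7, het, allele
    balance) and one survives.

    Column order: [fails-QUAL, fails-MAC, fails-call-rate, fails-het,
    fails-AB, survivor].
    """
    # dosages per site (rows become individuals after transpose)
    dos = np.array([
        [2, 1, 0, 0],  # fails QUAL only
        [1, 0, 0, 0],  # minor allele count 1 < 3
        [2, 1, 0, 0],  # two calls at depth 5 get masked -> call rate 0.5
        [1, 1, 1, 0],  # observed het 0.75 > 0.6
        [2, 1, 0, 0],  # het call AD (9, 1) -> allele balance 0.9
        [2, 1, 0, 0],  # survivor
    ]).T
    dp = np.full((4, 6), 20, dtype=np.int32)
    dp[2, 2] = 5
    dp[3, 2] = 5
    ad_ref = np.zeros((4, 6), dtype=np.int32)
    ad_alt = np.zeros((4, 6), dtype=np.int32)
    for i in range(4):
        for j in range(6):
            g = dos[i, j]
            d = dp[i, j]
            if g == 0:
                ad_ref[i, j] = d
            elif g == 2:
                ad_alt[i, j] = d
            else:
                ad_ref[i, j] = d // 2
                ad_alt[i, j] = d - d // 2
    # the AB-failing site: its het call gets AD (9, 1)
    het_row = int(np.argmax(dos[:, 4] == 1))
    ad_ref[het_row, 4] = 9
    ad_alt[het_row, 4] = 1
    dp[het_row, 4] = 10
    qual = [10.0, 50.0, 50.0, 50.0, 50.0, 50.0]
    return make_matrix(dos, dp=dp, ad_ref=ad_ref, ad_alt=ad_alt, qual=qual)


@pytest.fixture
def table2_clutches():
    """Per-female screened-offspring and inferred-sire counts for the
    five surveyed waterbodies (berried-female clutch results)."""
    rows = []

    def add(wb, pairs):
        for k, (n_off, n_sires) in enumerate(pairs, 1):
            rows.append({"waterbody": wb, "female": f"{wb}-{k}",
                         "n_offspring": n_off, "n_sires": n_sires})

    add("EastGC1", [(30, 1), (31, 2), (29, 1), (31, 2), (31, 3)])
    add("EastGC2", [(34, 2)])
    add("EastGC4", [(26, 4), (29, 5), (21, 4), (31, 4)])
    add("WestGC1", [(44, 1), (35, 2), (36, 3), (30, 4), (33, 1), (31, 3)])
    add("Hotel1", [(28, 2), (18, 3), (36, 6), (4, 1), (36, 7), (36, 3)])
    return pd.DataFrame(rows)
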