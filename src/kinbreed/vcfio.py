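"""Reading and writing the formats around the pipeline.

VCF v4.2 is the native interchange format (GT:DP:AD, RAD-tag id in the ID
column using a ``tag:offset`` convention).  GenePop and Colony2 ``.dat``
exporters provide interoperability with NeEstimator-style LD estimation
and full-likelihood sibship reconstruction, respectively.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["read_vcf", "write_vcf", "export_genepop", "export_colony_dat",
           "read_metadata", "write_metadata", "write_pedigree", "read_pedigree"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, tag_window: int = 300) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multiallelic or indel records are
    skipped with a logged count (available in ``meta['n_skipped']``).  The
    RAD-tag id is parsed from the ID column (``tag:offset``); records
    without one are grouped into tags by position window (default 300 bp,
    roughly one sheared RAD fragment).  Non-diploid genotypes raise.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)

    dosages, dps, adr, ada, rows = [], [], [], [], []
    n_skipped = 0
    has_dp = has_ad = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes
        if any(len(g) != 3 for g in gts):
            raise ValueError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0,1,2; 3 = missing
        gt[gt == 3] = MISSING

        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_dp = False
        else:
            dp = dp.reshape(n).astype(np.int64)
            dp = np.where(dp < 0, 0, dp)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            has_ad = False
        else:
            ad = ad.reshape(n, -1).astype(np.int64)
            ad = np.where(ad < 0, 0, ad)

        tag = None
        if v.ID and ":" in v.ID:
            tag = v.ID.split(":", 1)[0]
        qual = v.QUAL if v.QUAL is not None else np.nan
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], qual, tag))
        dosages.append(gt)
        dps.append(dp if dp is not None else np.zeros(n, dtype=np.int64))
        adr.append(ad[:, 0] if ad is not None else np.zeros(n, dtype=np.int64))
        ada.append(ad[:, 1] if ad is not None else np.zeros(n, dtype=np.int64))
    vcf.close()

    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual",
                                       "tag"])
    if loci["tag"].isna().any():
        loci["tag"] = _infer_tags(loci, tag_window)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    dosage = (np.vstack(dosages).T if dosages
              else np.empty((n, 0), dtype=np.int8))
    gm = GenotypeMatrix(
        ids=samples, loci=loci, dosage=dosage,
        dp=np.vstack(dps).T.astype(np.int32) if (dosages and has_dp) else None,
        ad_ref=np.vstack(adr).T.astype(np.int32) if (dosages and has_ad) else None,
        ad_alt=np.vstack(ada).T.astype(np.int32) if (dosages and has_ad) else None,
        meta={"n_skipped": n_skipped},
    )
    return gm


def _infer_tags(loci: pd.DataFrame, window: int) -> list[str]:
    """Group positions within ``window`` bp on one chromosome into a tag."""
    tags = [None] * len(loci)
    order = loci.sort_values(["chrom", "pos"]).index
    cur_chrom, cur_start, cur_tag = None, None, None
    for idx in order:
        existing = loci.at[idx, "tag"]
        chrom, pos = loci.at[idx, "chrom"], loci.at[idx, "pos"]
        if chrom != cur_chrom or cur_start is None or pos - cur_start > window:
            cur_chrom, cur_start = chrom, pos
            cur_tag = f"{chrom}_{pos}"
        tags[loci.index.get_loc(idx)] = (existing if isinstance(existing, str)
                                         else cur_tag)
    return tags


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2 with GT:DP:AD, the tag in the ID column, records
    sorted by (chrom, pos).  Missing calls become ``./.``."""
    order = gm.loci.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    g = gm.take_loci(order)
    with_depth = g.dp is not None and g.ad_ref is not None

    lines = ["##fileformat=VCFv4.2", "##source=kinbreed"]
    for chrom in pd.unique(g.loci["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.ids))

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fmt = "GT:DP:AD" if with_depth else "GT"
    for j in range(g.n_loci):
        r = g.loci.iloc[j]
        qual = "." if (r["qual"] is None or
                       (isinstance(r["qual"], float) and math.isnan(r["qual"]))
                       ) else f"{float(r['qual']):g}"
        fields = [str(r["chrom"]), str(int(r["pos"])), f"{r['tag']}:{int(r['pos'])}",
                  str(r["ref"]), str(r["alt"]), qual, "PASS", ".", fmt]
        for i in range(g.n_individuals):
            call = gt_str[int(g.dosage[i, j])]
            if with_depth:
                call += f":{int(g.dp[i, j])}:{int(g.ad_ref[i, j])},{int(g.ad_alt[i, j])}"
            fields.append(call)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def export_genepop(gm: GenotypeMatrix, pop_labels, path,
                   title: str = "kinbreed export") -> None:
    """GenePop file with 4-digit allele coding (ref=01, alt=02, missing
    0000) and one POP block per label, in first-appearance order."""
    labels = list(pop_labels)
    if len(labels) != gm.n_individuals:
        raise ValueError("one population label per individual required")
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    lines = [title]
    lines += [f"{r['tag']}_{r['chrom']}_{int(r['pos'])}"
              for _, r in gm.loci.iterrows()]
    seen: list = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for pop in seen:
        lines.append("POP")
        for i, lab in enumerate(labels):
            if lab != pop:
                continue
            alleles = " ".join(code[int(d)] for d in gm.dosage[i])
            lines.append(f"{gm.ids[i]} ,  {alleles}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Colony2
# ---------------------------------------------------------------------------

def export_colony_dat(gm: GenotypeMatrix, offspring_ids, path,
                      candidate_females=(), candidate_males=(),
                      maternal_dyads=(), dropout_rate: float = 0.001,
                      other_error_rate: float = 0.01,
                      prob_mother_included: float = 0.99,
                      prob_father_included: float = 0.01,
                      seed: int = 1234, allow_inbreeding: bool = True,
                      project: str = "kinbreed") -> None:
    """Write a Colony2 ``.dat`` project for full-likelihood sibship runs.

    The layout follows Colony's dioecious / polygamous / diploid project
    format: header counts, marker names, codominant flags, per-marker
    allelic-dropout and other-typing-error rows, offspring genotypes with
    two columns per locus (missing = 0), candidate parent sections with
    their inclusion probabilities, and known mother-offspring dyads.
    """
    if len(list(offspring_ids)) == 0:
        raise ValueError("offspring set is empty")
    idx = {x: i for i, x in enumerate(gm.ids)}
    for mother, child in maternal_dyads:
        if mother not in idx or child not in idx:
            raise KeyError(f"dyad individual absent from matrix: "
                           f"{mother if mother not in idx else child}")
    for ind in list(candidate_females) + list(candidate_males):
        if ind not in idx:
            raise KeyError(f"candidate parent absent from matrix: {ind}")

    def geno_row(ind: str) -> str:
        g = gm.dosage[idx[ind]]
        pairs = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
        return " ".join(pairs[int(d)] for d in g)

    offspring_ids = list(offspring_ids)
    L = gm.n_loci
    lines = [
        f"'{project}'             ! project name",
        f"'{project}_out'         ! output file name",
        f"{len(offspring_ids)}    ! number of offspring",
        f"{L}    ! number of loci",
        f"{seed}  ! random number seed",
        "0       ! do not update allele frequencies",
        "2       ! dioecious species",
        f"{1 if allow_inbreeding else 0}       ! inbreeding",
        "0       ! diploid",
        "0 0     ! polygamy for males and females",
        "0       ! no clone inference",
        "1       ! sibship size scaling",
        "0 0     ! no sibship prior",
        "0       ! unknown population allele frequencies",
        "1       ! number of runs",
        "3       ! long run",
        "0       ! no monitor",
        "10000   ! monitor interval",
        "0       ! non-GUI run",
        "1       ! full-likelihood method",
        "2       ! medium likelihood precision",
        " ".join(f"mk{j + 1}" for j in range(L)) + "   ! marker names",
        " ".join("0" for _ in range(L)) + "   ! codominant markers",
        " ".join(f"{dropout_rate:g}" for _ in range(L)) + "   ! allelic dropout rate",
        " ".join(f"{other_error_rate:g}" for _ in range(L)) + "   ! other typing error rate",
    ]
    for ind in offspring_ids:
        lines.append(f"{ind} {geno_row(ind)}")
    lines.append(f"{prob_mother_included:g} {prob_father_included:g}   "
                 "! prob. mother / father included in candidates")
    lines.append(f"{len(list(candidate_females))} {len(list(candidate_males))}"
                 "   ! numbers of candidate mothers and fathers")
    for ind in candidate_females:
        lines.append(f"{ind} {geno_row(ind)}")
    for ind in candidate_males:
        lines.append(f"{ind} {geno_row(ind)}")
    lines.append(f"{len(list(maternal_dyads))} 0   ! known maternal / paternal dyads")
    for mother, child in maternal_dyads:
        lines.append(f"{mother} {child}")
    lines += [
        "0 0   ! known maternal / paternal sibships",
        "0 0   ! excluded maternities / paternities",
        "0 0   ! excluded maternal / paternal sibships",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["id", "waterbody", "capture_date", "sex",
                    "carapace_length_mm", "stage", "mother_id"]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False, columns=METADATA_COLUMNS)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"id": str, "mother_id": str},
                       keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks columns {missing}")
    return meta


def write_pedigree(pedigree, path) -> None:
    off = pedigree.offspring.copy()
    off = off.rename(columns={"id": "offspring_id", "dam": "dam_id",
                              "sire": "sire_id"})
    off.to_csv(path, index=False,
               columns=["offspring_id", "dam_id", "sire_id", "cohort",
                        "birth_date"])


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"offspring_id": str, "dam_id": str,
                                    "sire_id": str})
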