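"""SNP and genotype-call quality filtering.

The cascade mirrors a RAD-capture pedigree workflow: site-level
prefilters (QUAL, minor allele count, near-total missingness, very low
read counts), removal of failed samples, a per-genotype depth mask,
locus call-rate, excess-heterozygosity and allele-balance screens, an
optional one-SNP-per-RAD-tag selection, and finally one of three regime
presets:

``panel``
    stop after the shared cascade (marker-panel development).
``juvenile``
    drop individuals >50% missing, mask calls below 20 reads, keep
    MAF >= 0.005 (cohort / breeder-number analyses).
``paternity``
    drop individuals >75% missing, mask calls below 20 reads, keep
    MAF >= 0.3 (berried-female clutch analyses).

Site statistics (MAC, MAF, call rate, heterozygosity, allele balance)
are recomputed at the step where each is applied, on the calls surviving
at that point.  "Greater than" thresholds are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = ["FilterConfig", "FilterReport", "allele_balance",
           "filter_cascade", "select_one_snp_per_tag", "REGIMES"]

REGIMES = ("panel", "juvenile", "paternity")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults are the standard RAD
    pedigree values; ``max_individual_missing`` and ``min_maf`` are taken
    from the regime when left as None)."""

    min_site_qual: float = 20.0
    min_minor_allele_count: int = 3
    max_site_missing_prefilter: float = 0.99    # strictly greater fails
    min_genotype_depth_prefilter: int = 3       # drop calls with <= 2 reads
    max_individual_missing_prefilter: float = 0.99
    min_genotype_depth: int = 7
    min_locus_call_rate: float = 0.75
    max_obs_het: float = 0.6
    allele_balance_bounds: tuple[float, float] = (0.4, 0.6)
    one_snp_per_tag: bool = True
    max_individual_missing: float | None = None  # 0.5 juvenile / 0.75 paternity
    min_depth_regime: int = 20
    min_maf: float | None = None                 # 0.005 juvenile / 0.3 paternity
    depth20_per_genotype: bool = True            # else per-site mean depth

    def resolved(self, regime: str) -> "FilterConfig":
        cfg = FilterConfig(**{f: getattr(self, f) for f in self.__dataclass_fields__})
        if regime == "juvenile":
            cfg.max_individual_missing = (0.5 if self.max_individual_missing is None
                                          else self.max_individual_missing)
            cfg.min_maf = 0.005 if self.min_maf is None else self.min_maf
        elif regime == "paternity":
            cfg.max_individual_missing = (0.75 if self.max_individual_missing is None
                                          else self.max_individual_missing)
            cfg.min_maf = 0.3 if self.min_maf is None else self.min_maf
        return cfg


@dataclass
class FilterReport:
    """Per-step removal counts; ``sum of removals + survivors = input``
    holds separately for sites, individuals, and genotype calls."""

    steps: list[dict] = field(default_factory=list)
    input_shape: tuple[int, int] = (0, 0)
    output_shape: tuple[int, int] = (0, 0)

    def record(self, step: str, *, sites: int = 0, individuals: int = 0,
               calls: int = 0, skipped: bool = False, note: str = "") -> None:
        self.steps.append({"step": step, "sites_removed": int(sites),
                           "individuals_removed": int(individuals),
                           "calls_masked": int(calls),
                           "skipped": skipped, "note": note})

    def removed(self, step: str) -> int:
        for s in self.steps:
            if s["step"] == step:
                return s["sites_removed"] or s["individuals_removed"] or s["calls_masked"]
        raise KeyError(step)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def allele_balance(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site ref-read fraction over heterozygous calls with AD.

    AB = sum(AD_ref) / sum(AD_ref + AD_alt) across het calls.  Sites with
    no het call carrying reads are NaN (exempt from the AB screen).
    """
    if gm.ad_ref is None or gm.ad_alt is None:
        return np.full(gm.n_loci, np.nan)
    het = gm.dosage == 1
    ref = np.where(het, gm.ad_ref, 0).sum(axis=0).astype(float)
    tot = ref + np.where(het, gm.ad_alt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, ref / tot, np.nan)


def _mask_calls(gm: GenotypeMatrix, bad: np.ndarray) -> int:
    """Set calls where ``bad`` (and currently called) to missing in place."""
    bad = bad & gm.called
    gm.dosage[bad] = MISSING
    return int(bad.sum())


def filter_cascade(gm: GenotypeMatrix, config: FilterConfig | None = None,
                   regime: str = "panel"
                   ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full cascade; returns the filtered matrix and a report.

    Removing every site is reported, not raised.  Depth-based steps are
    recorded as skipped when the matrix carries no DP.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    cfg = (config or FilterConfig()).resolved(regime)
    out = gm.copy()
    rep = FilterReport(input_shape=(gm.n_individuals, gm.n_loci))

    # 1. site QUAL
    qual = out.loci["qual"].to_numpy(dtype=float)
    keep = ~(qual < cfg.min_site_qual)  # NaN QUAL is exempt
    rep.record("site_qual", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 2. minor allele count
    keep = out.minor_allele_count() >= cfg.min_minor_allele_count
    rep.record("minor_allele_count", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 3. site missingness prefilter (> threshold fails)
    keep = ~(out.locus_missingness() > cfg.max_site_missing_prefilter)
    rep.record("site_missing_prefilter", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 4. very-low-read genotype calls
    if out.dp is not None:
        n = _mask_calls(out, out.dp < cfg.min_genotype_depth_prefilter)
        rep.record("depth_prefilter_mask", calls=n)
    else:
        rep.record("depth_prefilter_mask", skipped=True, note="no DP")

    # 5. failed individuals
    keep_ind = ~(out.individual_missingness()
                 > cfg.max_individual_missing_prefilter)
    rep.record("individual_missing_prefilter", individuals=(~keep_ind).sum())
    out = out.take_individuals(keep_ind)

    # 6. depth-7 genotype mask
    if out.dp is not None:
        n = _mask_calls(out, out.dp < cfg.min_genotype_depth)
        rep.record("depth7_mask", calls=n)
    else:
        rep.record("depth7_mask", skipped=True, note="no DP")

    # 7. locus call rate
    keep = (1.0 - out.locus_missingness()) >= cfg.min_locus_call_rate
    rep.record("locus_call_rate", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 8. excess observed heterozygosity (> threshold fails)
    het = out.obs_het()
    keep = ~(het > cfg.max_obs_het)
    rep.record("obs_het", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 9. allele balance outside bounds (sites without het AD are exempt)
    ab = allele_balance(out)
    lo, hi = cfg.allele_balance_bounds
    keep = ~((ab < lo) | (ab > hi))
    keep |= np.isnan(ab)
    rep.record("allele_balance", sites=(~keep).sum())
    out = out.take_loci(keep)

    # 10. one SNP per RAD tag
    if cfg.one_snp_per_tag:
        before = out.n_loci
        out = select_one_snp_per_tag(out)
        rep.record("one_snp_per_tag", sites=before - out.n_loci)
    else:
        rep.record("one_snp_per_tag", skipped=True)

    # regime-specific screens
    if regime in ("juvenile", "paternity"):
        keep_ind = ~(out.individual_missingness() > cfg.max_individual_missing)
        rep.record("individual_missing_regime", individuals=(~keep_ind).sum())
        out = out.take_individuals(keep_ind)

        if out.dp is not None:
            if cfg.depth20_per_genotype:
                n = _mask_calls(out, out.dp < cfg.min_depth_regime)
                rep.record("depth20_mask", calls=n)
            else:
                with np.errstate(invalid="ignore"):
                    mean_dp = np.where(out.called, out.dp, np.nan)
                    mean_dp = np.nanmean(mean_dp, axis=0)
                keep = ~(mean_dp < cfg.min_depth_regime)
                rep.record("depth20_mask", sites=(~keep).sum(),
                           note="per-site mean depth")
                out = out.take_loci(keep)
        else:
            rep.record("depth20_mask", skipped=True, note="no DP")

        keep = out.maf() >= cfg.min_maf
        rep.record("maf_regime", sites=(~keep).sum())
        out = out.take_loci(keep)

    # fixpoint re-screen: depth masking can push sites / individuals that
    # passed an earlier screen back below threshold, so the site and
    # individual screens are re-applied on the final call set until
    # stable.  This makes the cascade idempotent and guarantees that the
    # output satisfies every screen simultaneously.
    for _ in range(20):
        if out.n_loci == 0:
            break
        removed = 0
        if regime in ("juvenile", "paternity"):
            keep_ind = ~(out.individual_missingness()
                         > cfg.max_individual_missing)
            removed += int((~keep_ind).sum())
            out = out.take_individuals(keep_ind)
        keep = out.minor_allele_count() >= cfg.min_minor_allele_count
        keep &= (1.0 - out.locus_missingness()) >= cfg.min_locus_call_rate
        with np.errstate(invalid="ignore"):
            keep &= ~(out.obs_het() > cfg.max_obs_het)
            ab = allele_balance(out)
            lo, hi = cfg.allele_balance_bounds
            keep &= ~((ab < lo) | (ab > hi)) | np.isnan(ab)
            if regime in ("juvenile", "paternity"):
                keep &= out.maf() >= cfg.min_maf
        removed += int((~keep).sum())
        out = out.take_loci(keep)
        if removed == 0:
            break
    rep.record("rescreen_fixpoint",
               sites=rep.input_shape[1] - out.n_loci
               - sum(s["sites_removed"] for s in rep.steps))

    rep.output_shape = (out.n_individuals, out.n_loci)
    return out, rep


def select_one_snp_per_tag(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one SNP per RAD tag: the least missing, then the highest MAF,
    then the first (lowest-position) SNP."""
    miss = gm.locus_missingness()
    maf = np.nan_to_num(gm.maf(), nan=-1.0)
    tab = pd.DataFrame({
        "tag": gm.loci["tag"].to_numpy(),
        "miss": miss,
        "neg_maf": -maf,
        "pos": gm.loci["pos"].to_numpy(),
        "idx": np.arange(gm.n_loci),
    })
    winners = (tab.sort_values(["tag", "miss", "neg_maf", "pos"],
                               kind="mergesort")
               .groupby("tag", sort=False).head(1)["idx"]
               .sort_values().to_numpy())
    return gm.take_loci(winners)
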