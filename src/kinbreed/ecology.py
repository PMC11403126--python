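"""Cohort assignment, multiple-paternity summaries, shared-parent
detection across cohorts or waterbodies, and before/after treatment
contrasts — the results-facing layer on top of the sibship machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .estimators import NsEstimate, RSResult
from .kinship import InferredPedigree, SibshipPartition
from .simulate import ADULT_CARAPACE_MM

__all__ = ["CohortAssignment", "CohortConfig", "assign_cohorts",
           "MPSummary", "mp_summary", "shared_parents",
           "treatment_contrast"]


# ---------------------------------------------------------------------------
# cohort assignment
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    adult_threshold_mm: float = ADULT_CARAPACE_MM
    season_start_month: int = 8   # captures Aug-Dec of year y and Jan-Jul of
                                  # year y+1 form breeding-season bin y
    min_cohort_size: int = 10


@dataclass
class CohortAssignment:
    """Offspring id -> cohort label, with per-cohort sizes and the
    individuals excluded (with a reason)."""

    cohort_of: dict[str, str]
    sizes: dict[str, int]
    excluded: dict[str, str] = field(default_factory=dict)


def _season_bin(capture: date, start_month: int) -> int:
    return capture.year if capture.month >= start_month else capture.year - 1


def assign_cohorts(metadata: pd.DataFrame,
                   partition: SibshipPartition | None = None,
                   config: CohortConfig | None = None) -> CohortAssignment:
    """Assign juveniles to cohorts from capture season, size, and sibship.

    Individuals at or above the adult carapace threshold are excluded
    ("oversize"), as are rows without a capture date.  Initial bins are
    breeding-season windows; two bins are merged whenever a full-sib pair
    spans them (small fall sibs and their larger spring sibs belong to
    one breeding bout).  Cohorts below ``min_cohort_size`` are dropped
    with reason "tiny cohort".  Assignment is stable under permutation of
    the metadata row order.
    """
    cfg = config or CohortConfig()
    excluded: dict[str, str] = {}
    bins: dict[str, int] = {}
    for r in metadata.sort_values("id").itertuples(index=False):
        if r.stage == "adult" or (pd.notna(r.carapace_length_mm)
                                  and r.carapace_length_mm >= cfg.adult_threshold_mm):
            excluded[r.id] = "oversize"
            continue
        if not r.capture_date or pd.isna(r.capture_date):
            excluded[r.id] = "missing capture date"
            continue
        cap = date.fromisoformat(str(r.capture_date))
        bins[r.id] = _season_bin(cap, cfg.season_start_month)

    # merge bins spanned by a full-sib pair (union-find over bin labels)
    labels = sorted(set(bins.values()))
    parent = {b: b for b in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if partition is not None:
        for fam in partition.families:
            present = sorted({bins[x] for x in fam if x in bins})
            for a, b in zip(present, present[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    merged = {i: find(b) for i, b in bins.items()}
    sizes_raw: dict[int, int] = {}
    for b in merged.values():
        sizes_raw[b] = sizes_raw.get(b, 0) + 1

    cohort_of: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for i, b in merged.items():
        if sizes_raw[b] < cfg.min_cohort_size:
            excluded[i] = "tiny cohort"
            continue
        label = f"cohort_{b}"
        cohort_of[i] = label
        sizes[label] = sizes.get(label, 0) + 1
    return CohortAssignment(cohort_of=cohort_of, sizes=sizes,
                            excluded=excluded)


# ---------------------------------------------------------------------------
# multiple paternity
# ---------------------------------------------------------------------------

@dataclass
class MPSummary:
    """Per-waterbody means/SDs of screened offspring and inferred sires,
    plus the overall proportion of multiply-sired females."""

    per_waterbody: pd.DataFrame  # waterbody, n_females, mean/sd offspring, mean/sd sires
    per_female: pd.DataFrame     # waterbody, female, n_offspring, n_sires
    prop_multiple: float
    overall_mean_offspring: float
    overall_sd_offspring: float
    overall_mean_sires: float
    overall_sd_sires: float


def mp_summary(clutches: pd.DataFrame) -> MPSummary:
    """Summarize multiple paternity from per-female clutch results.

    ``clutches`` needs columns ``waterbody, female, n_offspring,
    n_sires`` (one row per berried female).  SDs are sample SDs (n-1);
    a female is multiply sired when ``n_sires >= 2``.
    """
    req = {"waterbody", "female", "n_offspring", "n_sires"}
    missing = req - set(clutches.columns)
    if missing:
        raise ValueError(f"clutch table lacks columns {sorted(missing)}")
    if len(clutches) == 0:
        raise ValueError("no clutches")

    def sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")

    rows = []
    for wb, grp in clutches.groupby("waterbody", sort=True):
        rows.append({
            "waterbody": wb,
            "n_females": len(grp),
            "mean_offspring": float(grp["n_offspring"].mean()),
            "sd_offspring": sd(grp["n_offspring"]),
            "mean_sires": float(grp["n_sires"].mean()),
            "sd_sires": sd(grp["n_sires"]),
            "prop_multiple": float((grp["n_sires"] >= 2).mean()),
        })
    per_wb = pd.DataFrame(rows)
    return MPSummary(
        per_waterbody=per_wb,
        per_female=clutches.copy(),
        prop_multiple=float((clutches["n_sires"] >= 2).mean()),
        overall_mean_offspring=float(clutches["n_offspring"].mean()),
        overall_sd_offspring=sd(clutches["n_offspring"]),
        overall_mean_sires=float(clutches["n_sires"].mean()),
        overall_sd_sires=sd(clutches["n_sires"]),
    )


# ---------------------------------------------------------------------------
# shared parents across groups
# ---------------------------------------------------------------------------

def shared_parents(pedigree: InferredPedigree,
                   group_of: dict[str, str]) -> pd.DataFrame:
    """Parents whose offspring span two or more groups (cohorts or
    waterbodies), from one JOINT sibship analysis.

    Parent slots are only comparable within a single inference run, so
    this takes one ``InferredPedigree`` covering all groups plus an
    offspring -> group mapping.  (Passing per-group pedigrees from
    separate runs is a hard error by construction: their slot ids do not
    meet.)  Each returned row is a parent slot with the groups it spans
    and its per-group offspring counts; a companion classification of
    every cross-group sibling pair (FS = both slots shared, HS = one) is
    attached as ``DataFrame.attrs['cross_pairs']``.
    """
    missing = [o for o in pedigree.offspring if o not in group_of]
    if missing:
        raise ValueError(
            f"{len(missing)} offspring lack a group label (e.g. "
            f"{missing[:3]}); joint analysis over all groups required")

    slot_groups: dict[str, dict[str, int]] = {}
    for off, slots in pedigree.offspring.items():
        g = group_of[off]
        for s in slots:
            slot_groups.setdefault(s, {})
            slot_groups[s][g] = slot_groups[s].get(g, 0) + 1

    rows = []
    for s in sorted(slot_groups):
        groups = slot_groups[s]
        if len(groups) >= 2:
            rows.append({"parent_slot": s,
                         "groups": ",".join(sorted(groups)),
                         "n_groups": len(groups),
                         "offspring_counts": dict(sorted(groups.items())),
                         "n_offspring": sum(groups.values())})
    out = pd.DataFrame(rows, columns=["parent_slot", "groups", "n_groups",
                                      "offspring_counts", "n_offspring"])

    cross = []
    offs = sorted(pedigree.offspring)
    for i, a in enumerate(offs):
        sa = set(pedigree.offspring[a])
        ga = group_of[a]
        for b in offs[i + 1:]:
            if group_of[b] == ga:
                continue
            shared = sa & set(pedigree.offspring[b])
            if shared:
                cross.append({"id_i": a, "id_j": b,
                              "relation": "FS" if len(shared) == 2 else "HS",
                              "shared_slots": ",".join(sorted(shared))})
    out.attrs["cross_pairs"] = pd.DataFrame(
        cross, columns=["id_i", "id_j", "relation", "shared_slots"])
    return out


# ---------------------------------------------------------------------------
# treatment contrast
# ---------------------------------------------------------------------------

def treatment_contrast(before: tuple[NsEstimate, RSResult | None],
                       after: tuple[NsEstimate, RSResult | None]) -> dict:
    """Percent change in the Chao breeder asymptote and in rarefied mean
    reproductive success between two cohort-level result sets, with CI
    overlap flags.  Negative change = decline."""
    ns_b, rs_b = before
    ns_a, rs_a = after
    out = {
        "ns_chao_before": ns_b.chao,
        "ns_chao_after": ns_a.chao,
        "ns_chao_pct_change": 100.0 * (ns_a.chao - ns_b.chao) / ns_b.chao,
        "ns_chao_ci_overlap": (abs(ns_a.chao - ns_b.chao)
                               <= 1.96 * (ns_a.se + ns_b.se)),
    }
    if rs_b is not None and rs_a is not None:
        out.update({
            "rs_before": rs_b.mean,
            "rs_after": rs_a.mean,
            "rs_pct_change": 100.0 * (rs_a.mean - rs_b.mean) / rs_b.mean,
            "rs_ci_overlap": not (rs_b.ci[1] < rs_a.ci[0]
                                  or rs_a.ci[1] < rs_b.ci[0]),
        })
    return out
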