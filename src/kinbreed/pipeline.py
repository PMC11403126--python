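"""End-to-end orchestration: simulate (or load) -> filter -> kinship ->
sibship -> cohorts -> estimators -> paternity -> permutation test.

One global seed fans out deterministically to per-stage seeds via
``numpy.random.SeedSequence.spawn``, so a run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, estimators, kinship, qc, vcfio
from .permtest import median_ratio_test
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and switches for one pipeline run.

    Either a simulation scenario (``sim``) or paths to an existing VCF +
    metadata CSV must be provided.
    """

    outdir: str | Path
    sim: SimConfig | None = None
    vcf_path: str | Path | None = None
    metadata_path: str | Path | None = None
    regime: str = "juvenile"
    seed: int = 0
    eps: float = 0.01
    n_boot: int = 200
    rs_n_sub: int = 75
    rs_reps: int = 1000
    n_perm: int = 1000
    min_shared_loci: int = 100
    filter_config: qc.FilterConfig = field(default_factory=qc.FilterConfig)


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a results manifest.

    Returns the manifest dict; it is also written to
    ``outdir/manifest.json`` together with per-stage CSV reports.  Every
    threshold in effect is logged and recorded in the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 6)
    manifest: dict = {"seed": config.seed, "regime": config.regime,
                      "thresholds": {
                          "eps": config.eps,
                          "min_shared_loci": config.min_shared_loci,
                          "rs_n_sub": config.rs_n_sub,
                      }}

    # --- stage: inputs -----------------------------------------------------
    if config.sim is not None:
        sim = config.sim
        sim.seed = seeds[0]
        ped, _true_gm, gm, meta = simulate_dataset(sim)
        manifest["input"] = {"mode": "simulated",
                             "n_offspring_true": int(ped.n_offspring)}
        vcfio.write_vcf(gm, out / "simulated.vcf")
        vcfio.write_metadata(meta, out / "metadata.csv")
        vcfio.write_pedigree(ped, out / "true_pedigree.csv")
    else:
        if config.vcf_path is None or config.metadata_path is None:
            raise FileNotFoundError(
                "vcf_path and metadata_path are required when no simulation "
                "scenario is given")
        for p in (config.vcf_path, config.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        gm = vcfio.read_vcf(config.vcf_path)
        meta = vcfio.read_metadata(config.metadata_path)
        manifest["input"] = {"mode": "files", "vcf": str(config.vcf_path)}

    # --- stage: filter -----------------------------------------------------
    try:
        filtered, report = qc.filter_cascade(gm, config.filter_config,
                                             regime=config.regime)
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'filter' failed: {e}") from e
    report.as_frame().to_csv(out / "filter_report.csv", index=False)
    manifest["filter"] = {"input_shape": list(report.input_shape),
                          "output_shape": list(report.output_shape)}

    # --- stage: kinship + sibship on juveniles ------------------------------
    meta_idx = meta.set_index("id")
    juveniles = [i for i in filtered.ids
                 if i in meta_idx.index
                 and meta_idx.at[i, "stage"] == "juvenile"]
    if len(juveniles) < 2:
        raise RuntimeError("stage 'kinship' failed: fewer than 2 juveniles "
                           "after filtering")
    juv = filtered.select_ids(juveniles)
    calls = kinship.classify_pairs(juv, eps=config.eps,
                                   min_shared_loci=config.min_shared_loci)
    calls.to_csv(out / "pair_calls.csv", index=False)
    partition = kinship.build_sibship(calls)
    inferred = kinship.infer_parents(partition)
    manifest["sibship"] = {"n_families": len(partition.families),
                           "q_fs": round(partition.q_fs, 6),
                           "q_hs": round(partition.q_hs, 6),
                           "ns": inferred.ns}

    # --- stage: cohorts ------------------------------------------------------
    assign = ecology.assign_cohorts(meta[meta["id"].isin(juveniles)],
                                    partition)
    manifest["cohorts"] = {"sizes": dict(sorted(assign.sizes.items())),
                           "n_excluded": len(assign.excluded)}

    # --- stage: estimators (per cohort and combined) -------------------------
    phi = kinship.king_matrix(juv.dosage)
    cohort_results = {}
    groups = {"combined": juveniles}
    for label in sorted(assign.sizes):
        groups[label] = [i for i in juveniles
                         if assign.cohort_of.get(i) == label]
    for label, members in groups.items():
        if len(members) < 10:
            continue
        sub_part = _restrict_partition(partition, members)
        sub_inf = kinship.infer_parents(sub_part)
        res: dict = {"sample_size": len(members)}
        nb_w = estimators.nb_sibship(sub_part, n_boot=config.n_boot,
                                     seed=seeds[1])
        res["nb_wang"] = _nb_dict(nb_w)
        try:
            nb_l = estimators.nb_ld(juv.select_ids(members))
            res["nb_ld"] = _nb_dict(nb_l)
        except ValueError as e:
            res["nb_ld"] = {"error": str(e)}
        ns = estimators.ns_chao(sub_inf, seed=seeds[2])
        res["ns"] = ns.ns
        res["ns_chao"] = round(ns.chao, 3)
        res["ns_chao_se"] = round(ns.se, 3)
        if len(members) >= config.rs_n_sub:
            rs = estimators.rarefied_rs(sub_inf, n_sub=config.rs_n_sub,
                                        reps=config.rs_reps, seed=seeds[3])
            res["rs"] = {"mean": round(rs.mean, 4), "sd": round(rs.sd, 4),
                         "ci": [round(rs.ci[0], 4), round(rs.ci[1], 4)]}
        res["theta"] = round(estimators.coancestry(sub_part).theta, 6)
        res["offspring_per_parent"] = round(
            estimators.offspring_per_parent(len(members), sub_inf.ns), 4)
        cohort_results[label] = res
    manifest["estimates"] = cohort_results

    # --- stage: shared parents across cohorts --------------------------------
    labelled = {i: assign.cohort_of[i] for i in juveniles
                if i in assign.cohort_of}
    if len(set(labelled.values())) >= 2:
        joint = kinship.infer_parents(
            _restrict_partition(partition, list(labelled)))
        shared = ecology.shared_parents(joint, labelled)
        shared.drop(columns=["offspring_counts"]).to_csv(
            out / "shared_parents.csv", index=False)
        manifest["shared_parents"] = {"n_shared": len(shared)}

    # --- stage: permutation test between the two largest cohorts -------------
    ordered = sorted(assign.sizes, key=assign.sizes.get, reverse=True)
    if len(ordered) >= 2:
        a, b = ordered[0], ordered[1]
        members = {i: lab for i, lab in labelled.items() if lab in (a, b)}
        idx = [juveniles.index(i) for i in members]
        sub_phi = phi[np.ix_(idx, idx)]
        labs = [members[juveniles[i]] for i in idx]
        r = median_ratio_test(sub_phi, labs, a, b, n_perm=config.n_perm,
                              seed=seeds[4])
        manifest["median_ratio_test"] = {
            "groups": [a, b], "statistic": round(r.statistic, 6),
            "p_value": round(r.p_value, 6), "n_perm": r.n_perm}

    # --- stage: multiple paternity on simulated clutches ----------------------
    if config.sim is not None:
        mp = _simulated_paternity(ped, filtered, config, seeds[5])
        if mp is not None:
            summary, table = mp
            table.to_csv(out / "clutch_sires.csv", index=False)
            manifest["multiple_paternity"] = {
                "n_females": len(table),
                "mean_sires": round(summary.overall_mean_sires, 4),
                "prop_multiple": round(summary.prop_multiple, 4)}

    text = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(text + "\n")
    return manifest


def _restrict_partition(partition, members: list[str]):
    wanted = set(members)
    families = []
    keep_idx = []
    for k, fam in enumerate(partition.families):
        sub = [x for x in fam if x in wanted]
        if sub:
            keep_idx.append(k)
            families.append(sub)
    remap = {old: new for new, old in enumerate(keep_idx)}
    hs = {}
    for (a, b), w in partition.hs_edges.items():
        if a in remap and b in remap:
            hs[(remap[a], remap[b])] = w
    from .kinship import SibshipPartition, _pair_q
    q_fs, q_hs = _pair_q(families, hs)
    return SibshipPartition(families=families, hs_edges=hs, q_fs=q_fs,
                            q_hs=q_hs)


def _nb_dict(nb) -> dict:
    def f(x):
        return "inf" if np.isinf(x) else round(float(x), 3)
    return {"point": f(nb.point), "ci": [f(nb.ci[0]), f(nb.ci[1])]}


def _simulated_paternity(ped, gm, config: RunConfig, seed: int):
    """Cluster true clutches (dam x cohort groups with >= 5 sampled
    offspring) by paternity using the known-mother machinery."""
    rng = np.random.default_rng(seed)
    have = set(gm.ids)
    off = ped.offspring[ped.offspring["id"].isin(have)]
    ids = {x: k for k, x in enumerate(gm.ids)}
    rows = []
    for (dam, cohort), grp in off.groupby(["dam", "cohort"]):
        if len(grp) < 5 or dam not in ids:
            continue
        clutch = gm.select_ids(list(grp["id"]))
        part = kinship.count_sires(gm.dosage[ids[dam]], clutch,
                                   allele_freqs=gm.alt_freq(),
                                   eps=config.eps)
        rows.append({"waterbody": "sim", "female": f"{dam}_c{cohort}",
                     "n_offspring": len(grp), "n_sires": part.n_sires,
                     "true_sires": grp["sire"].nunique()})
        if len(rows) >= 12:
            break
    if not rows:
        return None
    table = pd.DataFrame(rows)
    return ecology.mp_summary(table), table
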