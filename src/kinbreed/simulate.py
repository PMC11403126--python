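"""Synthetic mating-system simulator with ground-truth pedigrees.

Emulates a polygamous, dioecious crayfish-like breeding system: each
breeding female mates with a zero-truncated-Poisson number of males,
paternity shares within her clutch follow a Dirichlet draw (small
concentration = one dominant sire), clutch sizes are negative binomial,
and a configurable fraction of one cohort's breeders also breeds in the
next cohort.  Genotypes arise by Mendelian gene dropping from founders in
Hardy-Weinberg proportions; an observation layer adds per-allele
genotyping error, negative-binomial read depth, depth-dependent
missingness, and synthesized site quality scores.  Carapace length grows
linearly with age so that cohorts are separable from size x capture date.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "TruePedigree",
    "simulate_breeding",
    "simulate_genotypes",
    "apply_observation_model",
    "simulate_growth",
    "simulate_random_mating",
    "simulate_clutch",
    "simulate_dataset",
    "mendelian_drop",
    "zero_truncated_poisson",
    "load_scenario",
    "write_scenario",
    "read_scenario",
]

ADULT_CARAPACE_MM = 20.0  # field convention separating juveniles from adults


@dataclass
class SimConfig:
    """Parameters of the simulated breeding system and observation model.

    Counts must be >= 1, probabilities in [0, 1], and the minor-allele
    frequency range within (0, 0.5].
    """

    n_males: int = 50
    n_females: int = 50
    n_loci: int = 930
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_mates_per_female: float = 2.8  # zero-truncated Poisson parameter
    male_skew_concentration: float = 0.5  # Dirichlet conc.; small = dominant sire
    clutch_size_mean: float = 8.0
    clutch_size_dispersion: float = 2.0  # negative binomial size parameter
    n_cohorts: int = 1
    parent_carryover_prob: float = 0.0
    error_rate: float = 0.01  # per-allele genotyping error
    mean_depth: float = 28.0
    depth_dispersion: float = 15.0
    missing_rate: float = 0.02  # base dropout on top of depth-0 calls
    qual_fail_rate: float = 0.02  # fraction of sites synthesized with QUAL < 20
    growth_intercept_mm: float = 5.0
    growth_rate_mm_per_day: float = 0.05
    growth_sd_mm: float = 2.0
    snps_per_tag: int = 1
    n_chromosomes: int = 94
    waterbody: str = "pond1"
    birth_date0: date = date(2020, 9, 1)
    cohort_spacing_days: int = 300
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_males", "n_females", "n_loci", "n_cohorts",
                     "snps_per_tag", "n_chromosomes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1 (empty breeding pool)"
                                 if name in ("n_males", "n_females")
                                 else f"{name} must be >= 1")
        for name in ("parent_carryover_prob", "missing_rate", "qual_fail_rate",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        for name in ("mean_mates_per_female", "male_skew_concentration",
                     "clutch_size_mean", "clutch_size_dispersion",
                     "mean_depth", "depth_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruePedigree:
    """Ground-truth pedigree: one dam and one sire per offspring.

    ``offspring`` columns: id, dam, sire, cohort, birth_date.
    ``parents`` columns: id, sex ('F' or 'M').
    """

    offspring: pd.DataFrame
    parents: pd.DataFrame

    def __post_init__(self) -> None:
        sex = dict(zip(self.parents["id"], self.parents["sex"]))
        dams = self.offspring["dam"].map(sex)
        sires = self.offspring["sire"].map(sex)
        if not (dams == "F").all() or not (sires == "M").all():
            raise ValueError("dam must be female and sire male for every offspring")

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    @property
    def parent_ids(self) -> list[str]:
        return list(self.parents["id"])

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.offspring["id"])

    def contributing_parents(self, cohort: int | None = None) -> set[str]:
        off = self.offspring
        if cohort is not None:
            off = off[off["cohort"] == cohort]
        return set(off["dam"]) | set(off["sire"])


# ---------------------------------------------------------------------------
# breeding
# ---------------------------------------------------------------------------

def zero_truncated_poisson(lam: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Sample from Poisson(lam) conditioned on being >= 1.

    As lam -> 0 the distribution degenerates to the point mass at 1.
    """
    if lam <= 1e-9:
        return np.ones(size, dtype=np.int64)
    p0 = np.exp(-lam)
    u = rng.uniform(size=size)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)


def _negbin(mean: float, dispersion: float, size: int,
            rng: np.random.Generator) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_breeding(config: SimConfig,
                      rng: np.random.Generator | None = None) -> TruePedigree:
    """Draw a multi-cohort pedigree under the polygamous mating model.

    Per cohort, each breeding female mates with ``m ~ ZTPoisson(lambda)``
    males; her clutch size is negative binomial (floored at 1) and each
    mate receives at least one offspring when the clutch allows, the
    remainder split by Dirichlet shares.  A fraction
    ``parent_carryover_prob`` of one cohort's breeders (dams and realized
    sires) is forced to breed again in the next cohort; the rest of each
    cohort's breeding pool is drawn from never-bred adults, so carryover 0
    gives disjoint parental pools and carryover 1 re-uses every breeder.
    """
    config.validate()
    if rng is None:
        rng = config.rng()

    females = [f"F{i:04d}" for i in range(config.n_females)]
    males = [f"M{i:04d}" for i in range(config.n_males)]
    p_carry = config.parent_carryover_prob

    # pool size per cohort chosen so the whole adult pool is used across
    # cohorts in expectation
    denom = 1.0 + (config.n_cohorts - 1) * (1.0 - p_carry)
    n_f = max(1, int(round(config.n_females / denom)))
    n_m = max(1, int(round(config.n_males / denom)))

    unused_f = list(rng.permutation(females))
    unused_m = list(rng.permutation(males))

    rows = []
    counter = 0
    prev_dams: list[str] = []
    prev_sires: list[str] = []
    for cohort in range(config.n_cohorts):
        carried_f = [f for f in prev_dams if rng.uniform() < p_carry]
        carried_m = [m for m in prev_sires if rng.uniform() < p_carry]
        dams = list(carried_f)
        while len(dams) < n_f and unused_f:
            dams.append(unused_f.pop())
        sire_pool = list(carried_m)
        while len(sire_pool) < n_m and unused_m:
            sire_pool.append(unused_m.pop())
        if not dams or not sire_pool:
            raise ValueError("empty breeding pool")

        n_mates = zero_truncated_poisson(config.mean_mates_per_female,
                                         len(dams), rng)
        mates: list[list[str]] = []
        for i, dam in enumerate(dams):
            m = min(int(n_mates[i]), len(sire_pool))
            chosen = list(rng.choice(sire_pool, size=m, replace=False))
            mates.append(chosen)
        # carried sires are guaranteed to breed again: distribute any not
        # already drawn as forced extra mates, round-robin over females
        pending = [m for m in carried_m
                   if not any(m in ms for ms in mates)]
        if pending:
            order = rng.permutation(len(dams))
            for k, sire in enumerate(pending):
                mates[order[k % len(dams)]].append(sire)

        clutch_sizes = np.maximum(
            _negbin(config.clutch_size_mean, config.clutch_size_dispersion,
                    len(dams), rng), 1)
        birth = config.birth_date0 + timedelta(
            days=cohort * config.cohort_spacing_days)
        cohort_sires: set[str] = set()
        for i, dam in enumerate(dams):
            ms = mates[i]
            size = int(clutch_sizes[i])
            if size < len(ms):
                ms = list(rng.choice(ms, size=size, replace=False))
            shares = rng.dirichlet(
                np.full(len(ms), config.male_skew_concentration))
            counts = np.ones(len(ms), dtype=np.int64)
            extra = size - len(ms)
            if extra > 0:
                counts += rng.multinomial(extra, shares)
            for sire, k in zip(ms, counts):
                cohort_sires.add(sire)
                for _ in range(int(k)):
                    rows.append((f"J{counter:05d}", dam, sire, cohort, birth))
                    counter += 1
        prev_dams = dams
        prev_sires = sorted(cohort_sires)

    offspring = pd.DataFrame(
        rows, columns=["id", "dam", "sire", "cohort", "birth_date"])
    parents = pd.DataFrame(
        {"id": females + males,
         "sex": ["F"] * len(females) + ["M"] * len(males)})
    return TruePedigree(offspring=offspring, parents=parents)


def simulate_random_mating(n_dams: int, n_sires: int, n_offspring: int,
                           rng: np.random.Generator,
                           cohort: int = 0) -> TruePedigree:
    """Ideal random-mating pedigree: each offspring draws its dam and sire
    uniformly and independently.  Ne = 4*Nm*Nf/(Nm+Nf) for this design."""
    dams = [f"F{i:04d}" for i in range(n_dams)]
    sires = [f"M{i:04d}" for i in range(n_sires)]
    d = rng.integers(0, n_dams, size=n_offspring)
    s = rng.integers(0, n_sires, size=n_offspring)
    offspring = pd.DataFrame({
        "id": [f"J{i:05d}" for i in range(n_offspring)],
        "dam": [dams[i] for i in d],
        "sire": [sires[i] for i in s],
        "cohort": cohort,
        "birth_date": date(2020, 9, 1),
    })
    parents = pd.DataFrame({"id": dams + sires,
                            "sex": ["F"] * n_dams + ["M"] * n_sires})
    return TruePedigree(offspring=offspring, parents=parents)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _locus_table(config: SimConfig) -> pd.DataFrame:
    """Assign loci to RAD tags, chromosomes, and positions."""
    n = config.n_loci
    tag_index = np.arange(n) // config.snps_per_tag
    within = np.arange(n) % config.snps_per_tag
    chrom = tag_index % config.n_chromosomes
    tag_rank = tag_index // config.n_chromosomes  # tag serial within chrom
    pos = 10_000 + tag_rank * 5_000 + within * 60  # tags well separated
    return pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom],
        "pos": (pos + 1).astype(np.int64),
        "ref": "A",
        "alt": "T",
        "qual": 60.0,
        "tag": [f"tag{t:05d}" for t in tag_index],
    })


def mendelian_drop(dam_g: np.ndarray, sire_g: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One offspring genotype from parental dosages: one gamete per parent,
    each gamete carrying ALT with probability dosage/2, independently per
    locus."""
    a = rng.uniform(size=dam_g.shape) < dam_g / 2.0
    b = rng.uniform(size=sire_g.shape) < sire_g / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


def simulate_genotypes(pedigree: TruePedigree, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       founder_freqs: np.ndarray | None = None
                       ) -> GenotypeMatrix:
    """Error-free genotypes by gene dropping.

    Founders (all pedigree parents) are drawn in Hardy-Weinberg
    proportions at ALT frequencies uniform in ``maf_range`` (or the
    supplied ``founder_freqs``); each offspring receives one allele from
    each parent independently per locus.  Rows are parents then offspring.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    L = config.n_loci
    if founder_freqs is None:
        founder_freqs = rng.uniform(config.maf_range[0], config.maf_range[1],
                                    size=L)
    freqs = np.asarray(founder_freqs, dtype=float)

    parent_ids = pedigree.parent_ids
    founder_g = rng.binomial(2, freqs, size=(len(parent_ids), L)).astype(np.int8)
    geno = {pid: founder_g[i] for i, pid in enumerate(parent_ids)}

    off = pedigree.offspring
    child_g = np.empty((len(off), L), dtype=np.int8)
    for i, (dam, sire) in enumerate(zip(off["dam"], off["sire"])):
        child_g[i] = mendelian_drop(geno[dam], geno[sire], rng)

    ids = parent_ids + list(off["id"])
    dosage = np.vstack([founder_g, child_g])
    return GenotypeMatrix(ids=ids, loci=_locus_table(config), dosage=dosage,
                          meta={"founder_freqs": freqs})


def apply_observation_model(gm: GenotypeMatrix, config: SimConfig,
                            rng: np.random.Generator | None = None
                            ) -> GenotypeMatrix:
    """Overlay genotyping error, read depth, missingness, and site QUAL.

    Each of a genotype's two allele copies flips with probability
    ``error_rate``; depth is negative binomial (mean_depth,
    depth_dispersion) and calls at depth 0 — plus a ``missing_rate``
    Bernoulli dropout — are set missing.  Allelic depths are binomial
    given the observed genotype.  Site QUAL is drawn so that a
    ``qual_fail_rate`` fraction of sites falls below the QUAL=20 screen.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    eps = config.error_rate
    g = gm.dosage.astype(np.int64)
    shape = g.shape

    alt_to_ref = rng.binomial(np.maximum(g, 0), eps)
    ref_to_alt = rng.binomial(np.maximum(2 - g, 0), eps)
    obs = np.clip(g - alt_to_ref + ref_to_alt, 0, 2)

    dp = _negbin(config.mean_depth, config.depth_dispersion,
                 int(np.prod(shape)), rng).reshape(shape).astype(np.int32)
    dropout = rng.uniform(size=shape) < config.missing_rate
    miss = (dp == 0) | dropout | (gm.dosage == MISSING)
    dp = np.where(miss, 0, dp)

    p_alt = np.choose(obs, [eps, 0.5, 1.0 - eps])
    ad_alt = rng.binomial(dp, p_alt).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)
    obs = np.where(miss, MISSING, obs).astype(np.int8)
    ad_alt[miss] = 0
    ad_ref[miss] = 0

    loci = gm.loci.copy()
    fails = rng.uniform(size=len(loci)) < config.qual_fail_rate
    qual = np.where(fails, rng.uniform(5.0, 19.9, size=len(loci)),
                    rng.uniform(20.0, 90.0, size=len(loci)))
    loci["qual"] = np.round(qual, 2)

    return GenotypeMatrix(ids=list(gm.ids), loci=loci, dosage=obs, dp=dp,
                          ad_ref=ad_ref, ad_alt=ad_alt, meta=dict(gm.meta))


def simulate_drift_population(n_dams: int, n_sires: int, n_loci: int,
                              n_sample: int, rng: np.random.Generator,
                              n_generations: int = 5,
                              maf_range: tuple[float, float] = (0.05, 0.5),
                              n_chromosomes: int = 10) -> GenotypeMatrix:
    """A cohort sampled from an ideal population of constant breeder number.

    Breeds ``n_dams + n_sires`` random-mating adults for ``n_generations``
    so unlinked-locus linkage disequilibrium reaches the drift-
    recombination equilibrium the LD breeder-number estimator assumes
    (a single generation from LD-free founders carries only ~3/4 of the
    equilibrium LD), then returns ``n_sample`` offspring genotypes.
    """
    freqs = rng.uniform(maf_range[0], maf_range[1], size=n_loci)
    dams = rng.binomial(2, freqs, size=(n_dams, n_loci)).astype(np.int8)
    sires = rng.binomial(2, freqs, size=(n_sires, n_loci)).astype(np.int8)

    def breed(n_children: int) -> np.ndarray:
        d = rng.integers(0, n_dams, size=n_children)
        s = rng.integers(0, n_sires, size=n_children)
        a = rng.uniform(size=(n_children, n_loci)) < dams[d] / 2.0
        b = rng.uniform(size=(n_children, n_loci)) < sires[s] / 2.0
        return (a.astype(np.int8) + b.astype(np.int8))

    for _ in range(n_generations - 1):
        kids = breed(n_dams + n_sires)
        dams, sires = kids[:n_dams], kids[n_dams:]
    sample = breed(n_sample)

    cfg = SimConfig(n_loci=n_loci, n_chromosomes=n_chromosomes)
    return GenotypeMatrix(ids=[f"S{i:04d}" for i in range(n_sample)],
                          loci=_locus_table(cfg), dosage=sample,
                          meta={"founder_freqs": freqs})


def simulate_clutch(n_offspring: int, sire_shares, freqs: np.ndarray,
                    rng: np.random.Generator):
    """A known-mother clutch: mother and sires drawn HWE, offspring split
    among sires by ``sire_shares`` (each sire gets at least one offspring).

    Returns ``(mother_genotype, offspring_dosage, sire_index)``.
    """
    shares = np.asarray(sire_shares, dtype=float)
    shares = shares / shares.sum()
    k = len(shares)
    if n_offspring < k:
        raise ValueError("clutch smaller than number of sires")
    freqs = np.asarray(freqs, dtype=float)
    L = len(freqs)
    mother = rng.binomial(2, freqs).astype(np.int8)
    sires = rng.binomial(2, freqs, size=(k, L)).astype(np.int8)
    counts = np.ones(k, dtype=np.int64)
    counts += rng.multinomial(n_offspring - k, shares)
    sire_index = np.repeat(np.arange(k), counts)
    rng.shuffle(sire_index)
    child = np.empty((n_offspring, L), dtype=np.int8)
    for i, s in enumerate(sire_index):
        child[i] = mendelian_drop(mother, sires[s], rng)
    return mother, child, sire_index


# ---------------------------------------------------------------------------
# phenotypes / metadata
# ---------------------------------------------------------------------------

def simulate_growth(pedigree: TruePedigree, sampling_dates: list[date],
                    config: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample metadata with linear carapace-length growth.

    length_mm = intercept + rate * age_days + Normal(0, sd), floored at
    1 mm.  Each offspring is captured on a random sampling date on or
    after its birth; offspring born after every sampling date are not
    sampled.  Parents are treated as adults hatched one year before the
    first cohort.

    Returns a DataFrame with columns id, waterbody, capture_date, sex,
    carapace_length_mm, stage, mother_id.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    dates = sorted(sampling_dates)
    rows = []

    def length_at(age_days: int) -> float:
        noise = rng.normal(0.0, config.growth_sd_mm) if config.growth_sd_mm > 0 else 0.0
        return max(1.0, config.growth_intercept_mm
                   + config.growth_rate_mm_per_day * age_days + noise)

    for _, r in pedigree.offspring.iterrows():
        eligible = [d for d in dates if d >= r["birth_date"]]
        if not eligible:
            continue  # born after the last sampling date: not sampled
        # trapping targets juveniles: prefer dates within ~9 months of birth
        young = [d for d in eligible
                 if (d - r["birth_date"]).days <= 270] or eligible[:1]
        cap = young[int(rng.integers(0, len(young)))]
        age = (cap - r["birth_date"]).days
        lng = length_at(age)
        rows.append((r["id"], config.waterbody, cap.isoformat(), "unknown",
                     round(lng, 2),
                     "juvenile" if lng < ADULT_CARAPACE_MM else "adult", ""))

    adult_birth = config.birth_date0 - timedelta(days=365)
    for _, r in pedigree.parents.iterrows():
        cap = dates[0]
        age = (cap - adult_birth).days
        lng = max(length_at(age), ADULT_CARAPACE_MM + 1.0)
        rows.append((r["id"], config.waterbody, cap.isoformat(), r["sex"],
                     round(lng, 2), "adult", ""))

    return pd.DataFrame(rows, columns=[
        "id", "waterbody", "capture_date", "sex", "carapace_length_mm",
        "stage", "mother_id"])


def simulate_dataset(config: SimConfig, sampling_dates: list[date] | None = None):
    """Convenience wrapper: pedigree, error-free and observed genotypes,
    and metadata from one seed.  Returns
    ``(pedigree, true_gm, observed_gm, metadata)``."""
    config.validate()
    rng = config.rng()
    ped = simulate_breeding(config, rng)
    true_gm = simulate_genotypes(ped, config, rng)
    obs_gm = apply_observation_model(true_gm, config, rng)
    if sampling_dates is None:
        sampling_dates = [
            config.birth_date0 + timedelta(days=45 + i * config.cohort_spacing_days)
            for i in range(config.n_cohorts)
        ] + [
            config.birth_date0 + timedelta(days=240 + i * config.cohort_spacing_days)
            for i in range(config.n_cohorts)
        ]
    meta = simulate_growth(ped, sampling_dates, config, rng)
    return ped, true_gm, obs_gm, meta


# ---------------------------------------------------------------------------
# scenario files (flat key = value)
# ---------------------------------------------------------------------------

def write_scenario(config: SimConfig, path) -> None:
    lines = []
    for f in dataclasses.fields(SimConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = f"{v[0]},{v[1]}"
        elif isinstance(v, date):
            v = v.isoformat()
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario(path) -> SimConfig:
    kwargs = {}
    types = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    defaults = SimConfig()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in types:
            raise KeyError(f"unknown scenario key: {key}")
        ref = getattr(defaults, key)
        if isinstance(ref, bool):
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(ref, int):
            kwargs[key] = int(val)
        elif isinstance(ref, float):
            kwargs[key] = float(val)
        elif isinstance(ref, tuple):
            a, b = val.split(",")
            kwargs[key] = (float(a), float(b))
        elif isinstance(ref, date):
            kwargs[key] = date.fromisoformat(val)
        else:
            kwargs[key] = val
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def load_scenario(name: str = "hotel1_like") -> SimConfig:
    """Load a bundled scenario (currently ``hotel1_like``: two cohorts with
    20% breeder carryover and a 930-SNP panel) or a path to a scenario
    file."""
    p = Path(name)
    if p.exists():
        return read_scenario(p)
    ref = resources.files("kinbreed").joinpath(f"data/{name}.cfg")
    with resources.as_file(ref) as fp:
        return read_scenario(fp)
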