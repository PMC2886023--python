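"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`simulate_intensities` draws a two-colour loop-design microarray
  experiment directly from the normalization model's generative law: every
  reading is mu + comparison-group effect + gene + array x gene + dye x gene
  + flock x gene + treatment x gene + residual, each random effect an
  independent zero-mean Gaussian with its configured variance, plus any
  planted differential-expression shifts.  The default hybridisation layout
  mirrors the study design: a circular alternate dye-swap loop over the ten
  sub-line x time samples (RH0..SH2) in which every RNA sample is labelled
  once with each dye and appears on exactly two arrays, repeated for three
  biological replicates (two Merino flocks).

* :func:`simulate_population` builds a discrete-generation pedigree and
  draws a heritable 0-5 fleece-rot score: latent liability = fixed effects
  (flock, sex, birth type, rear type, date-of-birth slope) + SNP dosage
  effects + polygenic breeding value (variance ratio h2) + residual, scored
  at four body sites with site noise, each site clamped and rounded to 0-5,
  the animal's score being the maximum over sites.  Genotypes are drawn at
  Hardy-Weinberg proportions at the configured minor-allele frequencies.

Every simulator returns its ground truth so downstream estimators have
parameter-recovery tests, and a single global seed expands into independent
per-stage child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import SUBLINE_TREATMENTS, VarianceComponents


class LoopDesignError(ValueError):
    """The hybridisation layout is not a valid loop."""


# --------------------------------------------------------------------------
# loop design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One labelled RNA sample: a treatment from one flock and replicate."""

    treatment: str
    flock: str
    replicate: int

    @property
    def label(self) -> str:
        return f"{self.treatment}.r{self.replicate}"


def default_loop_design(
    treatments: tuple[str, ...] = SUBLINE_TREATMENTS,
    n_replicates: int = 3,
    flocks: tuple[str, ...] = ("Trangie", "Trangie", "CSIRO"),
) -> list[tuple[str, Sample, Sample]]:
    """Circular alternate dye-swap loop per biological replicate.

    Within a replicate the samples form one directed cycle: array *i*
    hybridises sample *i* in the red channel against sample *i+1* (mod k)
    in the green channel, so each sample intervenes in exactly two
    hybridisations, once per dye.  Replicates get their own arrays; the
    flock of every sample in a replicate is ``flocks[replicate]``.
    """
    if n_replicates > len(flocks):
        raise LoopDesignError("need a flock assignment for every replicate")
    design = []
    for rep in range(n_replicates):
        samples = [Sample(t, flocks[rep], rep) for t in treatments]
        k = len(samples)
        for i in range(k):
            array_id = f"A{rep * k + i + 1:03d}"
            design.append((array_id, samples[i], samples[(i + 1) % k]))
    return design


def validate_loop(design: list[tuple[str, Sample, Sample]]) -> None:
    """Every sample must appear exactly once as red and once as green."""
    red: dict = {}
    green: dict = {}
    for array_id, r, g in design:
        for channel, seen, s in (("red", red, r), ("green", green, g)):
            key = (s.label, s.flock)
            if key in seen:
                raise LoopDesignError(
                    f"sample {s.label} used twice in the {channel} channel "
                    f"(arrays {seen[key]} and {array_id})")
            seen[key] = array_id
    if set(red) != set(green):
        raise LoopDesignError("samples do not each appear once per channel")


# --------------------------------------------------------------------------
# intensity simulation
# --------------------------------------------------------------------------

@dataclass
class ArraySimConfig:
    n_genes: int = 200
    n_blocks_per_array: int = 2
    treatments: tuple[str, ...] = SUBLINE_TREATMENTS
    n_replicates: int = 3
    flocks: tuple[str, ...] = ("Trangie", "Trangie", "CSIRO")
    loop_design: list[tuple[str, Sample, Sample]] | None = None
    true_components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(
            sigma2_G=4.0, sigma2_AG=0.3, sigma2_DG=0.1, sigma2_FG=0.1,
            sigma2_TG=0.2, sigma2_e=0.25))
    mu: float = 8.2
    sigma_C: float = 0.5          # spread of comparison-group (slide/block/dye) offsets
    planted_de: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def resolved_design(self):
        d = self.loop_design if self.loop_design is not None else default_loop_design(
            self.treatments, self.n_replicates, self.flocks)
        validate_loop(d)
        for _, r, g in d:
            for s in (r, g):
                if s.treatment not in self.treatments:
                    raise LoopDesignError(f"undeclared treatment {s.treatment!r} in loop")
        return d


@dataclass
class ArraySimTruth:
    components: VarianceComponents
    mu: float
    gene_effects: pd.Series
    array_gene: pd.DataFrame
    dye_gene: pd.DataFrame
    flock_gene: pd.DataFrame
    treatment_gene: pd.DataFrame   # includes planted shifts
    comparison_group: pd.Series


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically expand one global seed into independent child seeds
    (each below 2**31 so they remain portable integers)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_intensities(cfg: ArraySimConfig) -> tuple[pd.DataFrame, ArraySimTruth]:
    """Draw one observation per (array, dye, gene) from the generative model.

    Genes are assigned to printing blocks round-robin (a gene sits at the
    same block position on every slide, as printed arrays do).  Returns the
    long observation table and the ground-truth effect values.
    """
    design = cfg.resolved_design()
    rng = np.random.default_rng(child_seeds(cfg.seed, 1)[0])
    comps = cfg.true_components

    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    arrays = [a for a, _, _ in design]
    dyes = ["red", "green"]
    flocks = sorted({s.flock for _, r, g in design for s in (r, g)})
    treatments = list(cfg.treatments)
    blocks = [f"b{j + 1}" for j in range(cfg.n_blocks_per_array)]
    gene_block = {g: blocks[i % len(blocks)] for i, g in enumerate(genes)}

    sd = np.sqrt
    G = pd.Series(rng.normal(0, sd(comps.sigma2_G), cfg.n_genes), index=genes)
    AG = pd.DataFrame(rng.normal(0, sd(comps.sigma2_AG), (cfg.n_genes, len(arrays))),
                      index=genes, columns=arrays)
    DG = pd.DataFrame(rng.normal(0, sd(comps.sigma2_DG), (cfg.n_genes, 2)),
                      index=genes, columns=dyes)
    FG = pd.DataFrame(rng.normal(0, sd(comps.sigma2_FG), (cfg.n_genes, len(flocks))),
                      index=genes, columns=flocks)
    TG = pd.DataFrame(rng.normal(0, sd(comps.sigma2_TG), (cfg.n_genes, len(treatments))),
                      index=genes, columns=treatments)
    for gene, shifts in cfg.planted_de.items():
        for trt, shift in shifts.items():
            if not np.isfinite(shift):
                raise ValueError("planted_de shifts must be finite")
            TG.loc[gene, trt] += shift

    c_index = pd.MultiIndex.from_product([arrays, blocks, dyes],
                                         names=["array_id", "block_id", "dye"])
    C = pd.Series(rng.normal(0, cfg.sigma_C, len(c_index)), index=c_index)

    rows = []
    for array_id, s_red, s_green in design:
        for dye, s in (("red", s_red), ("green", s_green)):
            for gene in genes:
                rows.append((array_id, gene_block[gene], dye, gene, s.flock, s.treatment))
    obs = pd.DataFrame(rows, columns=["array_id", "block_id", "dye", "gene_id",
                                      "flock_id", "treatment_id"])
    n = len(obs)
    y = (cfg.mu
         + C.loc[pd.MultiIndex.from_frame(obs[["array_id", "block_id", "dye"]])].to_numpy()
         + G.loc[obs["gene_id"]].to_numpy()
         + AG.to_numpy()[G.index.get_indexer(obs["gene_id"]),
                         AG.columns.get_indexer(obs["array_id"])]
         + DG.to_numpy()[G.index.get_indexer(obs["gene_id"]),
                         DG.columns.get_indexer(obs["dye"])]
         + FG.to_numpy()[G.index.get_indexer(obs["gene_id"]),
                         FG.columns.get_indexer(obs["flock_id"])]
         + TG.to_numpy()[G.index.get_indexer(obs["gene_id"]),
                         TG.columns.get_indexer(obs["treatment_id"])]
         + rng.normal(0, sd(comps.sigma2_e), n))
    obs["log2_intensity"] = y

    truth = ArraySimTruth(components=comps, mu=cfg.mu, gene_effects=G,
                          array_gene=AG, dye_gene=DG, flock_gene=FG,
                          treatment_gene=TG, comparison_group=C)
    return obs, truth


# --------------------------------------------------------------------------
# population simulation
# --------------------------------------------------------------------------

@dataclass
class SnpSpec:
    snp_id: str
    maf: float
    beta: float = 0.0    # additive effect, score units per minor-allele copy

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"MAF of {self.snp_id} must be in (0, 0.5], got {self.maf}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class PopulationSimConfig:
    n_founders: int = 80
    n_generations: int = 3
    offspring_per_mating: int = 4
    h2: float = 0.3
    flock_effects: dict[str, float] = field(
        default_factory=lambda: {"Armidale": 0.0, "Trangie": 0.4})
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {"F": 0.0, "M": -0.2})
    birth_type_effects: dict[str, float] = field(
        default_factory=lambda: {"single": 0.0, "twin": 0.15})
    rear_type_effects: dict[str, float] = field(
        default_factory=lambda: {"single": 0.0, "twin": 0.1})
    dob_slope: float = 0.005        # score units per day of birth within season
    snp_specs: list[SnpSpec] = field(default_factory=list)
    mean_prewet: float = 1.5        # latent liability means on the 0-5 score scale
    mean_postwet: float = 3.0
    latent_sd: float = 1.0          # sd of polygenic + residual liability
    site_noise_sd: float = 0.25
    n_sites: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders")


@dataclass
class PopulationSimTruth:
    breeding_values: pd.Series
    h2: float
    snp_specs: list[SnpSpec]
    latent_prewet: pd.Series
    latent_postwet: pd.Series


def simulate_population(
    cfg: PopulationSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PopulationSimTruth]:
    """Pedigree + phenotypes + genotypes with known breeding values.

    Returns ``(pedigree, phenotypes, genotypes, truth)``.  The pedigree is
    topologically ordered (parents precede offspring); founders have unknown
    parents (``0``).  Phenotypes carry the four raw site scores pre- and
    post-wetting.  Genotype calls are minor-allele dosages 0/1/2.
    """
    seeds = child_seeds(cfg.seed, 3)
    rng_ped = np.random.default_rng(seeds[0])
    rng_gen = np.random.default_rng(seeds[1])
    rng_phe = np.random.default_rng(seeds[2])

    # ---- pedigree: discrete generations, random sire x dam matings
    animals: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sex: list[str] = []
    generation: list[int] = []
    for i in range(cfg.n_founders):
        animals.append(f"an{i + 1:05d}")
        sires.append("0")
        dams.append("0")
        sex.append("M" if i % 2 == 0 else "F")
        generation.append(0)
    counter = cfg.n_founders
    prev = list(range(cfg.n_founders))
    for gen in range(1, cfg.n_generations):
        males = [j for j in prev if sex[j] == "M"]
        females = [j for j in prev if sex[j] == "F"]
        n_matings = max(len(females), 1)
        cur = []
        for m in range(n_matings):
            s = males[int(rng_ped.integers(len(males)))]
            d = females[m % len(females)]
            for _ in range(cfg.offspring_per_mating):
                animals.append(f"an{counter + 1:05d}")
                counter += 1
                sires.append(animals[s])
                dams.append(animals[d])
                sex.append("M" if rng_ped.random() < 0.5 else "F")
                generation.append(gen)
                cur.append(counter - 1)
        prev = cur
    n = len(animals)
    pedigree = pd.DataFrame({"animal_id": animals, "sire_id": sires, "dam_id": dams})

    # ---- breeding values: founders N(0, h2*latent_sd^2); offspring mid-parent
    # plus Mendelian sampling with half the additive variance
    s2a = cfg.h2 * cfg.latent_sd ** 2
    bv = np.zeros(n)
    index = {a: i for i, a in enumerate(animals)}
    for i in range(n):
        if sires[i] == "0":
            bv[i] = rng_phe.normal(0, np.sqrt(s2a)) if s2a > 0 else 0.0
        else:
            mid = 0.5 * (bv[index[sires[i]]] + bv[index[dams[i]]])
            bv[i] = mid + (rng_phe.normal(0, np.sqrt(0.5 * s2a)) if s2a > 0 else 0.0)

    # ---- genotypes at HWE per SNP (alleles drawn independently)
    geno = {}
    for spec in cfg.snp_specs:
        dosage = rng_gen.binomial(1, spec.maf, n) + rng_gen.binomial(1, spec.maf, n)
        geno[spec.snp_id] = dosage
    genotypes = pd.DataFrame(geno, index=pd.Index(animals, name="animal_id")).reset_index()

    # ---- fixed effects
    flocks = list(cfg.flock_effects)
    flock = [flocks[int(rng_phe.integers(len(flocks)))] for _ in range(n)]
    birth = ["single" if rng_phe.random() < 0.7 else "twin" for _ in range(n)]
    rear = [b if rng_phe.random() < 0.9 else ("twin" if b == "single" else "single")
            for b in birth]
    dob = rng_phe.integers(0, 60, n).astype(float)   # day born within the lambing season
    fixed_part = (np.array([cfg.flock_effects[f] for f in flock])
                  + np.array([cfg.sex_effects[s] for s in sex])
                  + np.array([cfg.birth_type_effects[b] for b in birth])
                  + np.array([cfg.rear_type_effects[r] for r in rear])
                  + cfg.dob_slope * (dob - dob.mean()))
    snp_part = np.zeros(n)
    for spec in cfg.snp_specs:
        snp_part += spec.beta * geno[spec.snp_id]

    s2e = (1.0 - cfg.h2) * cfg.latent_sd ** 2
    resid_pre = rng_phe.normal(0, np.sqrt(s2e), n)
    resid_post = rng_phe.normal(0, np.sqrt(s2e), n)
    latent_pre = cfg.mean_prewet + fixed_part + snp_part + bv + resid_pre
    latent_post = cfg.mean_postwet + fixed_part + snp_part + bv + resid_post

    def score_sites(latent, rng):
        sites = latent[:, None] + rng.normal(0, cfg.site_noise_sd, (n, cfg.n_sites))
        return np.clip(np.rint(sites), 0, 5).astype(int)

    pre_sites = score_sites(latent_pre, rng_phe)
    post_sites = score_sites(latent_post, rng_phe)

    phen = pd.DataFrame({
        "animal_id": animals, "flock": flock, "sex": sex, "dob": dob,
        "birth_type": birth, "rear_type": rear})
    for j in range(cfg.n_sites):
        phen[f"prewet_site{j + 1}"] = pre_sites[:, j]
        phen[f"postwet_site{j + 1}"] = post_sites[:, j]

    truth = PopulationSimTruth(
        breeding_values=pd.Series(bv, index=pd.Index(animals, name="animal_id")),
        h2=cfg.h2, snp_specs=list(cfg.snp_specs),
        latent_prewet=pd.Series(latent_pre, index=animals),
        latent_postwet=pd.Series(latent_post, index=animals))
    return pedigree, phen, genotypes, truth
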