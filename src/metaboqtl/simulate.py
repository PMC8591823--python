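"""Synthetic study generator with planted, recorded ground truth.

Emulates a feedlot study of crossbred beef cattle: biallelic autosomal SNP
dosages, systematic-effect covariates (animal type, birth year, herd, pen,
age, six-way genomic breed composition), plasma metabolite concentrations in
micromolar with planted per-SNP and polygenic genetic effects, serial body
weights on a ~14-day grid and daily dry-matter intake with small planted
metabolite effects on the feed-efficiency traits.  A gene annotation and a
GMT gene-set collection are generated alongside so the downstream window
mapping and enrichment stages have a coordinate frame with known planted
genes.

Every quantity that downstream stages are expected to recover is returned in
a :class:`SimulationTruth`.  All randomness flows from ``config.seed``; each
component draws from its own child generator, so e.g. the genotypes produced
by :func:`simulate_genotypes` are identical to the ones inside
:func:`simulate_study` for the same config.

Default magnitudes follow the scale of the emulated study: ~500 animals,
31 metabolites, planted metabolite-trait effects sized so an individual
metabolite explains on the order of 1% of trait variance, and moderate
metabolite heritabilities.  Metabolite concentrations are emitted on the raw
(untransformed) micromolar scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import GenotypeMatrix

TRAIT_NAMES = ("rfi", "dmi", "adg", "mwt")

# rng stream ids per component (children of the top-level seed)
_STREAMS = {"genotypes": 0, "covariates": 1, "metabolites": 2, "feed": 3,
            "annotation": 4, "gene_sets": 5}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    ``causal_plan`` holds (metabolite index, SNP index, effect in uM per
    alternate allele); ``trait_plan`` holds (trait name, metabolite index,
    effect in trait units per uM).  ``metabolite_h2`` is the polygenic
    narrow-sense heritability of each metabolite relative to polygenic +
    residual variance (planted causal SNPs add on top).
    """

    n_animals: int = 493
    n_snps: int = 5000
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_metabolites: int = 31
    causal_plan: list[tuple[int, int, float]] = field(default_factory=list)
    metabolite_h2: float | list[float] = 0.3
    trait_plan: list[tuple[str, int, float]] = field(default_factory=list)
    covariate_levels: dict[str, int] = field(
        default_factory=lambda: {"animal_type": 3, "birth_year": 10, "herd": 5, "pen": 8}
    )
    days_on_test: int = 98
    seed: int = 0
    # magnitudes
    chromosome_length: int = 10_000_000
    metabolite_baseline: float = 100.0  # uM
    metabolite_noise_sd: float = 10.0  # uM, residual SD
    covariate_effect_sd: float = 5.0  # uM per categorical level / breed fraction
    ld_rho: float = 0.0  # AR(1) haplotype correlation between adjacent SNPs
    bw_noise_sd: float = 5.0  # kg, weigh-scale noise
    dmi_noise_sd: float = 0.6  # kg/day, residual intake SD
    dmi_coefficients: tuple[float, float, float] = (0.5, 1.2, 0.09)  # b0, b_adg, b_mwt

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_animals < 2 or self.n_snps < 1:
            raise ConfigError("need n_animals >= 2 and n_snps >= 1")
        if self.days_on_test < 28:
            raise ConfigError("days_on_test must be >= 28")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        h2 = self.h2_vector()
        if ((h2 < 0) | (h2 >= 1)).any():
            raise ConfigError("metabolite heritabilities must lie in [0, 1)")
        for k, j, _ in self.causal_plan:
            if not (0 <= k < self.n_metabolites and 0 <= j < self.n_snps):
                raise ConfigError(f"causal_plan entry out of range: ({k}, {j})")
        for t, k, _ in self.trait_plan:
            if t not in TRAIT_NAMES:
                raise ConfigError(f"unknown trait {t!r} in trait_plan")
            if not (0 <= k < self.n_metabolites):
                raise ConfigError(f"trait_plan metabolite index out of range: {k}")

    def h2_vector(self) -> np.ndarray:
        h2 = self.metabolite_h2
        if np.isscalar(h2):
            return np.full(self.n_metabolites, float(h2))
        h2 = np.asarray(h2, dtype=float)
        if h2.shape != (self.n_metabolites,):
            raise ConfigError("metabolite_h2 list length must equal n_metabolites")
        return h2

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[component]])

    def metabolite_names(self) -> list[str]:
        width = len(str(self.n_metabolites))
        return [f"metab_{k + 1:0{width}d}" for k in range(self.n_metabolites)]


@dataclass
class SimulationTruth:
    """Planted ground truth, filled in as components are generated."""

    causal_plan: list[tuple[int, int, float]]
    causal_snp_ids: dict[str, list[str]]  # metabolite name -> SNP ids
    trait_plan: list[tuple[str, int, float]]
    polygenic: np.ndarray = field(repr=False)  # animals x metabolites
    metabolite_base_var: np.ndarray  # polygenic + residual variance per metabolite
    planted_genes: dict[str, list[str]] = field(default_factory=dict)
    latent_adg: np.ndarray | None = field(default=None, repr=False)
    latent_initial_bw: np.ndarray | None = field(default=None, repr=False)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Biallelic autosomal dosages with per-SNP allele frequencies.

    Frequencies are uniform over ``maf_range``; dosages are binomial(2, p)
    per SNP, independent across SNPs unless ``ld_rho > 0``, in which case the
    two latent haplotypes per animal follow an AR(1) Gaussian copula along
    each chromosome (block-correlated alleles).  Positions are uniform over
    chromosomes 1..n_chromosomes; imputation-accuracy scores default to 1.
    """
    rng = config.rng("genotypes")
    m, n = config.n_snps, config.n_animals
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    # chromosome assignment: round-robin block split, positions sorted
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for c, idx in enumerate(per_chrom, start=1):
        chrom[idx] = str(c)
        pos[idx] = np.sort(
            rng.choice(config.chromosome_length, size=len(idx), replace=False) + 1
        )

    if config.ld_rho == 0:
        dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    else:
        from scipy import stats as _st

        thresh = _st.norm.ppf(p)
        dosages = np.zeros((n, m))
        for idx in per_chrom:  # AR(1) within chromosome, independent across
            k = len(idx)
            for _hap in range(2):
                z = np.empty((n, k))
                z[:, 0] = rng.standard_normal(n)
                innov = rng.standard_normal((n, k - 1)) if k > 1 else None
                for j in range(1, k):
                    z[:, j] = config.ld_rho * z[:, j - 1] + np.sqrt(
                        1 - config.ld_rho**2
                    ) * innov[:, j - 1]
                dosages[:, idx] += (z < thresh[idx]).astype(float)

    snps = pd.DataFrame(
        {
            "id": [f"snp_{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "accuracy": 1.0,
        }
    )
    samples = [f"animal_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Systematic-effect table: type, birth year, herd, pen, age, breed mix.

    Animal types follow the emulated population's bull/heifer/steer mix;
    breed composition is Dirichlet(1) over six ancestral components.
    """
    rng = config.rng("covariates")
    n = config.n_animals
    lv = config.covariate_levels
    type_labels = ["bull", "heifer", "steer"][: lv.get("animal_type", 3)]
    type_probs = np.array([93, 125, 275], dtype=float)[: len(type_labels)]
    covars = pd.DataFrame(
        {
            "animal": [f"animal_{i + 1:04d}" for i in range(n)],
            "animal_type": rng.choice(type_labels, size=n, p=type_probs / type_probs.sum()),
            "birth_year": 2002 + rng.integers(0, lv.get("birth_year", 10), size=n),
            "herd": [f"herd_{h + 1}" for h in rng.integers(0, lv.get("herd", 5), size=n)],
            "pen": [f"pen_{h + 1}" for h in rng.integers(0, lv.get("pen", 8), size=n)],
            "age": np.round(rng.normal(270.0, 30.0, size=n)),
        }
    )
    breed = rng.dirichlet(np.ones(6), size=n)
    for k in range(6):
        covars[f"breed{k + 1}"] = breed[:, k]
    return covars


def _systematic_shift(covars: pd.DataFrame, sd: float, rng) -> np.ndarray:
    """One draw of additive fixed covariate effects applied to all animals."""
    shift = np.zeros(len(covars))
    for col in ("animal_type", "birth_year", "herd", "pen"):
        levels = pd.unique(covars[col])
        eff = dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))
        shift += covars[col].map(eff).to_numpy(dtype=float)
    age = covars["age"].to_numpy(dtype=float)
    shift += rng.normal(0.0, sd / 100.0) * (age - age.mean())
    breed_cols = [c for c in covars.columns if c.startswith("breed")]
    shift += covars[breed_cols].to_numpy(dtype=float) @ rng.normal(
        0.0, sd, size=len(breed_cols)
    )
    return shift


def simulate_metabolites(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    covars: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Metabolite concentrations (uM) with planted genetic architecture.

    Each metabolite k is baseline + planted SNP effects + polygenic value +
    systematic covariate shifts + Gaussian noise.  The polygenic value is
    ``Z u`` with Z the frequency-standardized dosages and i.i.d. SNP effects,
    so its covariance matches the genomic relationship matrix; its variance
    is set from ``metabolite_h2`` as s2_a = h2/(1-h2) * noise_sd^2.
    """
    rng = config.rng("metabolites")
    n, m = geno.n_samples, geno.n_snps
    h2 = config.h2_vector()
    s2e = config.metabolite_noise_sd**2
    s2a = h2 / (1.0 - h2) * s2e

    X = geno.mean_imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = np.zeros_like(X)
    Z[:, poly] = (X[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    m_poly = int(poly.sum())

    names = config.metabolite_names()
    values = np.empty((n, config.n_metabolites))
    polygenic = np.zeros((n, config.n_metabolites))
    causal_ids: dict[str, list[str]] = {nm: [] for nm in names}
    for k in range(config.n_metabolites):
        g = np.zeros(n)
        if s2a[k] > 0 and m_poly > 0:
            u = rng.normal(0.0, np.sqrt(s2a[k] / m_poly), size=m)
            u[~poly] = 0.0
            g = Z @ u
        polygenic[:, k] = g
        yk = config.metabolite_baseline + g + rng.normal(0.0, np.sqrt(s2e), size=n)
        values[:, k] = yk
    for k, j, beta in config.causal_plan:
        values[:, k] += beta * geno.dosages[:, j]
        causal_ids[names[k]].append(geno.snps.at[j, "id"])
    if covars is not None:
        for k in range(config.n_metabolites):
            values[:, k] += _systematic_shift(covars, config.covariate_effect_sd, rng)

    table = pd.DataFrame(values, columns=names)
    table.insert(0, "animal", geno.samples)
    truth = SimulationTruth(
        causal_plan=list(config.causal_plan),
        causal_snp_ids=causal_ids,
        trait_plan=list(config.trait_plan),
        polygenic=polygenic,
        metabolite_base_var=s2a + s2e,
    )
    return table, truth


def simulate_feed_records(
    metabolites: pd.DataFrame,
    config: SimulationConfig,
    truth: SimulationTruth,
    covars: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serial body weights (~14-day grid) and daily dry-matter intake.

    Latent growth: initial BW ~ N(300, 30) kg, ADG ~ N(1.4, 0.15) kg/day;
    serial BW is the latent line plus weigh-scale noise.  DMI is a linear
    function of latent ADG and metabolic midweight plus planted metabolite
    effects and noise.  Planted trait effects enter the trait's generative
    quantity: 'adg' shifts latent ADG, 'mwt' shifts latent initial BW (in kg
    per uM of the centered metabolite), 'dmi' and 'rfi' shift intake.
    """
    rng = config.rng("feed")
    n = config.n_animals
    animals = metabolites["animal"].tolist()
    metab = metabolites.drop(columns="animal").to_numpy()
    metab_c = metab - metab.mean(axis=0)

    initial_bw = rng.normal(300.0, 30.0, size=n)
    adg = rng.normal(1.4, 0.15, size=n)
    dmi_shift = np.zeros(n)
    for trait, k, effect in config.trait_plan:
        if trait == "adg":
            adg += effect * metab_c[:, k]
        elif trait == "mwt":
            initial_bw += effect * metab_c[:, k]
        else:  # dmi and rfi effects both act on intake
            dmi_shift += effect * metab_c[:, k]
    if covars is not None:
        adg += _systematic_shift(covars, 0.03, rng)
        initial_bw += _systematic_shift(covars, 8.0, rng)

    truth.latent_adg = adg.copy()
    truth.latent_initial_bw = initial_bw.copy()

    days = np.arange(0, config.days_on_test + 1, 14)
    if days[-1] != config.days_on_test:
        days = np.append(days, config.days_on_test)
    weights = pd.DataFrame(
        {
            "animal": np.repeat(animals, len(days)),
            "day": np.tile(days, n),
            "weight": (
                initial_bw[:, None]
                + adg[:, None] * days[None, :]
                + rng.normal(0.0, config.bw_noise_sd, size=(n, len(days)))
            ).ravel(),
        }
    )

    midpoint = initial_bw + adg * config.days_on_test / 2.0
    mwt = midpoint**0.75
    b0, b_adg, b_mwt = config.dmi_coefficients
    dmi = (
        b0
        + b_adg * adg
        + b_mwt * mwt
        + dmi_shift
        + rng.normal(0.0, config.dmi_noise_sd, size=n)
    )
    if covars is not None:
        dmi += _systematic_shift(covars, 0.15, rng)
    intake = pd.DataFrame({"animal": animals, "dmi": dmi})
    return weights, intake


def simulate_annotation(
    geno: GenotypeMatrix, config: SimulationConfig, truth: SimulationTruth | None = None
) -> pd.DataFrame:
    """Gene annotation tiled along the synthetic genome.

    Gene density mimics a mammalian autosome (~one gene per 115 kbp: gaps
    exponential with mean 85 kbp, lengths exponential with mean 30 kbp).
    Biotypes are mostly protein_coding with a small snoRNA/miRNA fraction.
    When a truth with planted causal SNPs is given, a dedicated
    protein-coding gene spanning each causal SNP (+/- 15 kbp) is inserted and
    recorded in ``truth.planted_genes``.
    """
    rng = config.rng("annotation")
    rows = []
    gid = 0
    for c in range(1, config.n_chromosomes + 1):
        pos = 1
        while True:
            pos += int(rng.exponential(85_000)) + 1
            length = int(rng.exponential(30_000)) + 200
            if pos + length > config.chromosome_length:
                break
            gid += 1
            biotype = rng.choice(
                ["protein_coding", "miRNA", "snoRNA"], p=[0.90, 0.05, 0.05]
            )
            rows.append(
                {
                    "gene_id": f"GENE{gid:05d}",
                    "symbol": f"G{gid}",
                    "chrom": str(c),
                    "start": pos,
                    "end": pos + length,
                    "biotype": biotype,
                }
            )
            pos += length
    ann = pd.DataFrame(rows)

    if truth is not None:
        names = config.metabolite_names()
        planted_rows = []
        for k, j, _beta in truth.causal_plan:
            snp = geno.snps.iloc[j]
            gene_id = f"PLANTED_{snp['id'].upper()}"
            planted_rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": gene_id,
                    "chrom": str(snp["chrom"]),
                    "start": max(1, int(snp["pos"]) - 15_000),
                    "end": int(snp["pos"]) + 15_000,
                    "biotype": "protein_coding",
                }
            )
            truth.planted_genes.setdefault(names[k], []).append(gene_id)
        if planted_rows:
            ann = pd.concat([ann, pd.DataFrame(planted_rows)], ignore_index=True)
            ann = ann.sort_values(["chrom", "start"]).reset_index(drop=True)
    return ann


def simulate_gene_sets(
    annotation: pd.DataFrame,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
    n_sets: int = 20,
) -> dict[str, set[str]]:
    """Random GMT-style gene sets over the annotation, plus one planted set.

    The planted set contains every planted gene and random fill, so a
    successful end-to-end run can flag it as enriched.
    """
    rng = config.rng("gene_sets")
    genes = annotation["gene_id"].tolist()
    sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(10, 51))
        sets[f"function_{s + 1:02d}"] = set(rng.choice(genes, size=size, replace=False))
    if truth is not None and truth.planted_genes:
        planted = {g for gs in truth.planted_genes.values() for g in gs}
        fill = rng.choice(genes, size=15, replace=False)
        sets["planted_function"] = planted | set(fill)
    return sets


@dataclass
class SyntheticStudy:
    """One complete synthetic dataset plus its ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    metabolites: pd.DataFrame
    serial_weights: pd.DataFrame
    intake: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: SimulationTruth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every component of a study dataset from one seed."""
    geno = simulate_genotypes(config)
    covars = simulate_covariates(config)
    metab, truth = simulate_metabolites(geno, config, covars)
    weights, intake = simulate_feed_records(metab, config, truth, covars)
    ann = simulate_annotation(geno, config, truth)
    sets = simulate_gene_sets(ann, config, truth)
    return SyntheticStudy(
        config=config,
        genotypes=geno,
        covariates=covars,
        metabolites=metab,
        serial_weights=weights,
        intake=intake,
        annotation=ann,
        gene_sets=sets,
        truth=truth,
    )


def snp_effect_for_variance_fraction(
    q2: float, allele_freq: float, base_var: float
) -> float:
    """Effect (uM/allele) so one SNP explains fraction ``q2`` of total variance.

    ``base_var`` is the metabolite variance without the SNP (polygenic +
    residual); the SNP's own variance 2pq beta^2 is included in the total, so
    beta = sqrt(q2/(1-q2) * base_var / (2 p q)).
    """
    if not (0 < q2 < 1):
        raise ConfigError("variance fraction must be in (0,1)")
    p = allele_freq
    if not (0 < p < 1):
        raise ConfigError("allele frequency must be in (0,1)")
    return float(np.sqrt(q2 / (1.0 - q2) * base_var / (2.0 * p * (1.0 - p))))


def trait_effect_for_variance_fraction(
    r2: float, metab_var: float, trait_base_var: float
) -> float:
    """Regression effect so a metabolite explains fraction ``r2`` of a trait.

    ``trait_base_var`` is the trait variance without the metabolite term
    (for RFI: the intake residual variance).
    """
    if not (0 < r2 < 1):
        raise ConfigError("variance fraction must be in (0,1)")
    if metab_var <= 0 or trait_base_var <= 0:
        raise ConfigError("variances must be positive")
    return float(np.sqrt(r2 / (1.0 - r2) * trait_base_var / metab_var))
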