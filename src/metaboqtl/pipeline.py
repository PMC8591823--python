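"""End-to-end orchestration: QC -> traits -> adjust -> screen -> mGWAS -> genes.

The pipeline can run fully in memory from a :class:`SyntheticStudy` (or any
equally-shaped inputs) via :func:`run_study`, or from files on disk via
:func:`run_all`.  Stage outputs are pure functions of the inputs and
configuration, so re-running with the same config reproduces identical
tables; a :class:`RunManifest` records per-stage record counts and timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust as _adjust
from . import genes as _genes
from . import mgwas as _mgwas
from . import phenotypes as _pheno
from . import qc as _qc
from . import traits as _traits
from .enrich import _empty_results as _empty_enrichment
from .enrich import enrich as _overlap_enrich
from .enrich import read_gmt as _read_gmt
from .errors import ConfigError
from .genotypes import GenotypeMatrix, read_dosage_tsv, read_vcf
from .grm import GRM, compute_grm
from .reml import VarianceComponents, reml_variance_components
from .simulate import (
    SimulationConfig,
    SyntheticStudy,
    simulate_genotypes,
    simulate_study,
    snp_effect_for_variance_fraction,
    trait_effect_for_variance_fraction,
)

log = logging.getLogger(__name__)

TRAIT_COLUMNS = {"rfi": "rfi", "dmi": "dmi_std", "adg": "adg", "mwt": "mwt"}


@dataclass
class PipelineConfig:
    """Thresholds and toggles for a full run (paper-scale defaults)."""

    metabolite_alpha: float = 0.1
    snp_alpha: float = 1e-5
    enrichment_alpha: float = 0.05
    min_accuracy: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 1e-4
    flank: int = 70_000
    outlier_sd: float = 3.0
    test: str = "wald"
    diet_energy: float = 1.0
    reference_energy: float = 1.0
    do_qc: bool = True
    do_enrichment: bool = True
    output_dir: str | None = None

    def __post_init__(self):
        for name in ("metabolite_alpha", "snp_alpha", "enrichment_alpha", "hwe_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.flank < 0:
            raise ConfigError("flank must be non-negative")


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, seconds: float, **counts):
        self.stages.append({"stage": stage, "seconds": round(seconds, 3), **counts})

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "failed_stage": self.failed_stage}, indent=2, default=str))


@dataclass
class PipelineResult:
    manifest: RunManifest
    qc_report: _qc.QCReport | None
    phenotypes: pd.DataFrame
    association: pd.DataFrame
    selected: dict[str, list[str]]
    joint_vm_vp: dict[str, float]
    variance_components: dict[str, VarianceComponents]
    scans: dict[str, pd.DataFrame]
    significant: dict[str, pd.DataFrame]
    qtls: dict[str, list[_genes.QTLRegion]]
    gene_maps: dict[str, pd.DataFrame]
    trait_genes: dict[str, pd.DataFrame]
    trait_overlaps: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]


class _Stage:
    """Context-managed stage timer that records into the manifest."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name
        self.counts: dict = {}

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            self.manifest.record(self.name, dt, **self.counts)
            log.info("stage %s: done in %.2fs %s", self.name, dt, self.counts)
        else:
            self.manifest.failed_stage = self.name
            log.error("stage %s: failed (%s)", self.name, exc)
        return False


def run_study(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    metabolites: pd.DataFrame,
    serial_weights: pd.DataFrame,
    intake: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_sets: dict[str, set[str]] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory tables; see the module docstring."""
    config = config or PipelineConfig()
    manifest = RunManifest(config=vars(config).copy())
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- genotype QC -------------------------------------------------------
    qc_report = None
    if config.do_qc:
        with _Stage(manifest, "qc") as st:
            genotypes, qc_report = _qc.filter_variants(
                genotypes,
                min_accuracy=config.min_accuracy,
                min_maf=config.min_maf,
                hwe_alpha=config.hwe_alpha,
            )
            st.counts = {"snps_retained": qc_report.n_retained,
                         "snps_removed": qc_report.n_input - qc_report.n_retained}
            if outdir:
                pd.DataFrame([vars(qc_report)]).to_csv(
                    outdir / "qc_report.tsv", sep="\t", index=False)

    # --- trait derivation --------------------------------------------------
    with _Stage(manifest, "derive") as st:
        pheno = _pheno.derive_feed_phenotypes(
            serial_weights, intake,
            diet_energy=config.diet_energy,
            reference_energy=config.reference_energy,
        )
        st.counts = {"animals": len(pheno)}
        if outdir:
            pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)

    # --- alignment on the genotyped animals --------------------------------
    order = list(genotypes.samples)
    covars = covariates.set_index("animal").loc[order].reset_index()
    pheno_o = pheno.set_index("animal").loc[order]
    metab_o = metabolites.set_index("animal").loc[order]

    # --- pre-adjustment ----------------------------------------------------
    with _Stage(manifest, "adjust") as st:
        trait_adj = {
            t: _adjust.adjust_phenotype(
                pheno_o[col].to_numpy(float), covars, config.outlier_sd)
            for t, col in TRAIT_COLUMNS.items()
        }
        metab_adj = _adjust.adjust_table(metab_o, covars, config.outlier_sd)
        st.counts = {
            "traits": len(trait_adj),
            "metabolites": len(metab_adj),
            "outliers": int(sum((~a.keep).sum() for a in
                               list(trait_adj.values()) + list(metab_adj.values()))),
        }
        if outdir:
            adj_tab = pd.DataFrame({"animal": order})
            for name, a in {**trait_adj, **metab_adj}.items():
                adj_tab[name] = a.residuals
                adj_tab[f"{name}_keep"] = a.keep
            adj_tab.to_csv(outdir / "adjusted_phenotypes.tsv", sep="\t", index=False)

    # --- trait-metabolite screen ------------------------------------------
    with _Stage(manifest, "assoc_metab") as st:
        assoc, selected, joint = _traits.trait_metabolite_screen(
            trait_adj, metab_adj, alpha=config.metabolite_alpha)
        st.counts = {"pairs_tested": len(assoc),
                     "selected": int(sum(len(v) for v in selected.values()))}
        if outdir:
            tab = assoc.copy()
            tab["selected"] = tab.apply(
                lambda r: r["metabolite"] in selected.get(r["trait"], []), axis=1)
            tab["joint_vm_vp_pct"] = tab["trait"].map(joint)
            tab.to_csv(outdir / "trait_metabolite.tsv", sep="\t", index=False)

    scan_metabs = sorted({m for v in selected.values() for m in v})

    # --- GRM ---------------------------------------------------------------
    with _Stage(manifest, "grm") as st:
        grm_full = compute_grm(genotypes)
        st.counts = {"animals": grm_full.n_samples, "snps": grm_full.n_snps}

    # --- REML + mGWAS per selected metabolite ------------------------------
    vcs: dict[str, VarianceComponents] = {}
    scans: dict[str, pd.DataFrame] = {}
    sig: dict[str, pd.DataFrame] = {}
    qtls: dict[str, list[_genes.QTLRegion]] = {}
    gene_maps: dict[str, pd.DataFrame] = {}
    scan_cfg = _mgwas.ScanConfig(alpha=config.snp_alpha, test=config.test)
    with _Stage(manifest, "mgwas") as st:
        for m in scan_metabs:
            a = metab_adj[m]
            keep = a.keep
            y = a.residuals[keep]
            sub_geno = GenotypeMatrix(
                samples=[s for s, k in zip(order, keep) if k],
                snps=genotypes.snps,
                dosages=genotypes.dosages[keep],
            )
            sub_grm = GRM(
                matrix=grm_full.matrix[np.ix_(keep, keep)],
                sample_ids=sub_geno.samples,
                n_snps=grm_full.n_snps,
            )
            vcs[m] = reml_variance_components(y, sub_grm)
            scans[m] = _mgwas.mlma_scan(y, sub_geno, sub_grm, vcs[m], scan_cfg)
            sig[m] = _mgwas.select_significant(scans[m], alpha=config.snp_alpha)
            qtls[m] = _genes.cluster_qtls(sig[m], merge_window=2 * config.flank)
            gene_maps[m] = _genes.map_genes(sig[m], annotation, flank=config.flank)
            if outdir:
                scans[m].to_csv(outdir / f"scan_{m}.tsv", sep="\t", index=False)
                sig[m].to_csv(outdir / f"significant_{m}.tsv", sep="\t", index=False)
                _genes.qtl_table(qtls[m]).to_csv(
                    outdir / f"qtl_{m}.tsv", sep="\t", index=False)
        st.counts = {
            "metabolites_scanned": len(scan_metabs),
            "significant_snps": int(sum(len(s) for s in sig.values())),
            "qtls": int(sum(len(q) for q in qtls.values())),
        }
        if outdir and vcs:
            pd.DataFrame(
                [{"metabolite": m, **vars(v)} for m, v in vcs.items()]
            ).to_csv(outdir / "variance_components.tsv", sep="\t", index=False)

    # --- per-trait gene sets ----------------------------------------------
    with _Stage(manifest, "map_genes") as st:
        trait_genes, overlaps = _genes.union_genes_per_trait(gene_maps, selected)
        st.counts = {
            t: int(df["gene_id"].nunique()) for t, df in trait_genes.items()
        }
        if outdir:
            for t, df in trait_genes.items():
                df.to_csv(outdir / f"genes_{t}.tsv", sep="\t", index=False)
            overlaps.to_csv(outdir / "trait_gene_overlaps.tsv", sep="\t", index=False)

    # --- enrichment --------------------------------------------------------
    enrichment: dict[str, pd.DataFrame] = {}
    if config.do_enrichment and gene_sets:
        with _Stage(manifest, "enrich") as st:
            universe = set(annotation["gene_id"])
            for t, df in trait_genes.items():
                cands = set(df["gene_id"])
                if not cands:
                    enrichment[t] = _empty_enrichment()
                    continue
                enrichment[t] = _overlap_enrich(
                    cands, gene_sets, universe=universe,
                    alpha=config.enrichment_alpha)
                if outdir:
                    enrichment[t].to_csv(
                        outdir / f"enrichment_{t}.tsv", sep="\t", index=False)
            st.counts = {
                "significant_sets": int(sum(
                    r["significant"].sum() for r in enrichment.values()))
            }

    if outdir:
        manifest.to_json(outdir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        qc_report=qc_report,
        phenotypes=pheno,
        association=assoc,
        selected=selected,
        joint_vm_vp=joint,
        variance_components=vcs,
        scans=scans,
        significant=sig,
        qtls=qtls,
        gene_maps=gene_maps,
        trait_genes=trait_genes,
        trait_overlaps=overlaps,
        enrichment=enrichment,
    )


@dataclass
class PipelinePaths:
    """File locations for a disk-based run (TSV/VCF/GFF3/BED/GMT)."""

    genotypes: str
    covariates: str
    metabolites: str
    serial_weights: str
    intake: str
    annotation: str
    gene_sets: str | None = None


def run_all(paths: PipelinePaths, config: PipelineConfig | None = None) -> PipelineResult:
    """Disk-based entry point: load the named files, then :func:`run_study`."""
    for name, p in vars(paths).items():
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input file for {name!r} does not exist: {p}")
    gpath = str(paths.genotypes)
    geno = read_vcf(gpath) if gpath.endswith(".vcf") else read_dosage_tsv(gpath)
    apath = str(paths.annotation)
    if apath.endswith((".gff3", ".gff")):
        ann = _genes.read_gff3(apath)
    else:
        ann = _genes.read_bed_annotation(apath)
    sets = _read_gmt(paths.gene_sets) if paths.gene_sets else None
    return run_study(
        genotypes=geno,
        covariates=pd.read_csv(paths.covariates, sep="\t"),
        metabolites=pd.read_csv(paths.metabolites, sep="\t"),
        serial_weights=pd.read_csv(paths.serial_weights, sep="\t"),
        intake=pd.read_csv(paths.intake, sep="\t"),
        annotation=ann,
        gene_sets=sets,
        config=config,
    )


def demo_config(
    seed: int,
    n_animals: int = 500,
    n_snps: int = 5000,
    n_metabolites: int = 10,
    snp_variance_fraction: float = 0.08,
    trait_variance_fraction: float = 0.015,
    planted: bool = True,
) -> SimulationConfig:
    """Demo study design: three causal SNPs on three RFI-linked metabolites.

    Each causal SNP explains ``snp_variance_fraction`` of its metabolite's
    variance and each of those metabolites explains
    ``trait_variance_fraction`` of residual feed intake.  Effect sizes are
    derived from the realized allele frequencies, so the genotypes are drawn
    once here and identically again inside :func:`simulate_study`.
    """
    base = SimulationConfig(
        n_animals=n_animals,
        n_snps=n_snps,
        n_metabolites=n_metabolites,
        metabolite_h2=0.25,
        seed=seed,
    )
    if not planted:
        return base
    geno = simulate_genotypes(base)
    freqs = geno.allele_frequencies()
    h2 = 0.25
    base_var = base.metabolite_noise_sd**2 / (1.0 - h2)
    causal, trait_plan = [], []
    # nearest SNP to each anchor whose realized MAF is well inside the QC
    # bound, so the planted signal cannot be filtered out by its own MAF drift
    maf = np.minimum(freqs, 1 - freqs)
    eligible = np.where(maf >= 0.10)[0]
    snp_idx = [
        int(eligible[np.argmin(np.abs(eligible - anchor))])
        for anchor in (n_snps // 6, n_snps // 2, (5 * n_snps) // 6)
    ]
    for k, j in enumerate(snp_idx):
        beta = snp_effect_for_variance_fraction(
            snp_variance_fraction, freqs[j], base_var)
        causal.append((k, j, beta))
        metab_var = base_var / (1.0 - snp_variance_fraction)
        b = trait_effect_for_variance_fraction(
            trait_variance_fraction, metab_var, base.dmi_noise_sd**2)
        trait_plan.append(("rfi", k, b))
    return SimulationConfig(
        n_animals=n_animals,
        n_snps=n_snps,
        n_metabolites=n_metabolites,
        metabolite_h2=h2,
        causal_plan=causal,
        trait_plan=trait_plan,
        seed=seed,
    )


def demo(
    seed: int = 0,
    output_dir: str | None = None,
    config: PipelineConfig | None = None,
    **design_kwargs,
) -> tuple[SyntheticStudy, PipelineResult]:
    """One-command synthetic run: simulate a study and push it end to end."""
    sim_cfg = demo_config(seed, **design_kwargs)
    study = simulate_study(sim_cfg)
    pipe_cfg = config or PipelineConfig()
    if output_dir is not None:
        pipe_cfg.output_dir = output_dir
    result = run_study(
        genotypes=study.genotypes,
        covariates=study.covariates,
        metabolites=study.metabolites,
        serial_weights=study.serial_weights,
        intake=study.intake,
        annotation=study.annotation,
        gene_sets=study.gene_sets,
        config=pipe_cfg,
    )
    return study, result
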