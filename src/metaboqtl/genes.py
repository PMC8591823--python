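"""SNP-to-gene window mapping, QTL clustering and per-trait gene sets.

Significant SNPs are surveyed with a 140-kbp window (70 kbp upstream and
70 kbp downstream): a gene is a candidate for a metabolite when its span
intersects the window of any of the metabolite's significant SNPs.  Small
nucleolar RNA and microRNA genes are excluded (protein-coding focus).
SNPs whose windows overlap on a chromosome merge transitively into QTL
regions.  Per-trait candidate sets are the union over the trait's selected
metabolites, with full provenance retained.

All coordinates are 1-based inclusive (GFF3 convention); BED input is
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

DEFAULT_FLANK = 70_000
EXCLUDED_BIOTYPES = frozenset({"snoRNA", "miRNA"})

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "biotype"]


def read_gff3(path) -> pd.DataFrame:
    """Gene records from a GFF3 file into the annotation table.

    Keeps ``type == gene`` lines; gene id, name and biotype are parsed from
    the attribute column (``ID=``/``gene_id=``, ``Name=``, ``biotype=``).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("gene_id") or attrs.get("ID", "").removeprefix("gene:")
            if not gene_id:
                raise DataError(f"gene line without ID in {path}: {line[:80]}")
            rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": attrs.get("Name", gene_id),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
            )
    if not rows:
        raise DataError(f"no gene records found in {path}")
    return _validate_annotation(pd.DataFrame(rows))


def read_bed_annotation(path) -> pd.DataFrame:
    """6-column BED + biotype: chrom, start, end, gene_id, symbol, biotype.

    BED is 0-based half-open; converted to 1-based inclusive on read.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "symbol", "biotype"],
        dtype={"chrom": str},
        comment="#",
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return _validate_annotation(df[ANNOTATION_COLUMNS])


def _validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if (ann["start"] > ann["end"]).any():
        bad = ann.loc[ann["start"] > ann["end"], "gene_id"].tolist()
        raise DataError(f"genes with start > end: {bad[:5]}")
    return ann.reset_index(drop=True)


@dataclass
class QTLRegion:
    chrom: str
    start: int
    end: int
    snps: list[str]
    lead_snp: str
    lead_p: float


def cluster_qtls(sig_snps: pd.DataFrame, merge_window: int = 2 * DEFAULT_FLANK) -> list[QTLRegion]:
    """Merge significant SNPs into QTL regions.

    SNPs on the same chromosome whose +/- ``merge_window/2`` flanks overlap
    (inter-SNP distance <= ``merge_window``) merge transitively; a single
    sorted sweep realises the transitive closure.  Region bounds are the
    extreme member positions +/- the flank, floored at 1.
    """
    if sig_snps.empty:
        return []
    flank = merge_window // 2
    regions: list[QTLRegion] = []
    snps = sig_snps.sort_values(["chrom", "pos"])
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > merge_window)[0] + 1
        for block in np.split(np.arange(len(pos)), breaks):
            members = sub.iloc[block]
            lead = members.loc[members["p"].idxmin()]
            regions.append(
                QTLRegion(
                    chrom=str(chrom),
                    start=max(1, int(members["pos"].min()) - flank),
                    end=int(members["pos"].max()) + flank,
                    snps=members["snp"].tolist(),
                    lead_snp=str(lead["snp"]),
                    lead_p=float(lead["p"]),
                )
            )
    return regions


def qtl_table(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": len(r.snps),
                "lead_snp": r.lead_snp,
                "lead_p": r.lead_p,
            }
            for r in regions
        ]
    )


def map_genes(
    sig_snps: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    excluded_biotypes: frozenset[str] = EXCLUDED_BIOTYPES,
) -> pd.DataFrame:
    """Genes whose span intersects the +/- ``flank`` window of any SNP.

    Windows and gene spans are 1-based inclusive, so a gene is included iff
    ``gene.start <= snp.pos + flank`` and ``gene.end >= snp.pos - flank``.
    Returns provenance rows ``gene_id, symbol, biotype, chrom, snp, pos,
    distance`` (distance 0 when the SNP lies inside the gene).  Raises if the
    SNP and annotation chromosome names are disjoint.
    """
    if sig_snps.empty:
        return pd.DataFrame(
            columns=["gene_id", "symbol", "biotype", "chrom", "snp", "pos", "distance"]
        )
    snp_chroms = set(sig_snps["chrom"].astype(str))
    ann_chroms = set(annotation["chrom"].astype(str))
    if not snp_chroms & ann_chroms:
        raise DataError(
            f"no shared chromosome names between SNPs ({sorted(snp_chroms)[:5]}) "
            f"and annotation ({sorted(ann_chroms)[:5]})"
        )
    ann = annotation[~annotation["biotype"].isin(excluded_biotypes)]
    rows = []
    for chrom, sub in sig_snps.groupby(sig_snps["chrom"].astype(str), sort=False):
        genes = ann[ann["chrom"].astype(str) == chrom]
        if genes.empty:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        for _, s in sub.iterrows():
            lo, hi = s["pos"] - flank, s["pos"] + flank
            hit = (gs <= hi) & (ge >= lo)
            for _, g in genes[hit].iterrows():
                dist = max(g["start"] - s["pos"], s["pos"] - g["end"], 0)
                rows.append(
                    {
                        "gene_id": g["gene_id"],
                        "symbol": g["symbol"],
                        "biotype": g["biotype"],
                        "chrom": chrom,
                        "snp": s["snp"],
                        "pos": int(s["pos"]),
                        "distance": int(dist),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "biotype", "chrom", "snp", "pos", "distance"]
    )


def union_genes_per_trait(
    metab_gene_maps: dict[str, pd.DataFrame],
    trait_metab_links: dict[str, list[str]],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-trait candidate gene sets and pairwise trait-overlap counts.

    ``metab_gene_maps`` maps metabolite name -> provenance table from
    :func:`map_genes`; ``trait_metab_links`` maps trait -> its selected
    metabolites.  The per-trait table is the union of the metabolites' gene
    sets with a ``metabolite`` provenance column.
    """
    per_trait: dict[str, pd.DataFrame] = {}
    for trait, metabs in trait_metab_links.items():
        parts = []
        for m in metabs:
            gm = metab_gene_maps.get(m)
            if gm is not None and not gm.empty:
                parts.append(gm.assign(metabolite=m))
        if parts:
            per_trait[trait] = pd.concat(parts, ignore_index=True)
        else:
            warnings.warn(f"no candidate genes for trait {trait!r}", stacklevel=2)
            per_trait[trait] = pd.DataFrame(
                columns=["gene_id", "symbol", "biotype", "chrom", "snp", "pos",
                         "distance", "metabolite"]
            )
    traits = list(per_trait)
    overlaps = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            shared = set(per_trait[t1]["gene_id"]) & set(per_trait[t2]["gene_id"])
            overlaps.append({"trait_a": t1, "trait_b": t2, "n_shared_genes": len(shared)})
    return per_trait, pd.DataFrame(overlaps)
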