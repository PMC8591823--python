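"""QTL clustering and gene-window mapping against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from metaboqtl.errors import DataError
from metaboqtl.genes import (
    cluster_qtls,
    map_genes,
    read_bed_annotation,
    read_gff3,
    union_genes_per_trait,
)


def _sig(positions, chrom="1", ps=None):
    return pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom if isinstance(chrom, list) else [chrom] * len(positions),
            "pos": positions,
            "p": ps if ps is not None else [1e-6] * len(positions),
        }
    )


def clusters_oracle(snps: pd.DataFrame, merge_window: int) -> list[frozenset]:
    """Pairwise transitive closure by repeated sweeps (no sorting tricks)."""
    items = [
        {"chrom": r["chrom"], "pos": r["pos"], "members": {r["snp"]}}
        for _, r in snps.iterrows()
    ]
    clusters = []
    for it in items:
        merged = [it]
        rest = []
        for c in clusters:
            if c["chrom"] == it["chrom"] and any(
                abs(p - it["pos"]) <= merge_window for p in c["positions"]
            ):
                merged.append(c)
            else:
                rest.append(c)
        new = {
            "chrom": it["chrom"],
            "positions": {it["pos"]},
            "members": set(it["members"]),
        }
        for c in merged[1:]:
            new["positions"] |= c["positions"]
            new["members"] |= c["members"]
        clusters = rest + [new]
    # closure may need repeating until stable
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                if a["chrom"] == b["chrom"] and any(
                    abs(p - q) <= merge_window
                    for p in a["positions"]
                    for q in b["positions"]
                ):
                    a["positions"] |= b["positions"]
                    a["members"] |= b["members"]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(frozenset(c["members"]) for c in clusters)


class TestClusterQTLs:
    def test_close_snps_merge(self):
        regions = cluster_qtls(_sig([1_000_000, 1_100_000]))
        assert len(regions) == 1
        assert regions[0].start == 930_000 and regions[0].end == 1_170_000

    def test_chromosomes_never_merge(self):
        regions = cluster_qtls(_sig([1_000_000, 1_000_000], chrom=["1", "2"]))
        assert len(regions) == 2

    def test_lead_snp_has_min_p(self):
        regions = cluster_qtls(_sig([1_000_000, 1_050_000], ps=[1e-6, 1e-9]))
        assert regions[0].lead_snp == "s1"

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 15))
            snps = _sig(
                sorted(rng.integers(1, 2_000_000, size=n).tolist()),
                chrom=[str(c) for c in rng.integers(1, 4, size=n)],
            )
            snps = snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
            regions = cluster_qtls(snps)
            got = sorted(frozenset(r.snps) for r in regions)
            assert got == clusters_oracle(snps, 140_000)

    def test_region_count_bounded_by_snp_count(self, rng):
        snps = _sig(sorted(rng.integers(1, 10_000_000, size=25).tolist()))
        assert len(cluster_qtls(snps)) <= 25

    def test_empty_input(self):
        assert cluster_qtls(pd.DataFrame()) == []


class TestMapGenes:
    def test_gene_starting_inside_window_included(self, toy_annotation):
        hits = map_genes(_sig([1_000_000]), toy_annotation)
        assert "g_in" in set(hits["gene_id"])

    def test_exact_window_boundaries(self, toy_annotation):
        hits = set(map_genes(_sig([1_000_000]), toy_annotation)["gene_id"])
        assert "g_edge" in hits  # starts exactly at pos + 70000
        assert "g_out" not in hits  # starts one bp beyond

    def test_excluded_biotypes_are_dropped(self, toy_annotation):
        hits = set(map_genes(_sig([1_000_000]), toy_annotation)["gene_id"])
        assert "g_mirna" not in hits

    def test_chromosome_mismatch_raises(self, toy_annotation):
        with pytest.raises(DataError, match="chromosome"):
            map_genes(_sig([500], chrom="17"), toy_annotation)

    def test_matches_brute_force_interval_oracle(self, rng):
        for _ in range(40):
            n_snps = int(rng.integers(1, 8))
            n_genes = int(rng.integers(1, 25))
            snps = _sig(
                rng.integers(1, 1_000_000, size=n_snps).tolist(),
                chrom=[str(c) for c in rng.integers(1, 3, size=n_snps)],
            )
            starts = rng.integers(1, 1_000_000, size=n_genes)
            ann = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "symbol": [f"g{i}" for i in range(n_genes)],
                    "chrom": [str(c) for c in rng.integers(1, 3, size=n_genes)],
                    "start": starts,
                    "end": starts + rng.integers(100, 100_000, size=n_genes),
                    "biotype": "protein_coding",
                }
            )
            if not set(snps["chrom"]) & set(ann["chrom"]):
                with pytest.raises(DataError, match="chromosome"):
                    map_genes(snps, ann)
                continue
            got = map_genes(snps, ann)
            expected = {
                (g["gene_id"], s["snp"])
                for _, g in ann.iterrows()
                for _, s in snps.iterrows()
                if g["chrom"] == s["chrom"]
                and g["start"] <= s["pos"] + 70_000
                and g["end"] >= s["pos"] - 70_000
            }
            assert set(zip(got["gene_id"], got["snp"])) == expected


class TestUnionPerTrait:
    def test_union_and_overlap_counts(self):
        gm = {
            "m1": pd.DataFrame({"gene_id": ["A", "B"], "symbol": ["A", "B"],
                                "biotype": "pc", "chrom": "1", "snp": "s1",
                                "pos": 1, "distance": 0}),
            "m2": pd.DataFrame({"gene_id": ["B", "C"], "symbol": ["B", "C"],
                                "biotype": "pc", "chrom": "1", "snp": "s2",
                                "pos": 2, "distance": 0}),
        }
        links = {"rfi": ["m1", "m2"], "dmi": ["m2"]}
        per_trait, overlaps = union_genes_per_trait(gm, links)
        assert set(per_trait["rfi"]["gene_id"]) == {"A", "B", "C"}
        assert set(per_trait["dmi"]["gene_id"]) == {"B", "C"}
        row = overlaps.iloc[0]
        assert row["n_shared_genes"] == 2  # B and C shared via m2

    def test_trait_without_metabolites_warns(self):
        with pytest.warns(UserWarning, match="no candidate genes"):
            per_trait, _ = union_genes_per_trait({}, {"adg": []})
        assert per_trait["adg"].empty


class TestAnnotationIO:
    def test_gff3_round_trip_fields(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tensembl\tgene\t100\t500\t.\t+\t.\t"
            "ID=gene:ENSBTAG1;Name=ACACB;biotype=protein_coding\n"
            "1\tensembl\tmRNA\t100\t500\t.\t+\t.\tID=tx1;Parent=gene:ENSBTAG1\n"
            "2\tensembl\tgene\t30\t90\t.\t-\t.\tID=gene:ENSBTAG2;biotype=miRNA\n"
        )
        ann = read_gff3(gff)
        assert len(ann) == 2
        assert ann.iloc[0]["gene_id"] == "ENSBTAG1"
        assert ann.iloc[0]["symbol"] == "ACACB"
        assert ann.iloc[1]["biotype"] == "miRNA"

    def test_bed_coordinates_convert_to_one_based(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t500\tG1\tSYM1\tprotein_coding\n")
        ann = read_bed_annotation(bed)
        assert ann.iloc[0]["start"] == 100 and ann.iloc[0]["end"] == 500
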