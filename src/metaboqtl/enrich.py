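"""Gene-set overlap enrichment over GMT collections.

A transparent replacement for knowledge-base overlap tools: for each named
gene set the test is the one-sided hypergeometric (Fisher exact upper tail)
probability of drawing at least the observed overlap when ``n_candidates``
genes are sampled without replacement from a universe containing ``n_set``
set members.  Sets with p < 0.05 are flagged; a Benjamini-Hochberg column is
emitted for information but not used for the flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line -- name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                raise DataError(f"{path}:{ln}: GMT lines need name, description, members")
            members = {g for g in parts[2:] if g}
            if not members:
                raise DataError(f"{path}:{ln}: empty gene set {parts[0]!r}")
            sets[parts[0]] = members
    if not sets:
        raise DataError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def overlap_test(n_candidates: int, n_set: int, n_overlap: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p-value: P(X >= n_overlap).

    X counts set members among ``n_candidates`` genes drawn without
    replacement from ``n_universe`` genes of which ``n_set`` are in the set.
    """
    if n_overlap > min(n_candidates, n_set):
        raise DataError("overlap exceeds candidate or set size")
    if min(n_candidates, n_set, n_overlap, n_universe) < 0:
        raise DataError("counts must be non-negative")
    if n_universe < n_candidates + n_set - n_overlap:
        raise DataError("universe smaller than the union of candidates and set")
    if n_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_candidates))


def enrich(
    candidate_genes: set[str],
    collection: dict[str, set[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overlap test of one candidate list against every set in a collection.

    ``universe`` defaults to the union of all collection members.  Candidate
    genes outside the universe are counted and excluded with a warning
    (mirroring knowledge-base mapping loss).  Results are sorted ascending by
    p; ``significant`` flags p strictly below ``alpha``.
    """
    if universe is None:
        universe = set().union(*collection.values())
    for name, members in collection.items():
        stray = members - universe
        if stray:
            raise DataError(f"set {name!r} has members outside the universe: "
                            f"{sorted(stray)[:5]}")
    if not candidate_genes:
        warnings.warn("empty candidate gene set: no enrichment computed", stacklevel=2)
        return _empty_results()
    mapped = candidate_genes & universe
    n_unmapped = len(candidate_genes) - len(mapped)
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} of {len(candidate_genes)} candidate genes not in the "
            "universe; excluded from the overlap test",
            stacklevel=2,
        )
    if not mapped:
        return _empty_results()

    rows = []
    for name, members in collection.items():
        hit = mapped & members
        p = overlap_test(len(mapped), len(members), len(hit), len(universe))
        rows.append(
            {
                "set": name,
                "n_candidates": len(mapped),
                "set_size": len(members),
                "overlap": len(hit),
                "overlap_genes": ",".join(sorted(hit)),
                "p": p,
            }
        )
    res = pd.DataFrame(rows).sort_values(["p", "set"]).reset_index(drop=True)
    res["p_bh"] = multipletests(res["p"], method="fdr_bh")[1]
    res["significant"] = res["p"] < alpha
    return res


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["set", "n_candidates", "set_size", "overlap", "overlap_genes",
                 "p", "p_bh", "significant"]
    )


def edge_list(per_trait_results: dict[str, pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Bipartite gene--function edges for significant sets (for plotting)."""
    rows = []
    for trait, res in per_trait_results.items():
        for _, r in res[res["significant"]].iterrows():
            for gene in r["overlap_genes"].split(","):
                if gene:
                    rows.append({"trait": trait, "function": r["set"], "gene": gene})
    return pd.DataFrame(rows, columns=["trait", "function", "gene"])
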