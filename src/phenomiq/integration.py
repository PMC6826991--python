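"""Homology-based integration of yeast interaction classes with cancer
cell-line pharmacogenomics.

Per human gene, drug sensitivity is regressed on standardized expression
within a tissue stratum; because both sides are standardized the coefficient
is the Pearson correlation, whose sign encodes direction: negative means the
gene is *under*expressed in drug-sensitive lines, positive *over*expressed.
Yeast deletion enhancers whose human homolog is significantly underexpressed
in sensitive lines are UES (underexpression sensitivity) hits; yeast deletion
suppressors with significantly overexpressed homologs are OES hits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = ["human_gene", "tissue", "standardized_coefficient", "p_value", "n_lines"]
HIT_COLUMNS = [
    "yeast_gene", "human_gene", "homology_class", "drug", "tissue", "direction",
    "standardized_coefficient", "p_value",
]


def associate(
    expression: pd.DataFrame,
    sensitivity: pd.Series,
    tissues: pd.Series,
    stratum: str = "all",
    min_lines: int = 10,
) -> pd.DataFrame:
    """Per-gene expression↔sensitivity association within a tissue stratum.

    ``expression`` is genes × cell lines; ``sensitivity`` and ``tissues`` are
    indexed by cell line. ``stratum`` is "all" or a tissue label. The
    standardized coefficient is the slope of standardized sensitivity on
    standardized expression (= Pearson r) with a two-sided t test on n-2
    degrees of freedom. Genes with constant expression in the stratum are
    skipped (count logged).
    """
    lines = list(expression.columns)
    sens = sensitivity.loc[lines]
    tiss = tissues.loc[lines]
    if stratum != "all":
        keep = tiss[tiss == stratum].index
        if len(keep) < min_lines:
            raise ValueError(
                f"stratum {stratum!r} has {len(keep)} cell lines (< {min_lines})"
            )
        expression = expression[keep]
        sens = sens.loc[keep]
    n = expression.shape[1]
    if n < min_lines:
        raise ValueError(f"need >= {min_lines} cell lines, got {n}")

    X = expression.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "associate(%s): skipped %d constant-expression gene(s)",
            stratum, int(constant.sum()),
        )
    y = sens.to_numpy(dtype=float)
    yz = (y - y.mean()) / y.std(ddof=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yz) / ((n - 1) * sd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * student_t.sf(np.abs(tstat), df=n - 2)

    out = pd.DataFrame(
        {
            "human_gene": expression.index,
            "tissue": stratum,
            "standardized_coefficient": r,
            "p_value": p,
            "n_lines": n,
        }
    )
    return out[~constant].reset_index(drop=True)


def call_hits(
    yeast_results: pd.DataFrame,
    homolog_map: pd.DataFrame,
    associations: pd.DataFrame,
    alpha: float = 0.05,
    clusters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intersect yeast interaction classes with cell-line associations.

    ``yeast_results`` needs columns (yeast_gene, drug, class, z_K, z_L);
    ``associations`` needs (human_gene, drug, tissue, standardized_coefficient,
    p_value). A UES hit requires an enhancer yeast class, a negative
    coefficient and p < alpha; an OES hit a suppressor class, positive
    coefficient and p < alpha. Homolog rows naming unknown yeast genes are
    skipped with a warning; identical duplicate rows collapse to one hit.
    """
    known = set(yeast_results["yeast_gene"])
    unknown = sorted(set(homolog_map["yeast_gene"]) - known)
    if unknown:
        logger.warning(
            "call_hits: skipping %d homolog row(s) for unknown yeast gene(s): %s",
            len(unknown), ", ".join(unknown[:5]) + ("..." if len(unknown) > 5 else ""),
        )
    hom = homolog_map[homolog_map["yeast_gene"].isin(known)].drop_duplicates()

    merged = yeast_results.merge(hom, on="yeast_gene").merge(
        associations, on=["human_gene", "drug"] if "drug" in associations else "human_gene"
    )
    sig = merged["p_value"] < alpha
    ues = (merged["class"] == "enhancer") & (merged["standardized_coefficient"] < 0) & sig
    oes = (merged["class"] == "suppressor") & (merged["standardized_coefficient"] > 0) & sig
    merged["direction"] = np.where(ues, "UES", np.where(oes, "OES", ""))
    hits = merged[merged["direction"] != ""].copy()

    zcols = [c for c in yeast_results.columns if c.startswith("z_")]
    cols = HIT_COLUMNS + zcols
    if clusters is not None:
        hits = hits.merge(
            clusters.rename(columns={"gene": "yeast_gene"}), on="yeast_gene", how="left"
        )
        cols = cols + ["cluster_name"]
    hits = hits[cols].drop_duplicates().sort_values(
        ["drug", "tissue", "yeast_gene", "human_gene"], kind="stable"
    )
    return hits.reset_index(drop=True)


def summarize_conservation(
    hits: pd.DataFrame, yeast_results: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of yeast deletion enhancers with >= 1 UES homolog, per
    (drug, tissue stratum). Returns numerator, denominator and fraction."""
    rows = []
    enh = yeast_results[yeast_results["class"] == "enhancer"]
    tissues = sorted(hits["tissue"].unique()) if len(hits) else []
    for drug, genes in enh.groupby("drug")["yeast_gene"].agg(set).items():
        for tissue in tissues or ["all"]:
            ues = hits[
                (hits["drug"] == drug)
                & (hits["tissue"] == tissue)
                & (hits["direction"] == "UES")
            ]
            covered = genes & set(ues["yeast_gene"])
            rows.append(
                {
                    "drug": drug,
                    "tissue": tissue,
                    "n_enhancers": len(genes),
                    "n_with_ues_homolog": len(covered),
                    "fraction": len(covered) / len(genes) if genes else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["drug", "tissue", "n_enhancers", "n_with_ues_homolog", "fraction"]
    )


def yeast_class_table(interaction_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-(gene, drug) class plus z_K / z_L, from tidy interaction tables."""
    rows = []
    for tbl in interaction_tables:
        muts = tbl[tbl["strain_class"] != "reference"]
        z = muts.pivot_table(index="strain", columns="cpp", values="z", dropna=False)
        cls = muts[muts["cpp"] == "K"].set_index("strain")["class"]
        drug = muts["drug"].iloc[0]
        for gene in z.index:
            rows.append(
                {
                    "yeast_gene": gene,
                    "drug": drug,
                    "class": cls.get(gene, "none"),
                    "z_K": z.loc[gene].get("K", np.nan),
                    "z_L": z.loc[gene].get("L", np.nan),
                }
            )
    return pd.DataFrame(rows)
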