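"""GO-term enrichment of clusters and GO-term averaging (GTA) of interaction
scores.

Enrichment is the classical one-sided hypergeometric test: with N background
genes, M of them annotated to a term, and a cluster of n genes containing k
term genes, p = P(X >= k) for X ~ Hypergeometric(N, M, n). GTA summarizes a
term directly on the interaction scores: the GTA value is the mean score of
the term's genes, gtaSD its sample SD, and the GTA score |GTA value| - gtaSD;
a term passes the filter when |GTA value| > 2 and GTA score > 2 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    cluster: str
    k: int          # term genes in cluster
    n: int          # cluster size
    M: int          # term genes in background
    N: int          # background size
    p_value: float
    adjusted_p: float  # Bonferroni across terms tested for this cluster


@dataclass(frozen=True)
class GTAResult:
    term: str
    gta_value: float
    gta_sd: float
    gta_score: float
    n_genes: int
    passes_filter: bool


def hypergeom_pvalue(k: int, N: int, M: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(hypergeom.sf(k - 1, N, M, n))


def hypergeom_enrichment(
    cluster_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: pd.DataFrame,
    cluster_name: str = "cluster",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term with >= 1 cluster gene.

    ``annotations`` is the flat two-column gene→term table, restricted to the
    background before counting. Bonferroni correction runs across all terms
    with background annotation. Cluster genes absent from the background are
    an error (listed in the message).
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    missing = sorted(cluster - background)
    if missing:
        raise ValueError(
            "cluster genes absent from background: " + ", ".join(missing)
        )
    ann = annotations[annotations["gene"].isin(background)]
    N, n = len(background), len(cluster)
    by_term = ann.groupby("term")["gene"].agg(set)
    n_terms = len(by_term)
    results = []
    for term, genes in by_term.items():
        k = len(genes & cluster)
        if k == 0:
            continue
        p = hypergeom_pvalue(k, N, len(genes), n)
        results.append(
            EnrichmentResult(
                term=term, cluster=cluster_name, k=k, n=n, M=len(genes), N=N,
                p_value=p, adjusted_p=min(1.0, p * n_terms),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def scores_by_gene(
    interaction_table: pd.DataFrame, drug: str, cpp: str
) -> dict[str, float]:
    """gene -> interaction z-score for one (drug, CPP), mutants only."""
    sub = interaction_table[
        (interaction_table["drug"] == drug)
        & (interaction_table["cpp"] == cpp)
        & (interaction_table["strain_class"] != "reference")
        & ~interaction_table["flagged"]
    ]
    return dict(zip(sub["strain"], sub["z"].astype(float)))


def gta(
    term_genes: Iterable[str],
    scores: Mapping[str, float],
    term: str = "term",
    threshold: float = 2.0,
) -> GTAResult:
    """GTA value / SD / score for one term over a gene->score mapping.

    Genes absent from the score table are dropped (count logged); no gene
    present is an error. Sample SD (ddof=1); a single-gene term has SD 0.
    """
    term_genes = list(term_genes)
    present = [g for g in term_genes if g in scores]
    dropped = len(term_genes) - len(present)
    if dropped:
        logger.info("gta(%s): dropped %d gene(s) absent from score table", term, dropped)
    if not present:
        raise ValueError(f"no gene of term {term!r} present in the score table")
    vals = np.array([scores[g] for g in present], dtype=float)
    value = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    score = abs(value) - sd
    return GTAResult(
        term=term,
        gta_value=value,
        gta_sd=sd,
        gta_score=score,
        n_genes=len(present),
        passes_filter=(abs(value) > threshold and score > threshold),
    )


def gta_all(
    annotations: pd.DataFrame,
    scores: Mapping[str, float],
    threshold: float = 2.0,
) -> list[GTAResult]:
    """GTA for every annotated term with at least one scored gene."""
    results = []
    for term, genes in annotations.groupby("term")["gene"].agg(list).items():
        if not any(g in scores for g in genes):
            continue
        results.append(gta(genes, scores, term=term, threshold=threshold))
    return results


def gta_filter(results: Sequence[GTAResult]) -> list[GTAResult]:
    """Terms passing both GTA filters, sorted by |GTA value| descending."""
    kept = [r for r in results if r.passes_filter]
    kept.sort(key=lambda r: (-abs(r.gta_value), r.term))
    return kept


def gta_table(results: Sequence[GTAResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
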