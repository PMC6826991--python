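"""Recursive expectation-maximization clustering (REMc) of interaction profiles.

A Gaussian mixture is fit by EM to the matrix of interaction z-scores (one
row per gene, one column per drug × CPP, e.g. gemcitabine-K, cytarabine-K,
gemcitabine-L, cytarabine-L); the number of components is chosen by BIC over
a candidate grid, and each resulting hard cluster is clustered again,
recursively, until a cluster is best described by a single component, falls
below the minimum size, or the depth cap is reached. Cluster names encode
the lineage (round-parentLineage-index: the children of "1-0-16" are
"2-0.16-0", "2-0.16-1", ...). Shift columns are carried along for display
but never enter the model; genes whose culture did not grow without drug
carry the sentinel score 0.0001 in every z column and are clustered as-is
but flagged.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

#: interaction score assigned to genes with no growth in the absence of drug
MISSING_SENTINEL = 0.0001


class _TrackedGMM(GaussianMixture):
    """GaussianMixture that records the EM log-likelihood after every E step."""

    def fit(self, X, y=None):
        self.ll_trace_ = []
        return super().fit(X, y)

    def _e_step(self, X, **kwargs):
        log_prob_norm, log_resp = super()._e_step(X, **kwargs)
        self.ll_trace_.append(float(log_prob_norm))
        return log_prob_norm, log_resp


@dataclass
class EMResult:
    assignments: np.ndarray       # hard component label per row
    model: GaussianMixture
    chosen_k: int
    bic_by_k: dict[int, float]
    ll_traces: list[list[float]]  # one per (k, init) EM run actually executed


@dataclass
class ClusterNode:
    name: str
    members: list[str]
    depth: int
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    weights: np.ndarray | None = None
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "cluster_name": leaf.name, "depth": leaf.depth}
            for leaf in self.leaves()
            for g in leaf.members
        ]
        return pd.DataFrame(rows, columns=["gene", "cluster_name", "depth"])


def _derive_seed(seed: int, tag: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(tag.encode())) & 0x7FFFFFFF


def em_cluster(
    X: np.ndarray,
    k_candidates=range(1, 11),
    n_init: int = 5,
    seed: int = 0,
    covariance_type: str = "diag",
    reg_covar: float = 1e-6,
) -> EMResult:
    """Fit Gaussian mixtures for each candidate k and pick the BIC optimum.

    Each candidate is fit ``n_init`` times from k-means++ starts with
    deterministic derived seeds; the best run (highest log-likelihood) per k
    enters model selection. Hard assignments are maximum posterior
    responsibility. Singular covariances are handled by ``reg_covar``
    regularization inside EM.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ks = [k for k in k_candidates if 2 * k <= n] or [1]
    traces: list[list[float]] = []
    best_by_k: dict[int, GaussianMixture] = {}
    bic_by_k: dict[int, float] = {}
    for k in ks:
        best = None
        for i in range(n_init if k > 1 else 1):
            gmm = _TrackedGMM(
                n_components=k,
                covariance_type=covariance_type,
                reg_covar=reg_covar,
                random_state=_derive_seed(seed, f"k{k}i{i}"),
                n_init=1,
                max_iter=200,
            )
            with warnings.catch_warnings():
                # duplicate rows make the k-means init report fewer distinct
                # clusters than k; EM still converges (typically to k = 1 wins)
                warnings.simplefilter("ignore", ConvergenceWarning)
                gmm.fit(X)
            traces.append(list(gmm.ll_trace_))
            if best is None or gmm.lower_bound_ > best.lower_bound_:
                best = gmm
        best_by_k[k] = best
        bic_by_k[k] = float(best.bic(X))
    chosen_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    model = best_by_k[chosen_k]
    return EMResult(model.predict(X), model, chosen_k, bic_by_k, traces)


def build_profile_matrix(
    interaction_tables: list[pd.DataFrame], sentinel: float = MISSING_SENTINEL
) -> pd.DataFrame:
    """Pivot per-drug interaction tables into the REMc input matrix.

    Columns ``z_{drug}_{cpp}`` for K and L (the clustered block),
    ``shift_{drug}`` carried along for display only, and a boolean
    ``sentinel`` flag. Genes unscorable for a drug (no growth without drug)
    get the sentinel in that drug's z columns. Reference cultures are
    excluded (one row per mutant gene).
    """
    pieces = []
    for tbl in interaction_tables:
        muts = tbl[tbl["strain_class"] != "reference"]
        drug = muts["drug"].iloc[0]
        z = muts.pivot_table(index="strain", columns="cpp", values="z", dropna=False)
        shift = muts[muts["cpp"] == "K"].set_index("strain")["shift"]
        ng = muts[muts["cpp"] == "K"].set_index("strain")["no_growth_at_d0"]
        frame = pd.DataFrame(
            {
                f"z_{drug}_K": z.get("K"),
                f"z_{drug}_L": z.get("L"),
                f"shift_{drug}": shift,
                f"_sentinel_{drug}": ng.astype(bool),
            }
        )
        pieces.append(frame)
    mat = pd.concat(pieces, axis=1)
    sent_cols = [c for c in mat.columns if c.startswith("_sentinel_")]
    z_cols = [c for c in mat.columns if c.startswith("z_")]
    mat["sentinel"] = mat[sent_cols].any(axis=1) | mat[z_cols].isna().any(axis=1)
    for c in z_cols:
        mat.loc[mat["sentinel"], c] = sentinel
        mat[c] = mat[c].fillna(sentinel)
    mat = mat.drop(columns=sent_cols)
    mat.index.name = "gene"
    return mat.sort_index()


def z_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c.startswith("z_")]


def remc(
    matrix: pd.DataFrame,
    k_max: int = 10,
    n_init: int = 5,
    min_size: int = 8,
    max_depth: int = 4,
    seed: int = 0,
    covariance_type: str = "diag",
    trace_collector: list | None = None,
) -> ClusterNode:
    """Recursive EM clustering of a profile matrix; returns the root node.

    Only the z-score columns enter the model. Recursion stops when BIC picks
    a single component, a cluster has fewer than ``min_size`` members, or
    ``max_depth`` rounds have run. When ``trace_collector`` is a list, the
    per-iteration EM log-likelihood trace of every executed run is appended
    to it (for optimizer diagnostics).
    """
    X = matrix[z_columns(matrix)].to_numpy(dtype=float)
    genes = list(matrix.index)

    def recurse(node: ClusterNode, rows: np.ndarray, round_no: int, lineage: str):
        if round_no > max_depth or len(node.members) < max(min_size, 2):
            return
        res = em_cluster(
            X[rows],
            k_candidates=range(1, k_max + 1),
            n_init=n_init,
            seed=_derive_seed(seed, node.name),
            covariance_type=covariance_type,
        )
        if trace_collector is not None:
            trace_collector.extend(res.ll_traces)
        if res.chosen_k == 1:
            return
        node.means = res.model.means_
        node.covariances = res.model.covariances_
        node.weights = res.model.weights_
        for c in range(res.chosen_k):
            sub = rows[res.assignments == c]
            child = ClusterNode(
                name=f"{round_no}-{lineage}-{c}",
                members=[genes[i] for i in sub],
                depth=round_no,
            )
            node.children.append(child)
            recurse(child, sub, round_no + 1, f"{lineage}.{c}")

    # lineage bookkeeping mirrors the observed id style: round-1 clusters are
    # "1-0-c"; the children of "1-0-16" are "2-0.16-c".
    root = ClusterNode(name="root", members=genes, depth=0)

    def recurse_root():
        rows = np.arange(len(genes))
        res = em_cluster(
            X,
            k_candidates=range(1, k_max + 1),
            n_init=n_init,
            seed=_derive_seed(seed, "root"),
            covariance_type=covariance_type,
        )
        if trace_collector is not None:
            trace_collector.extend(res.ll_traces)
        if res.chosen_k == 1 or len(genes) < max(min_size, 2):
            return
        root.means = res.model.means_
        root.covariances = res.model.covariances_
        root.weights = res.model.weights_
        for c in range(res.chosen_k):
            sub = rows[res.assignments == c]
            child = ClusterNode(
                name=f"1-0-{c}", members=[genes[i] for i in sub], depth=1
            )
            root.children.append(child)
            recurse(child, sub, 2, f"0.{c}")

    if len(genes) >= max(min_size, 2) and max_depth >= 1:
        recurse_root()
    return root


def order_for_display(node: ClusterNode, matrix: pd.DataFrame) -> list[str]:
    """Member order for heatmap display: average-linkage hierarchical
    clustering on Euclidean distance of z profiles, members pre-sorted by
    gene name so ties (identical profiles) keep lexicographic order."""
    members = sorted(node.members)
    if len(members) <= 2:
        return members
    X = matrix.loc[members, z_columns(matrix)].to_numpy(dtype=float)
    d = pdist(X, metric="euclidean")
    if d.max() == 0.0:  # all profiles identical: keep lexicographic order
        return members
    order = leaves_list(linkage(d, method="average"))
    return [members[i] for i in order]
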