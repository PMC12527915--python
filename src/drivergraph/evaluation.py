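"""Evaluation metrics and analysis scores.

Classification metrics (top-k, macro-F1, one-vs-rest AUROC), rank-based
perturbation metrics, a normalized local inverse Simpson index (LISI) for
label mixing in an embedding, transition/likelihood/prediction scores for
phenotypic-shift analysis, and the differential-gene-expression (DGE)
ranking baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .data_core import CountMatrix, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "classification_metrics",
    "rank_metrics",
    "lisi",
    "transition_score",
    "prediction_score",
    "dge_baseline_ranking",
    "dge_candidate_ranks",
    "ranks_of_labels",
]


@dataclass
class MetricReport:
    top_1: float
    top_5: float
    macro_f1: float
    auroc: float
    mean_rank: float
    median_rank: float
    rank_distribution: np.ndarray
    per_gene_accuracy: pd.DataFrame
    n_pairs: int


def ranks_of_labels(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank (1 = best) of each true label under descending probability,
    ties broken by ascending candidate index."""
    probs = np.atleast_2d(probs)
    n, K = probs.shape
    order = np.lexsort((np.tile(np.arange(K), (n, 1)), -probs), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, K + 1)
    return ranks[np.arange(n), labels]


def classification_metrics(
    probs: np.ndarray, labels: np.ndarray, candidate_genes: list[str] | None = None
) -> MetricReport:
    """Multiclass metrics from per-pair likelihood vectors.

    top-k is the fraction of pairs whose true driver ranks <= k; macro-F1
    scores the argmax prediction; AUROC is the macro average of per-class
    one-vs-rest AUROC, skipping classes without both positive and negative
    examples (logged).
    """
    probs = np.atleast_2d(probs)
    labels = np.asarray(labels)
    if probs.shape[0] != labels.shape[0] or probs.shape[0] == 0:
        raise ValidationError("need >= 1 pair with matching labels")
    n, K = probs.shape
    ranks = ranks_of_labels(probs, labels)
    pred = probs.argmax(axis=1)
    present = np.unique(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        macro_f1 = float(
            f1_score(labels, pred, labels=present, average="macro", zero_division=0)
        )
    aucs = []
    skipped = 0
    for c in range(K):
        pos = labels == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, probs[:, c]))
        else:
            skipped += 1
    if skipped:
        logger.warning("AUROC: skipped %d classes without both outcomes", skipped)
    names = candidate_genes if candidate_genes else [str(i) for i in range(K)]
    per_gene = pd.DataFrame(
        {
            "gene": [names[c] for c in present],
            "n": [int((labels == c).sum()) for c in present],
            "top1": [float((pred[labels == c] == c).mean()) for c in present],
        }
    )
    return MetricReport(
        top_1=float((ranks <= 1).mean()),
        top_5=float((ranks <= 5).mean()),
        macro_f1=macro_f1,
        auroc=float(np.mean(aucs)) if aucs else float("nan"),
        mean_rank=float(ranks.mean()),
        median_rank=float(np.median(ranks)),
        rank_distribution=ranks,
        per_gene_accuracy=per_gene,
        n_pairs=n,
    )


def rank_metrics(
    probs: np.ndarray,
    labels: np.ndarray,
    second_labels: np.ndarray | None = None,
) -> dict:
    """Rank distributions of the true drivers.

    For dual perturbations, "perturbation 1" is the better-ranked of the
    two drivers and "perturbation 2" the worse-ranked, regardless of
    input order.
    """
    r1 = ranks_of_labels(probs, np.asarray(labels))
    out = {
        "ranks": r1,
        "mean_rank": float(r1.mean()),
        "median_rank": float(np.median(r1)),
    }
    if second_labels is not None:
        r2 = ranks_of_labels(probs, np.asarray(second_labels))
        better = np.minimum(r1, r2)
        worse = np.maximum(r1, r2)
        out.update(
            {
                "perturbation1_ranks": better,
                "perturbation2_ranks": worse,
                "perturbation1_mean": float(better.mean()),
                "perturbation2_mean": float(worse.mean()),
            }
        )
    return out


def lisi(
    embedding: np.ndarray, labels: np.ndarray, perplexity: int = 30
) -> np.ndarray:
    """Normalized local inverse Simpson index per cell, in [0, 1].

    For each cell a Gaussian kernel over its nearest neighbors is tuned so
    the distribution's perplexity matches ``perplexity``; the inverse
    Simpson index lambda of the neighborhood label distribution
    (lambda in [1, n_labels]) is rescaled as (lambda-1)/(n_labels-1), so 0
    means neighborhoods of a single label and 1 perfect mixing.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    n = embedding.shape[0]
    if n <= perplexity:
        raise ValidationError("need more cells than the perplexity")
    uniq, lab_idx = np.unique(labels, return_inverse=True)
    n_labels = uniq.size
    if n_labels == 1:
        logger.warning("single global label: all LISI scores are 0")
        return np.zeros(n)
    k = min(3 * perplexity, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist**2
    target = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        beta = _tune_beta(d2[i], target)
        p = np.exp(-beta * (d2[i] - d2[i].min()))
        p /= p.sum()
        mass = np.bincount(lab_idx[idx[i]], weights=p, minlength=n_labels)
        lam = 1.0 / (mass**2).sum()
        scores[i] = (lam - 1.0) / (n_labels - 1.0)
    return np.clip(scores, 0.0, 1.0)


def _tune_beta(d2: np.ndarray, target_entropy: float, tol: float = 1e-5) -> float:
    """Binary search for the Gaussian precision matching a target entropy."""
    beta, lo, hi = 1.0, 0.0, np.inf
    d2 = d2 - d2.min()
    for _ in range(64):
        p = np.exp(-beta * d2)
        s = p.sum()
        p /= s
        ent = -(p * np.log(p + 1e-300)).sum()
        if abs(ent - target_entropy) < tol:
            break
        if ent > target_entropy:  # too flat -> sharpen
            lo = beta
            beta = beta * 2 if np.isinf(hi) else 0.5 * (beta + hi)
        else:
            hi = beta
            beta = 0.5 * (beta + lo)
    return beta


def transition_score(
    src: NormalizedMatrix | np.ndarray,
    tgt: NormalizedMatrix | np.ndarray,
    marker_sets: dict[str, list[str]],
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mean target-minus-source normalized expression over each marker set.

    Rows are source/target pairs (i-th row of ``src`` with i-th row of
    ``tgt``); columns are marker-set names.
    """
    if isinstance(src, NormalizedMatrix):
        gene_ids = src.gene_ids
        src_vals, tgt_vals = src.values, tgt.values
    else:
        if gene_ids is None:
            raise ValidationError("gene_ids required with bare arrays")
        src_vals, tgt_vals = np.atleast_2d(src), np.atleast_2d(tgt)
    index = {g: i for i, g in enumerate(gene_ids)}
    out = {}
    for name, markers in marker_sets.items():
        if not markers:
            raise ValueError(f"marker set {name!r} is empty")
        missing = [m for m in markers if m not in index]
        if missing:
            raise ValidationError(f"markers not in vocabulary: {missing}")
        cols = [index[m] for m in markers]
        out[name] = (tgt_vals[:, cols] - src_vals[:, cols]).mean(axis=1)
    return pd.DataFrame(out)


def prediction_score(
    probs: np.ndarray,
    candidate_genes: list[str],
    driver_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Mean likelihood score over each curated driver set, per pair."""
    probs = np.atleast_2d(probs)
    index = {g: i for i, g in enumerate(candidate_genes)}
    out = {}
    for name, genes in driver_sets.items():
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(
                f"driver set {name!r} members outside candidates: {missing}"
            )
        out[name] = probs[:, [index[g] for g in genes]].mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# DGE baseline


def _leiden_clusters(
    values: np.ndarray, n_clusters: tuple[int, int], seed: int
) -> np.ndarray:
    """Graph-based clustering with the resolution tuned so the number of
    communities lands inside ``n_clusters`` (warning + proceed if not)."""
    import anndata
    import scanpy as sc

    ad = anndata.AnnData(values.astype(np.float32))
    sc.pp.neighbors(ad, n_neighbors=15, use_rep="X", random_state=seed)
    lo, hi = n_clusters
    res, best = 1.0, None
    for _ in range(12):
        sc.tl.leiden(
            ad, resolution=res, key_added="leiden", random_state=seed,
            flavor="leidenalg",
        )
        k = ad.obs["leiden"].nunique()
        best = ad.obs["leiden"].cat.codes.to_numpy()
        if lo <= k <= hi:
            return best
        res *= 1.6 if k < lo else 0.65
    logger.warning("cluster count %d outside [%d, %d]; proceeding", k, lo, hi)
    return best


def dge_baseline_ranking(
    src_cells: CountMatrix,
    tgt_cells: CountMatrix,
    n_clusters: tuple[int, int] = (20, 40),
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[int, pd.DataFrame], np.ndarray]:
    """Differential-expression driver ranking baseline.

    Target cells are normalized, log-transformed and Leiden-clustered into
    roughly ``n_clusters`` groups; each cluster is tested per gene against
    the pooled source reference with a two-sided rank-sum test
    (tie-corrected normal approximation), BH-adjusted, and genes
    significant at ``alpha`` are ranked by |log2 fold change| descending.

    Returns (cluster -> ranking table, cluster id per target cell).
    """
    if src_cells.n_cells == 0 or tgt_cells.n_cells == 0:
        raise ValidationError("both groups must be non-empty")
    if src_cells.gene_ids != tgt_cells.gene_ids:
        raise ValidationError("source and target gene ids differ")
    from .data_core import normalize_rows

    src = normalize_rows(src_cells.counts)
    tgt = normalize_rows(tgt_cells.counts)
    clusters = _leiden_clusters(tgt, n_clusters, seed)
    genes = np.array(src_cells.gene_ids)
    rankings: dict[int, pd.DataFrame] = {}
    for c in np.unique(clusters):
        grp = tgt[clusters == c]
        with np.errstate(all="ignore"):
            stat, pval = scipy.stats.mannwhitneyu(
                grp, src, axis=0, alternative="two-sided", method="asymptotic"
            )
        pval = np.nan_to_num(pval, nan=1.0)
        # means are on the L=1e4 proportion scale; the +1 pseudocount keeps
        # all-zero cluster genes from producing unbounded fold changes
        lfc = np.log2(
            (np.expm1(grp).mean(axis=0) + 1.0)
            / (np.expm1(src).mean(axis=0) + 1.0)
        )
        reject, qval, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
        sig = np.flatnonzero(reject)
        order = sig[np.lexsort((sig, -np.abs(lfc[sig])))]
        rankings[int(c)] = pd.DataFrame(
            {
                "gene": genes[order],
                "log2fc": lfc[order],
                "pval": pval[order],
                "qval": qval[order],
            }
        ).reset_index(drop=True)
    return rankings, clusters


def dge_candidate_ranks(
    rankings: dict[int, pd.DataFrame],
    clusters: np.ndarray,
    drivers: list[str],
    candidate_genes: list[str],
) -> np.ndarray:
    """Per-target-cell rank of its true driver within the candidate pool.

    A cluster's significant genes are taken in ranking order restricted to
    the candidate pool; candidates absent from the list follow, ordered by
    candidate index (deterministic).
    """
    cand = list(candidate_genes)
    per_cluster: dict[int, dict[str, int]] = {}
    for c, table in rankings.items():
        listed = [g for g in table["gene"] if g in set(cand)]
        rest = [g for g in cand if g not in set(listed)]
        per_cluster[c] = {g: i + 1 for i, g in enumerate(listed + rest)}
    return np.array(
        [per_cluster[int(c)][d] for c, d in zip(clusters, drivers)], dtype=np.int64
    )
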