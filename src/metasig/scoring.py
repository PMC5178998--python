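"""Metagene scoring: median summaries of gene clusters, high/low calls,
inter-metagene correlation structure, and a hypergeometric utility for
suggesting cluster labels from named gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MetageneMatrix, Signature, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "score_metagenes",
    "dichotomize",
    "metagene_correlations",
    "enrichment_label",
]


def score_metagenes(m: ExpressionMatrix, sig: Signature) -> MetageneMatrix:
    """Per-sample metagene score = median expression of the cluster's genes.

    Signature genes absent from the matrix are skipped with a warning;
    clusters with no present gene are dropped.
    """
    if len(sig) == 0:
        raise ValidationError("empty signature")
    rows = {}
    for label in sig.cluster_labels:
        genes = sig.cluster_genes(label)
        present = [g for g in genes if g in m.gene_ids]
        missing = set(genes) - set(present)
        if missing:
            logger.warning(
                "cluster %s: skipping %d signature gene(s) absent from the matrix",
                label,
                len(missing),
            )
        if not present:
            logger.warning("cluster %s has no gene in the matrix; dropped", label)
            continue
        rows[label] = np.median(m.values.loc[present].to_numpy(dtype=float), axis=0)
    if not rows:
        raise ValidationError("no signature cluster has genes in the matrix")
    scores = pd.DataFrame(rows, index=m.sample_ids).T
    return MetageneMatrix(scores=scores)


def dichotomize(mm: MetageneMatrix) -> MetageneMatrix:
    """Per-cluster high/low status at the across-sample median.

    A sample is "high" when its score is strictly above the cluster's
    median over the cohort passed in; ties at the median go to "low".
    """
    med = mm.scores.median(axis=1)
    status = pd.DataFrame(
        np.where(mm.scores.gt(med, axis=0), "high", "low"),
        index=mm.scores.index,
        columns=mm.scores.columns,
    )
    return MetageneMatrix(scores=mm.scores, status=status)


def metagene_correlations(mm: MetageneMatrix) -> pd.DataFrame:
    """Pairwise Pearson r between metagene score rows (unit diagonal).

    Constant metagenes yield NaN off-diagonal entries rather than numbers.
    """
    if mm.scores.shape[0] < 2 or mm.scores.shape[1] < 3:
        raise ValidationError("need >= 2 clusters and >= 3 samples")
    vals = mm.scores.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    r[sds == 0, :] = np.nan
    r[:, sds == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=mm.cluster_labels, columns=mm.cluster_labels)


def enrichment_label(
    cluster_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each named set in a cluster.

    Returns one row per set with overlap, tail p (probability of an
    overlap at least as large under random draws from the universe), and
    Benjamini-Hochberg adjusted p across sets; the top row is the
    suggested label.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    cluster = set(cluster_genes) & uni
    rows = []
    for name, members in gene_sets.items():
        hits = set(members) & uni
        overlap = len(cluster & hits)
        # P(X >= overlap), X ~ Hypergeom(N=|uni|, K=|hits|, n=|cluster|)
        p = float(hypergeom.sf(overlap - 1, len(uni), len(hits), len(cluster)))
        rows.append((name, len(hits), overlap, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return df
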