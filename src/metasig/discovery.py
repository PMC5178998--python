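"""Network-driven gene signature discovery.

The selection funnel: (1) keep high-variance genes, (2) consensus-cluster
them by resampled agglomerative Ward clustering on a Pearson distance,
(3) within each cluster keep genes backed by a confident interaction edge
to another cluster member, (4) within each cluster keep the largest group
of genes connected by pairwise expression correlation at or above the
threshold.  Survivors form the signature; every gene entering the funnel
keeps an audit trail of which filters it passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linkage import cut_merges, ward_linkage
from .config import PipelineConfig
from .containers import ExpressionMatrix, InteractionNetwork, Signature, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "filter_variable_genes",
    "pearson_distance",
    "ConsensusResult",
    "consensus_cluster",
    "network_filter",
    "correlation_filter",
    "discover_signature",
    "cluster_samples",
]

#: Pairs never drawn together in any resample leave consensus entries
#: undefined; more than this fraction of them aborts the run.
MAX_UNDEFINED_PAIR_FRACTION = 0.01


def filter_variable_genes(m: ExpressionMatrix, sd_threshold: float) -> list[str]:
    """Genes whose across-sample sd (ddof=1) strictly exceeds the threshold."""
    sd = m.values.std(axis=1, ddof=1)
    return list(m.gene_ids[(sd > sd_threshold).to_numpy()])


def _pearson_distance_from_rows(rows: np.ndarray, names) -> np.ndarray:
    sds = rows.std(axis=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance item(s): {[names[i] for i in zero[:5]]}; filter first"
        )
    r = np.corrcoef(rows)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def pearson_distance(m: ExpressionMatrix, axis: str = "genes") -> pd.DataFrame:
    """1 - Pearson r between genes (axis="genes") or samples (axis="samples")."""
    if axis == "genes":
        rows, names = m.values.to_numpy(dtype=float), list(m.gene_ids)
    elif axis == "samples":
        rows, names = m.values.to_numpy(dtype=float).T, list(m.sample_ids)
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    if len(names) < 2:
        raise ValidationError("need at least two items for a distance matrix")
    d = _pearson_distance_from_rows(rows, names)
    return pd.DataFrame(d, index=names, columns=names)


@dataclass
class ConsensusResult:
    """Output of resampled consensus clustering over genes.

    ``consensus[k]`` holds the items x items co-clustering proportion
    (co-clustered count over co-sampled count; diagonal 1).  ``areas`` are
    the areas under each k's consensus-entry CDF, ``delta_areas`` the
    standard relative gains used to pick ``chosen_k``, and ``labels[k]``
    the Ward cut of (1 - consensus) at k clusters.
    """

    items: list[str]
    consensus: dict[int, pd.DataFrame]
    areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    labels: dict[int, pd.Series] = field(default_factory=dict)
    undefined_pair_fraction: float = 0.0

    def chosen_labels(self) -> pd.Series:
        return self.labels[self.chosen_k]


def consensus_cluster(m: ExpressionMatrix, cfg: PipelineConfig) -> ConsensusResult:
    """Resampled Ward/Pearson consensus clustering of the matrix's genes.

    Each resample draws ceil(resample_fraction * n) genes without
    replacement, Ward-clusters them on Pearson distance, and cuts the
    dendrogram at every candidate k; co-clustering counts over co-sampling
    counts give the per-k consensus matrices.  Unless ``cfg.fixed_k`` pins
    the cluster count, the k with the largest relative gain in consensus-CDF
    area is chosen.
    """
    items = list(m.gene_ids)
    n = len(items)
    if n < 2:
        raise ValidationError("need at least two genes to cluster")
    ks = cfg.ks()
    n_sub = int(np.ceil(cfg.resample_fraction * n))
    if max(ks) > n_sub:
        raise ValidationError(
            f"k={max(ks)} exceeds the resample size {n_sub}; "
            "lower k_range or raise resample_fraction"
        )
    rows = m.values.to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.rng_seed), 10]))

    co_sample = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    for _ in range(cfg.n_resamples):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        d = _pearson_distance_from_rows(rows[idx], [items[i] for i in idx])
        Z = ward_linkage(d) if n_sub > 1 else None
        co_sample[np.ix_(idx, idx)] += 1.0
        for k in ks:
            labels = cut_merges(Z, n_sub, min(k, n_sub))
            for lab in range(labels.max() + 1):
                members = idx[labels == lab]
                co_cluster[k][np.ix_(members, members)] += 1.0

    offdiag = ~np.eye(n, dtype=bool)
    never = (co_sample == 0) & offdiag
    undef_frac = float(never.sum() / offdiag.sum())
    if undef_frac >= MAX_UNDEFINED_PAIR_FRACTION:
        raise ValidationError(
            f"{100 * undef_frac:.2f}% of gene pairs were never co-sampled; "
            "increase n_resamples or resample_fraction"
        )

    consensus: dict[int, pd.DataFrame] = {}
    areas: dict[int, float] = {}
    labels_by_k: dict[int, pd.Series] = {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), np.nan)
        c[co_sample == 0] = np.nan
        np.fill_diagonal(c, 1.0)
        entries = c[offdiag]
        entries = entries[~np.isnan(entries)]
        # area under the consensus-entry CDF on [0,1] equals 1 - mean entry
        areas[k] = float(1.0 - entries.mean()) if entries.size else 0.0
        cdf_dist = 1.0 - np.where(np.isnan(c), 0.0, c)
        np.fill_diagonal(cdf_dist, 0.0)
        cdf_dist = 0.5 * (cdf_dist + cdf_dist.T)
        if n > 1:
            final = cut_merges(ward_linkage(cdf_dist), n, min(k, n))
        else:
            final = np.zeros(1, dtype=int)
        labels_by_k[k] = pd.Series(final, index=items, name=f"k{k}")
        consensus[k] = pd.DataFrame(c, index=items, columns=items)

    deltas: dict[int, float] = {}
    running_max = None
    for k in ks:
        if running_max is None:
            deltas[k] = areas[k]
        else:
            gain = (areas[k] - running_max) / running_max if running_max > 0 else 0.0
            deltas[k] = max(gain, 0.0)
        running_max = areas[k] if running_max is None else max(running_max, areas[k])
    if cfg.fixed_k is not None:
        chosen = cfg.fixed_k
    else:
        chosen = max(ks, key=lambda k: (deltas[k], -k))
    return ConsensusResult(
        items=items,
        consensus=consensus,
        areas=areas,
        delta_areas=deltas,
        chosen_k=chosen,
        labels=labels_by_k,
        undefined_pair_fraction=undef_frac,
    )


def network_filter(
    cluster_genes: list[str], net: InteractionNetwork, score_threshold: float
) -> list[str]:
    """Genes with a confident edge to another gene of the same cluster.

    A gene survives only if some incident edge has score >= threshold and
    its other endpoint is also in ``cluster_genes``; genes absent from the
    network are removed.
    """
    in_cluster = set(cluster_genes)
    kept = []
    g = net.graph
    for gene in cluster_genes:
        if gene not in g:
            continue
        for nbr, data in g[gene].items():
            if nbr in in_cluster and data["score"] >= score_threshold:
                kept.append(gene)
                break
    return kept


def correlation_filter(
    m: ExpressionMatrix, genes: list[str], r_threshold: float
) -> list[list[str]]:
    """Connected components of the pairwise-correlation graph (size >= 2).

    Two genes are linked when their Pearson r across samples is at least
    the threshold (signed, not absolute).  Singleton components are
    dropped.  Components are returned in order of their first gene.
    """
    genes = [g for g in genes if g in m.gene_ids]
    if len(genes) < 2:
        return []
    rows = m.values.loc[genes].to_numpy(dtype=float)
    sds = rows.std(axis=1)
    keep = sds > 0
    genes = [g for g, k in zip(genes, keep) if k]
    rows = rows[keep]
    if len(genes) < 2:
        return []
    r = np.corrcoef(rows)
    adj = r >= r_threshold
    np.fill_diagonal(adj, False)
    # union-find over the adjacency
    parent = list(range(len(genes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i, g in enumerate(genes):
        groups.setdefault(find(i), []).append(g)
    return [grp for _, grp in sorted(groups.items()) if len(grp) >= 2]


def discover_signature(
    m: ExpressionMatrix, net: InteractionNetwork, cfg: PipelineConfig
) -> tuple[Signature, ConsensusResult | None]:
    """Run the full selection funnel and return the signature with audit flags.

    Within each consensus cluster the network filter runs first, then the
    correlation filter; the largest surviving correlation group inherits
    the cluster's label and smaller groups are logged and dropped.
    """
    var_genes = filter_variable_genes(m, cfg.sd_threshold)
    all_genes = list(m.gene_ids)
    prov = pd.DataFrame(
        False,
        index=pd.Index(all_genes, name="gene"),
        columns=["passed_variance", "passed_network", "passed_correlation"],
    )
    prov.loc[var_genes, "passed_variance"] = True
    if len(var_genes) < 2:
        logger.warning("fewer than two variable genes; empty signature")
        return Signature(pd.Series(dtype=str), prov), None

    sub = m.subset_genes(var_genes)
    cres = consensus_cluster(sub, cfg)
    cluster_labels = cres.chosen_labels()

    assignments: dict[str, str] = {}
    for lab in sorted(cluster_labels.unique()):
        cluster_genes = list(cluster_labels.index[cluster_labels == lab])
        kept_net = network_filter(cluster_genes, net, cfg.network_score_threshold)
        prov.loc[kept_net, "passed_network"] = True
        groups = correlation_filter(sub, kept_net, cfg.correlation_threshold)
        for grp in groups:
            prov.loc[grp, "passed_correlation"] = True
        if not groups:
            logger.info("cluster %s: no correlation group survived", lab)
            continue
        sizes = [len(g) for g in groups]
        best = groups[int(np.argmax(sizes))]  # ties -> earliest first gene
        for grp in groups:
            if grp is not best:
                logger.info(
                    "cluster %s: dropping smaller correlation group of %d gene(s)",
                    lab,
                    len(grp),
                )
        for gene in best:
            assignments[gene] = f"C{int(lab) + 1}"
    assigned = pd.Series(assignments, dtype=str)
    assigned = assigned.reindex([g for g in all_genes if g in assignments])
    sig = Signature(assigned, prov)
    logger.info(
        "signature: %d gene(s) in %d cluster(s) from %d variable gene(s)",
        len(sig),
        len(sig.cluster_labels),
        len(var_genes),
    )
    return sig, cres


def cluster_samples(m: ExpressionMatrix, signature: Signature, k: int) -> pd.Series:
    """Ward/Pearson clustering of samples on the signature genes; k-cut labels."""
    if k > len(m.sample_ids):
        raise ValidationError(f"k={k} exceeds the number of samples")
    genes = [g for g in signature.genes if g in m.gene_ids]
    if not genes:
        raise ValidationError("no signature gene present in the matrix")
    sub = m.subset_genes(genes)
    if k == 1:
        return pd.Series(0, index=m.sample_ids, name="sample_cluster")
    d = pearson_distance(sub, axis="samples")
    labels = cut_merges(ward_linkage(d.to_numpy()), len(d), k)
    return pd.Series(labels, index=m.sample_ids, name="sample_cluster")
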