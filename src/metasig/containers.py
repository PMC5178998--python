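"""In-memory containers shared across the pipeline.

The substrate of every stage is a genes x samples expression matrix on a
log scale; downstream stages pass around a gene->cluster signature, an
undirected weighted interaction graph, and a clusters x samples metagene
matrix with per-sample high/low calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "InteractionNetwork",
    "Signature",
    "MetageneMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violated a structural precondition (duplicate ids, bad range...)."""


@dataclass
class ExpressionMatrix:
    """Continuous log-scale expression, genes as rows and samples as columns.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    datasets
        Optional per-sample dataset (batch) label; normalization steps that
        operate within dataset use it. When ``None`` all samples are treated
        as a single dataset.
    """

    values: pd.DataFrame
    datasets: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.datasets is not None:
            self.datasets = self.datasets.reindex(cols)
            if self.datasets.isna().any():
                missing = self.datasets.index[self.datasets.isna()].tolist()
                raise ValidationError(f"samples without a dataset label: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dataset_groups(self) -> list[tuple[str, pd.Index]]:
        """Sample columns grouped by dataset label (one group if unlabeled)."""
        if self.datasets is None:
            return [("all", self.sample_ids)]
        out = []
        for label in pd.unique(self.datasets):
            out.append((label, self.sample_ids[(self.datasets == label).to_numpy()]))
        return out

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        ds = None if self.datasets is None else self.datasets.reindex(values.columns)
        return ExpressionMatrix(values, ds)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[:, samples])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.datasets)


@dataclass
class InteractionNetwork:
    """Undirected gene graph with confidence scores in [0, 1] on the edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges) -> "InteractionNetwork":
        """Build from an iterable of (gene_a, gene_b, score).

        Self-loops are dropped; duplicate edges keep the maximum score.
        """
        g = nx.Graph()
        for a, b, s in edges:
            s = float(s)
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"edge score {s} for ({a},{b}) outside [0, 1]")
            if a == b:
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
        return cls(g)

    def score(self, a, b) -> float | None:
        if self.graph.has_edge(a, b):
            return self.graph[a][b]["score"]
        return None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


PROVENANCE_FLAGS = ("passed_variance", "passed_network", "passed_correlation")


@dataclass
class Signature:
    """Gene -> cluster assignment with per-gene filter provenance.

    ``assignments`` holds only the retained genes.  ``provenance`` records,
    for every gene that entered the selection funnel, which filters it
    passed, so that the selection can be audited gene by gene.
    """

    assignments: pd.Series
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.assignments = self.assignments.astype(str)
        if self.provenance is None:
            prov = pd.DataFrame(
                True, index=self.assignments.index, columns=list(PROVENANCE_FLAGS)
            )
            self.provenance = prov
        for gene in self.assignments.index:
            row = self.provenance.loc[gene]
            if not bool(row.all()):
                raise ValidationError(
                    f"assigned gene {gene!r} has a failing provenance flag"
                )

    @property
    def genes(self) -> pd.Index:
        return self.assignments.index

    @property
    def cluster_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.assignments:
            seen.setdefault(lab, None)
        return list(seen)

    def cluster_genes(self, label: str) -> list[str]:
        return list(self.assignments.index[self.assignments == label])

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class MetageneMatrix:
    """Per-sample metagene scores (clusters x samples) and high/low status.

    A metagene score is the median expression of the cluster's genes in a
    sample; status dichotomizes each cluster's scores at the across-sample
    median (strictly above -> "high", ties -> "low").
    """

    scores: pd.DataFrame
    status: pd.DataFrame | None = None

    @property
    def cluster_labels(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns

    def high_mask(self, cluster: str) -> np.ndarray:
        if self.status is None:
            raise ValidationError("status not computed; call dichotomize first")
        return (self.status.loc[cluster] == "high").to_numpy()
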