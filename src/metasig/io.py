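"""Readers and writers for the on-disk formats.

Expression travels as plain TSV with a leading id column (GCT accepted
read-only); interaction networks as String-style three-column edge lists;
signatures as two-column gene/cluster TSV plus provenance flags; clinical
data as CSV with a documented column dictionary (see
:mod:`metasig.associations`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PROVENANCE_FLAGS,
    ExpressionMatrix,
    InteractionNetwork,
    Signature,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_signature",
    "write_signature",
    "read_clinical",
    "write_clinical",
]

#: Genes with more than this fraction of missing values are dropped on read.
MAX_MISSING_FRACTION = 0.20

_NA_TOKENS = ["", "NA", "NaN", "nan", "null", "None"]


def _parse_table(path: Path) -> pd.DataFrame:
    """Read a TSV (or GCT) table with the first column as row identifiers."""
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#1.2"):
        skip = 2  # GCT: version line + dimensions line
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        skiprows=skip,
        na_values=_NA_TOKENS,
        keep_default_na=False,
    )
    if skip and "Description" in df.columns:
        df = df.drop(columns=["Description"])
    return df


def read_expression(
    path: str | Path,
    orientation: str = "rows-are-genes",
    datasets: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV/GCT into canonical genes x samples orientation.

    Non-numeric cells raise a parse error naming the offending row and
    column.  Genes with more than 20% missing values are dropped with a
    warning; remaining gaps are imputed by the gene median so that every
    downstream stage sees finite values.
    """
    if orientation not in ("rows-are-genes", "rows-are-samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = _parse_table(path)
    if orientation == "rows-are-samples":
        df = df.T
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ValidationError(
                f"non-numeric expression value at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    df = df.astype(float)

    missing_frac = df.isna().mean(axis=1)
    to_drop = df.index[(missing_frac > MAX_MISSING_FRACTION).to_numpy()]
    if len(to_drop):
        logger.warning(
            "dropping %d gene(s) with >%.0f%% missing values: %s",
            len(to_drop),
            100 * MAX_MISSING_FRACTION,
            list(to_drop[:5]),
        )
        df = df.drop(index=to_drop)
    if df.isna().to_numpy().any():
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
    return ExpressionMatrix(df, datasets)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_network(path: str | Path, score_scale: str = "unit") -> InteractionNetwork:
    """Read a String-style three-column edge list (gene_a, gene_b, score).

    ``score_scale`` is ``"unit"`` for scores already in [0, 1] or
    ``"string-0-1000"`` for the String export convention (divided by 1000).
    Duplicate edges keep the maximum score; self-loops contribute the node
    but no edge.
    """
    if score_scale not in ("unit", "string-0-1000"):
        raise ValidationError(f"unknown score scale {score_scale!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError("network file must have three columns: gene_a, gene_b, score")
    a, b, s = df.columns[:3]
    scores = pd.to_numeric(df[s], errors="coerce")
    if scores.isna().any():
        raise ValidationError("non-numeric interaction score in network file")
    hi = 1000.0 if score_scale == "string-0-1000" else 1.0
    if (scores < 0).any() or (scores > hi).any():
        raise ValidationError(f"interaction score outside declared scale [0, {hi:g}]")
    vals = scores.to_numpy(dtype=float) / hi
    return InteractionNetwork.from_edges(
        zip(df[a].astype(str), df[b].astype(str), vals)
    )


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    rows = [
        (a, b, d["score"]) for a, b, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_signature(path: str | Path) -> Signature:
    """Read a signature TSV: gene, cluster_label [, provenance flags]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "cluster_label" not in df.columns:
        raise ValidationError("signature file needs 'gene' and 'cluster_label' columns")
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate gene in signature file")
    df = df.set_index("gene")
    assigned = df.index[df["cluster_label"].notna().to_numpy()]
    assignments = df.loc[assigned, "cluster_label"]
    prov = None
    if set(PROVENANCE_FLAGS).issubset(df.columns):
        prov = df[list(PROVENANCE_FLAGS)].apply(
            lambda c: c.str.lower().isin(["true", "1"])
        )
    return Signature(assignments, prov)


def write_signature(sig: Signature, path: str | Path) -> None:
    prov = sig.provenance
    df = prov.copy()
    df.insert(0, "cluster_label", sig.assignments.reindex(prov.index))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


CLINICAL_COLUMNS = {
    "sample_id": "unique sample identifier (index column)",
    "er_status": "estrogen receptor status: positive/negative",
    "pr_status": "progesterone receptor status: positive/negative",
    "ar_status": "androgen receptor status: positive/negative",
    "age_class": "age category",
    "size_class": "tumor size category",
    "nodal_status": "lymph-node involvement: N-/N+",
    "grade_class": "tumor grade category",
    "pcr": "pathological complete response after NAC: 0/1",
    "time": "follow-up time in months",
    "event": "1 = disease-specific death, 0 = censored",
    "til_intratumoral_pct": "intratumoral lymphocyte percentage, 0-100",
    "til_stromal_pct": "stromal lymphocyte percentage, 0-100",
}


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical CSV, indexed by sample_id.

    All columns beyond sample_id are optional; the validation checks only
    the constraints of the columns actually present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clinical file not found: {path}")
    df = pd.read_csv(path, na_values=_NA_TOKENS, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError("clinical file needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in clinical file")
    df = df.set_index("sample_id")
    if "event" in df.columns and "time" in df.columns:
        has_event = df["event"].notna()
        if (has_event & df["time"].isna()).any():
            raise ValidationError("event recorded without a survival time")
    if "time" in df.columns and (df["time"].dropna() < 0).any():
        raise ValidationError("negative survival time")
    for col in ("til_intratumoral_pct", "til_stromal_pct"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} outside [0, 100]")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
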