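"""Normalization and bimodal-marker sample stratification.

Batch effects are removed by per-dataset median centering of each gene and
a per-dataset quantile normalization of the sample columns.  Samples are
then stratified as marker-positive (HER2-like) or negative by fitting a
two-component Gaussian mixture to the marker gene's bimodal expression and
cutting at the equal-posterior point between the component means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata
from sklearn.mixture import GaussianMixture

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "median_center",
    "quantile_normalize",
    "BimodalFit",
    "fit_bimodal_cutoff",
    "select_positive",
]


def _check_nonempty(m: ExpressionMatrix) -> None:
    if m.values.size == 0:
        raise ValidationError("empty expression matrix")


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's within-dataset median; idempotent."""
    _check_nonempty(m)
    out = m.values.copy()
    for _, cols in m.dataset_groups():
        block = out.loc[:, cols]
        out.loc[:, cols] = block.sub(block.median(axis=1), axis=0)
    return m.with_values(out)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample within a dataset onto the mean sorted profile.

    The reference distribution is the mean of the sorted sample columns;
    tied values within a sample share the mean of their tied reference
    positions.  Applied independently per dataset label.
    """
    _check_nonempty(m)
    out = m.values.copy()
    for _, cols in m.dataset_groups():
        block = out.loc[:, cols].to_numpy(dtype=float)
        ref = np.sort(block, axis=0).mean(axis=1)
        for c in range(block.shape[1]):
            col = block[:, c]
            order = np.argsort(col, kind="stable")
            mapped = np.empty_like(col)
            mapped[order] = ref
            # ties share the mean of their assigned reference positions
            ranks = rankdata(col, method="average")
            if len(np.unique(ranks)) != len(ranks):
                df = pd.DataFrame({"v": col, "m": mapped})
                mapped = df.groupby("v")["m"].transform("mean").to_numpy()
            block[:, c] = mapped
        out.loc[:, cols] = block
    return m.with_values(out)


@dataclass
class BimodalFit:
    """Two-component Gaussian mixture fit to a marker gene.

    Components are ordered so ``means[0] < means[1]``; ``cutoff`` is the
    expression value between the means where the posterior membership
    probabilities of the two components are equal.  ``unimodal_warning``
    flags fits whose mean separation is under one pooled standard
    deviation, i.e. effectively unimodal data.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    cutoff: float
    converged: bool
    log_likelihood: float
    unimodal_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "cutoff": self.cutoff,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "unimodal_warning": self.unimodal_warning,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


#: EM controls: tolerance on the per-sample log-likelihood change,
#: iteration cap, number of quantile-based starts.  1e-6 lets weakly
#: separated (effectively unimodal) mixtures converge to the warning path
#: instead of erroring out at the iteration cap.
EM_TOL = 1e-6
EM_MAX_ITER = 500
EM_N_STARTS = 5


def _equal_posterior_cutoff(w, mu, sd) -> float:
    """Root of w0 N(x|mu0,sd0) = w1 N(x|mu1,sd1) between the means."""

    def diff(x: float) -> float:
        return w[0] * norm.pdf(x, mu[0], sd[0]) - w[1] * norm.pdf(x, mu[1], sd[1])

    lo, hi = mu[0], mu[1]
    try:
        if diff(lo) * diff(hi) < 0:
            return float(brentq(diff, lo, hi, xtol=1e-10))
    except ValueError:
        pass
    # no sign change (extreme weights / unequal sds): nearest-to-zero point
    grid = np.linspace(lo, hi, 2001)
    return float(grid[np.argmin(np.abs(diff(grid)))])


def fit_bimodal_cutoff(values) -> BimodalFit:
    """Fit the marker mixture by EM with quantile-based multi-starts.

    Each start initializes the component means at a pair of quantiles
    straddling the median; the best-log-likelihood converged fit is kept.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size < 10:
        raise ValidationError("need at least 10 finite values for a bimodal fit")
    if np.ptp(x) == 0:
        raise ValidationError("all marker values identical; no mixture exists")

    starts = [(0.25, 0.75), (0.10, 0.90), (0.33, 0.67), (0.05, 0.95), (0.40, 0.60)]
    best = None
    x2 = x.reshape(-1, 1)
    for qlo, qhi in starts[:EM_N_STARTS]:
        init = np.array([[np.quantile(x, qlo)], [np.quantile(x, qhi)]])
        gm = GaussianMixture(
            n_components=2,
            covariance_type="spherical",
            tol=EM_TOL,
            max_iter=EM_MAX_ITER,
            means_init=init,
            weights_init=np.array([0.5, 0.5]),
            n_init=1,
            reg_covar=1e-10,
        )
        gm.fit(x2)
        ll = float(gm.score(x2)) * x.size
        if gm.converged_ and (best is None or ll > best[0]):
            best = (ll, gm)
    if best is None:
        raise ValidationError(
            f"EM did not converge in {EM_MAX_ITER} iterations on any of "
            f"{EM_N_STARTS} starts (n={x.size})"
        )
    ll, gm = best
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_.ravel()[order]
    if mu[1] - mu[0] < 1e-9:
        raise ValidationError("degenerate mixture: component means coincide")
    pooled = float(np.sqrt(w[0] * sd[0] ** 2 + w[1] * sd[1] ** 2))
    unimodal = bool((mu[1] - mu[0]) < pooled)
    if unimodal:
        logger.warning(
            "marker distribution looks unimodal (separation %.3g < pooled sd %.3g)",
            mu[1] - mu[0],
            pooled,
        )
    cutoff = _equal_posterior_cutoff(w, mu, sd)
    return BimodalFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        cutoff=cutoff,
        converged=True,
        log_likelihood=ll,
        unimodal_warning=unimodal,
    )


def select_positive(
    m: ExpressionMatrix, marker: str, fit: BimodalFit
) -> ExpressionMatrix:
    """Samples with marker expression strictly above the cutoff.

    Ties at the cutoff are called negative; an empty selection is legal
    and logged.
    """
    if marker not in m.gene_ids:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")
    mask = (m.values.loc[marker] > fit.cutoff).to_numpy()
    if not mask.any():
        logger.warning("no sample exceeds the marker cutoff %.4g", fit.cutoff)
    return m.subset_samples(m.sample_ids[mask])
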