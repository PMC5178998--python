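"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants block-correlated gene modules (one latent factor per
module, so the implied covariance is positive semi-definite by
construction), an interaction network that is dense within modules and
sparse/weak elsewhere, a bimodally expressed receptor-like marker gene, and
clinical outcomes (hormone-receptor status, treatment response, censored
survival, lymphocyte-infiltration percentages) driven by the true module
scores through logistic, proportional-hazards and linear links.

Defaults mirror the published six-cluster signature: module sizes
28/11/20/22/36/21 (138 genes), an immune-vs-hormonal score correlation of
-0.46, a treatment-response odds ratio near 3.7 and a survival hazard
ratio near 0.58 for the immune-high stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InteractionNetwork, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_network",
    "simulate_clinical",
    "DEFAULT_MODULE_NAMES",
]

DEFAULT_MODULE_NAMES = (
    "immunity",
    "interferon",
    "signal_transduction",
    "hormonal_survival",
    "proliferation",
    "matrix",
)

DEFAULT_MODULE_SIZES = (28, 11, 20, 22, 36, 21)


def _default_cross_rho() -> np.ndarray:
    m = np.eye(len(DEFAULT_MODULE_SIZES))
    # immune and hormonal/survival scores anticorrelated
    m[0, 3] = m[3, 0] = -0.46
    return m


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Expression: each module m has a standard-normal latent score z_m per
    sample (scores correlated across modules via ``cross_module_rho``); a
    module gene is sqrt(rho) * z_m + sqrt(1-rho) * noise, so any two genes
    of the module correlate at ``within_module_rho`` in expectation and
    every gene has unit variance.  Noise genes are independent
    N(0, noise_sd^2).  The marker gene is a two-component Gaussian mixture
    whose high component models receptor-amplified samples.

    Clinical: ER-positivity is Bernoulli with a logit linear in the immune
    score; treatment response (pCR) follows a logistic model in ER status,
    dichotomized immune score and grade; survival is exponential with a
    proportional-hazards rate, censored administratively; lymphocyte
    percentages are a clipped linear function of the immune score.
    """

    n_samples: int = 300
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    module_names: tuple[str, ...] = DEFAULT_MODULE_NAMES
    within_module_rho: float | tuple[float, ...] = 0.8
    cross_module_rho: np.ndarray = field(default_factory=_default_cross_rho)
    n_noise_genes: int = 60
    noise_sd: float = 0.5
    # marker mixture: (high-component weight, mean_low, mean_high, sd)
    marker_mix: tuple[float, float, float, float] = (0.5, 0.0, 5.0, 0.5)
    marker_name: str = "ERBB2"
    immune_module: str = "immunity"
    # network
    p_in: float = 1.0
    p_decoy: float = 0.02
    isolated_fraction: float = 0.0
    # clinical links
    er_logit_intercept: float = 0.0
    er_logit_slope: float = -1.5
    pcr_intercept: float = -1.1
    pcr_log_or: dict = field(
        default_factory=lambda: {
            "er_positive": math.log(0.29),
            "immunity_high": math.log(3.71),
            "grade_high": math.log(4.16),
        }
    )
    cox_log_hr: dict = field(
        default_factory=lambda: {
            "immunity_high": math.log(0.58),
            "nodal_positive": math.log(3.29),
        }
    )
    baseline_hazard: float = 0.01  # events per month
    censor_rate: float = 0.3
    til_intercept: float = 16.5
    til_slope: float = 9.4
    til_sd: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if any(s < 1 for s in self.module_sizes):
            raise ValidationError("module sizes must be positive")
        self.module_names = tuple(self.module_names)[: len(self.module_sizes)]
        if len(self.module_names) != len(self.module_sizes):
            self.module_names = tuple(
                f"module_{i + 1}" for i in range(len(self.module_sizes))
            )
        rhos = self.rhos()
        if any(not (0.0 < r < 1.0) for r in rhos):
            raise ValidationError("within_module_rho must lie in (0, 1)")
        c = np.asarray(self.cross_module_rho, dtype=float)
        m = len(self.module_sizes)
        if c.shape != (m, m):
            raise ValidationError(
                f"cross_module_rho must be {m}x{m} for {m} modules"
            )
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValidationError("cross_module_rho must be symmetric with unit diagonal")
        off = c[~np.eye(m, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0:
            raise ValidationError("off-diagonal correlations must have magnitude < 1")
        if c.size and np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValidationError("cross_module_rho is not positive semi-definite")
        self.cross_module_rho = c
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("noise_sd and baseline_hazard must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValidationError("censor_rate must lie in [0, 1)")
        w, lo, hi, sd = self.marker_mix
        if not (0.0 < w < 1.0) or sd <= 0 or not lo < hi:
            raise ValidationError("marker_mix must be (weight in (0,1), mean_low < mean_high, sd > 0)")

    def rhos(self) -> tuple[float, ...]:
        if np.isscalar(self.within_module_rho):
            return (float(self.within_module_rho),) * len(self.module_sizes)
        return tuple(float(r) for r in self.within_module_rho)


@dataclass
class GroundTruth:
    """Oracle record of what was planted (never consumed by the pipeline).

    ``labels`` maps each simulated gene to its module name ("none" for
    noise genes, "marker" for the mixture marker); ``scores`` holds the
    true per-sample latent module scores; ``her2`` flags samples drawn
    from the marker's high component.
    """

    labels: pd.Series
    scores: pd.DataFrame
    her2: pd.Series

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the expression matrix and its ground truth."""
    rng = _rng(config.seed, 1)
    n = config.n_samples
    names = config.module_names
    m = len(names)
    if m:
        chol = np.linalg.cholesky(config.cross_module_rho + 1e-12 * np.eye(m))
        z = chol @ rng.standard_normal((m, n))  # true module scores, m x n
    else:  # noise-only (null) simulation
        z = np.empty((0, n))

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    gene_labels: list[str] = []
    for j, (name, size, rho) in enumerate(
        zip(names, config.module_sizes, config.rhos())
    ):
        eps = rng.standard_normal((size, n))
        rows = math.sqrt(rho) * z[j] + math.sqrt(1.0 - rho) * eps
        gene_rows.append(rows)
        gene_ids.extend(f"{name.upper()}_{i + 1:03d}" for i in range(size))
        gene_labels.extend([name] * size)
    if config.n_noise_genes:
        noise = config.noise_sd * rng.standard_normal((config.n_noise_genes, n))
        gene_rows.append(noise)
        gene_ids.extend(f"NOISE_{i + 1:03d}" for i in range(config.n_noise_genes))
        gene_labels.extend(["none"] * config.n_noise_genes)

    w, mean_lo, mean_hi, sd = config.marker_mix
    high = rng.random(n) < w
    marker = np.where(high, mean_hi, mean_lo) + sd * rng.standard_normal(n)
    gene_rows.append(marker[None, :])
    gene_ids.append(config.marker_name)
    gene_labels.append("marker")

    samples = [f"S{i + 1:04d}" for i in range(n)]
    values = pd.DataFrame(np.vstack(gene_rows), index=gene_ids, columns=samples)
    truth = GroundTruth(
        labels=pd.Series(gene_labels, index=gene_ids, name="module"),
        scores=pd.DataFrame(z, index=list(names), columns=samples),
        her2=pd.Series(high, index=samples, name="her2_high"),
    )
    return ExpressionMatrix(values), truth


def simulate_network(truth: GroundTruth, config: SimulationConfig) -> InteractionNetwork:
    """String-like edge list: confident edges within modules, weak decoys elsewhere.

    Within-module pairs get an edge with probability ``p_in`` and a score
    uniform on [0.7, 0.999]; all other pairs get sparse decoy edges with
    probability ``p_decoy`` and scores uniform on [0.15, 0.699].  A fraction
    ``isolated_fraction`` of each module's genes is excluded from confident
    edges so the network filter's removal path is exercised.
    """
    rng = _rng(config.seed, 2)
    genes = list(truth.labels.index)
    labels = truth.labels.to_numpy()
    n = len(genes)
    edges: list[tuple[str, str, float]] = []

    isolated: set[str] = set()
    for name in dict.fromkeys(labels):
        if name in ("none", "marker"):
            continue
        members = [g for g, lab in zip(genes, labels) if lab == name]
        k = int(round(config.isolated_fraction * len(members)))
        if k:
            picked = rng.choice(len(members), size=k, replace=False)
            isolated.update(members[i] for i in picked)

    lab_of = dict(zip(genes, labels))
    for i in range(n):
        gi = genes[i]
        for j in range(i + 1, n):
            gj = genes[j]
            same_module = (
                lab_of[gi] == lab_of[gj]
                and lab_of[gi] not in ("none", "marker")
                and gi not in isolated
                and gj not in isolated
            )
            if same_module:
                if rng.random() < config.p_in:
                    edges.append((gi, gj, rng.uniform(0.7, 0.999)))
            else:
                if rng.random() < config.p_decoy:
                    edges.append((gi, gj, rng.uniform(0.15, 0.699)))
    net = InteractionNetwork.from_edges(edges)
    net.graph.add_nodes_from(genes)
    return net


def _calibrate_censor_horizon(times: np.ndarray, target: float, rng) -> np.ndarray:
    """Administrative censoring times U(0, tau), tau found by bisection.

    Under C ~ U(0, tau) the expected censored fraction given the observed
    event times is mean(min(T/tau, 1)); tau is bisected so that it matches
    ``target``.
    """
    if target <= 0:
        return np.full_like(times, np.inf)

    def frac(tau: float) -> float:
        return float(np.mean(np.minimum(times / tau, 1.0)))

    lo, hi = np.min(times) * 1e-3 + 1e-9, np.max(times) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    return rng.uniform(0.0, tau, size=times.shape)


def simulate_clinical(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-sample clinical table driven by the true immune module score."""
    rng = _rng(config.seed, 3)
    samples = truth.scores.columns
    n = len(samples)
    if config.immune_module in truth.scores.index:
        immune = truth.scores.loc[config.immune_module].to_numpy()
    else:  # no immune module planted: outcomes decouple from expression
        immune = np.zeros(n)
    immune_high = immune > np.median(immune)

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    er_p = logistic(config.er_logit_intercept + config.er_logit_slope * immune)
    er = rng.random(n) < er_p
    pr = rng.random(n) < np.where(er, 0.8, 0.1)
    ar = rng.random(n) < np.where(er, 0.7, 0.25)
    grade_high = rng.random(n) < 0.65
    nodal = rng.random(n) < 0.55
    age_high = rng.random(n) < 0.5
    size_class = rng.choice(["T1-T2", "T3", "T4"], size=n, p=[0.45, 0.25, 0.30])

    covars = {
        "er_positive": er.astype(float),
        "immunity_high": immune_high.astype(float),
        "grade_high": grade_high.astype(float),
        "nodal_positive": nodal.astype(float),
    }
    eta = np.full(n, config.pcr_intercept)
    for name, lor in config.pcr_log_or.items():
        if name not in covars:
            raise ValidationError(f"unknown pCR covariate {name!r}")
        eta = eta + lor * covars[name]
    pcr = (rng.random(n) < logistic(eta)).astype(int)

    log_hazard = np.log(config.baseline_hazard) * np.ones(n)
    for name, lhr in config.cox_log_hr.items():
        if name not in covars:
            raise ValidationError(f"unknown survival covariate {name!r}")
        log_hazard = log_hazard + lhr * covars[name]
    t_event = rng.exponential(scale=1.0, size=n) / np.exp(log_hazard)
    censor = _calibrate_censor_horizon(t_event, config.censor_rate, rng)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    til_raw = (
        config.til_intercept
        + config.til_slope * immune
        + config.til_sd * rng.standard_normal(n)
    )
    til_it = np.clip(til_raw, 0.0, 100.0)
    til_str = np.clip(
        til_raw + 10.0 + 0.25 * config.til_sd * rng.standard_normal(n), 0.0, 100.0
    )

    return pd.DataFrame(
        {
            "er_status": np.where(er, "positive", "negative"),
            "pr_status": np.where(pr, "positive", "negative"),
            "ar_status": np.where(ar, "positive", "negative"),
            "age_class": np.where(age_high, ">=50", "<50"),
            "size_class": size_class,
            "nodal_status": np.where(nodal, "N+", "N-"),
            "grade_class": np.where(grade_high, "III", "I-II"),
            "pcr": pcr,
            "time": time,
            "event": event,
            "til_intratumoral_pct": til_it,
            "til_stromal_pct": til_str,
        },
        index=pd.Index(samples, name="sample_id"),
    )
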