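"""Synthetic multimodal cohorts with known ground truth.

The generator emulates the structure the pipeline expects from real tumour
cohorts: pathway-clique gene networks, a latent per-sample risk factor planted
into a subset of "signal" mRNAs, miRNAs anti-correlated with those mRNAs,
methylation inversely related to them (lower methylation at higher risk),
exponential event times whose hazard follows the Cox family exp(eta), uniform
censoring, and optional missing values. All draws are deterministic given the
configured seed, so every pipeline stage is testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, special

from gcsurv.omics_io import OmicsMatrix, SurvivalTable
from gcsurv.pathway_graph import PathwayGraph

import networkx as nx


@dataclass
class SynthConfig:
    """Cohort-generation settings (defaults are the package's test fixture).

    ``censor_max=None`` solves the uniform censoring horizon so the analytic
    expected censoring fraction equals ``target_censoring``.
    """

    n_samples: int = 300
    n_mrna: int = 60
    n_mirna: int = 20
    n_meth: int = 60
    n_pathways: int = 5
    pathway_size: int = 12
    n_signal_genes: int = 10
    effect_size: float = 1.0
    baseline_rate: float = 0.1
    censor_max: float | None = None
    target_censoring: float = 0.3
    missing_rate: float = 0.0
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_mrna:
            raise ValueError("n_signal_genes must not exceed n_mrna")
        if self.pathway_size < 2:
            raise ValueError("pathway_size must be >= 2")
        if self.n_pathways * self.pathway_size != self.n_mrna:
            raise ValueError("n_pathways * pathway_size must equal n_mrna")
        if self.n_signal_genes > self.n_mirna:
            raise ValueError("need one paired miRNA per signal gene")
        if self.n_meth < self.n_mrna:
            # methylation is gene-level over the same gene set
            raise ValueError("n_meth must be >= n_mrna (gene-level methylation)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort."""

    signal_mrna: list[str]
    signal_mirna: list[str]
    signal_meth: list[str]
    effect_size: float
    latent: np.ndarray
    eta: np.ndarray
    censor_max: float
    censoring_fraction: float

    def to_json(self) -> str:
        d = asdict(self)
        d["latent"] = list(map(float, self.latent))
        d["eta"] = list(map(float, self.eta))
        return json.dumps(d, indent=2)


def expected_censoring_fraction(
    baseline_rate: float, censor_max: float, effect_size: float, n_quad: int = 64
) -> float:
    """Analytic P(C < T) for T ~ Exp(rate * e^{effect*u}), u ~ N(0,1),
    C ~ U(0, c), via Gauss-Hermite quadrature over u."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    rho = baseline_rate * np.exp(effect_size * nodes)
    frac = (1.0 - np.exp(-rho * censor_max)) / (rho * censor_max)
    return float(np.sum(weights * frac) / np.sqrt(2 * np.pi))


def solve_censor_max(
    baseline_rate: float, effect_size: float, target: float
) -> float:
    """Censoring horizon whose expected censoring fraction equals ``target``."""
    f = lambda c: expected_censoring_fraction(baseline_rate, c, effect_size) - target
    lo, hi = 1e-6, 1.0
    while f(hi) > 0:  # fraction decreases with c; expand until bracketed
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("could not bracket the censoring horizon")
    return float(optimize.brentq(f, lo, hi))


def _pathway_cliques(gene_ids: list[str], n_pathways: int) -> PathwayGraph:
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    chunks = np.array_split(np.arange(len(gene_ids)), n_pathways)
    for chunk in chunks:
        members = [gene_ids[i] for i in chunk]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j])
    return PathwayGraph(g)


def generate_cohort(
    cfg: SynthConfig,
) -> tuple[list[OmicsMatrix], SurvivalTable, PathwayGraph, SynthTruth]:
    """Generate (mRNA, miRNA, methylation) matrices, survival, network, truth.

    Signal genes are the first n_signal_genes mRNAs (spread across pathway
    cliques by construction of the partition). The per-sample latent factor
    u ~ N(0,1) enters each signal mRNA additively with weight effect_size,
    drives the paired miRNAs negatively, lowers methylation of signal genes,
    and sets the hazard through eta = effect_size * u.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed)]))
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{i:04d}" for i in range(cfg.n_mrna)]
    mirnas = [f"mir-{i:03d}" for i in range(cfg.n_mirna)]
    meth_genes = genes + [f"G{i:04d}" for i in range(cfg.n_mrna, cfg.n_meth)]

    u = rng.normal(0.0, 1.0, size=n)  # latent risk factor
    # mRNA: baseline N(6,1) noise per entry, + effect*u on signal genes
    mrna = 6.0 + rng.normal(0.0, 1.0, size=(cfg.n_mrna, n))
    signal_idx = np.arange(cfg.n_signal_genes)
    mrna[signal_idx] += cfg.effect_size * u[None, :]

    # miRNA: paired miRNAs anti-correlated with their signal gene's centered value
    mirna = 4.0 + rng.normal(0.0, 1.0, size=(cfg.n_mirna, n))
    centered = mrna[signal_idx] - mrna[signal_idx].mean(axis=1, keepdims=True)
    mirna[signal_idx] = 4.0 + (-0.8 * centered + rng.normal(0.0, 0.6, size=(cfg.n_signal_genes, n)))

    # methylation: inverse-logit coupling for signal genes, Beta(2,2) otherwise
    meth = rng.beta(2.0, 2.0, size=(cfg.n_meth, n))
    meth[signal_idx] = special.expit(
        -0.5 * centered + rng.normal(0.0, 0.5, size=(cfg.n_signal_genes, n))
    )

    eta = cfg.effect_size * u
    censor_max = cfg.censor_max
    if censor_max is None:
        censor_max = solve_censor_max(cfg.baseline_rate, cfg.effect_size, cfg.target_censoring)
    rate = cfg.baseline_rate * np.exp(eta)
    T = rng.exponential(1.0 / rate)
    C = rng.uniform(0.0, censor_max, size=n)
    y = np.minimum(T, C)
    delta = (T <= C).astype(int)
    y = np.maximum(y, 1e-9)  # times strictly positive

    mats = [
        OmicsMatrix("mrna", genes, samples, mrna),
        OmicsMatrix("mirna", mirnas, samples, mirna),
        OmicsMatrix("methylation", meth_genes, samples, meth),
    ]
    if cfg.missing_rate > 0:
        mats = [
            inject_missing(m, cfg.missing_rate, int(cfg.seed) + 31 + i)
            for i, m in enumerate(mats)
        ]
    surv = SurvivalTable(samples, y, delta)
    graph = _pathway_cliques(genes, cfg.n_pathways)
    truth = SynthTruth(
        signal_mrna=[genes[i] for i in signal_idx],
        signal_mirna=[mirnas[i] for i in signal_idx],
        signal_meth=[meth_genes[i] for i in signal_idx],
        effect_size=cfg.effect_size,
        latent=u,
        eta=eta,
        censor_max=float(censor_max),
        censoring_fraction=float(1 - delta.mean()),
    )
    return mats, surv, graph, truth


def inject_missing(matrix: OmicsMatrix, rate: float, seed: int) -> OmicsMatrix:
    """Set each entry missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = matrix.copy()
    if rate == 0:
        return out
    mask = np.random.default_rng(seed).random(out.values.shape) < rate
    out.values[mask] = np.nan
    return out
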