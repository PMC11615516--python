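"""End-to-end orchestration: preprocess, fuse, encode, score, evaluate, select.

All fitted components (feature standardization, the contrastive encoder, the
Cox elastic net and its penalty-weight selection) see training samples only;
the held-out 20% is scored with frozen parameters. 5-fold cross-validation
repeats the same protocol with each fold as the held-out set.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gcsurv.contrastive_gcn import (
    EncoderConfig,
    EncoderParams,
    extract_embedding,
    train_encoder,
    Embedding,
)
from gcsurv.feature_select import (
    FeatureSets,
    ImportanceConfig,
    ImportanceModel,
    combine_sets,
    differential_expression,
    feature_report,
    fit_importance,
    modality_breakdown,
    select_de,
    select_top_k,
)
from gcsurv.fusion_augment import AugmentConfig, FusionBundle, Standardizer, stitch
from gcsurv.omics_io import OmicsMatrix, SurvivalTable, align_cohort
from gcsurv.omics_io import aggregate_methylation, filter_missing, impute_median, log2_transform
from gcsurv.pathway_graph import PathwayGraph, build_feature_adjacency, normalize_adjacency
from gcsurv.survival_risk import (
    EvalReport,
    RiskGroups,
    RiskModel,
    RiskScores,
    evaluate,
    fit_cox_en,
    km_curve,
    predict_risk,
    stratify_median,
)

logger = logging.getLogger(__name__)


@dataclass
class CoxConfig:
    lambda_en: float | None = None  # None => internal CV over a log grid
    alpha_mix: float = 0.5
    cv_folds: int = 5


@dataclass
class SelectConfig:
    top_k: int = 200
    lfc_threshold: float = 1.6
    alpha: float = 0.05
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)


@dataclass
class PipelineConfig:
    """All stage configurations plus the split protocol."""

    augment: AugmentConfig = field(default_factory=AugmentConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    cox: CoxConfig = field(default_factory=CoxConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    train_fraction: float = 0.8
    cv_folds: int = 5
    seed: int = 0
    select_features: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def seeded(self) -> "PipelineConfig":
        """Propagate the master seed into per-stage seeds."""
        return replace(
            self,
            augment=replace(self.augment, seed=self.seed + 1),
            encoder=replace(self.encoder, seed=self.seed + 2),
            select=replace(
                self.select, importance=replace(self.select.importance, seed=self.seed + 3)
            ),
        )


@dataclass
class PipelineResult:
    """Everything a run fits and reports."""

    train_ids: list[str]
    test_ids: list[str]
    scaler: Standardizer
    encoder_params: EncoderParams
    cox_model: RiskModel
    embedding: Embedding
    scores: RiskScores
    groups_all: RiskGroups
    report: EvalReport
    modalities: list[str]
    training_log: list[float]
    feature_sets: FeatureSets | None = None
    importance_model: ImportanceModel | None = None
    de_table: pd.DataFrame | None = None
    feature_table: pd.DataFrame | None = None
    modality_counts: dict | None = None


@dataclass
class CVReport:
    """Per-fold held-out metrics with their mean and standard deviation."""

    fold_c_index: list[float]
    fold_abs_log10_p: list[float]

    @property
    def mean_c_index(self) -> float:
        return float(np.mean(self.fold_c_index))

    @property
    def sd_c_index(self) -> float:
        return float(np.std(self.fold_c_index, ddof=1))

    @property
    def mean_abs_log10_p(self) -> float:
        return float(np.mean(self.fold_abs_log10_p))

    def to_dict(self) -> dict:
        return {
            "fold_c_index": self.fold_c_index,
            "fold_abs_log10_p": self.fold_abs_log10_p,
            "mean_c_index": self.mean_c_index,
            "sd_c_index": self.sd_c_index,
            "mean_abs_log10_p": self.mean_abs_log10_p,
        }


def holdout_split(
    sample_ids: list[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Uniform random split; |train| = round-half-up(fraction * n)."""
    n = len(sample_ids)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("degenerate split: one side would be empty")
    perm = np.random.default_rng(seed).permutation(n)
    train = [sample_ids[i] for i in sorted(perm[:n_train])]
    test = [sample_ids[i] for i in sorted(perm[n_train:])]
    return train, test


def cv_folds(sample_ids: list[str], k: int, seed: int) -> list[list[str]]:
    """k disjoint validation folds whose sizes differ by at most 1."""
    n = len(sample_ids)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    return [
        [sample_ids[i] for i in sorted(chunk)] for chunk in np.array_split(perm, k)
    ]


def preprocess(
    matrices: list[OmicsMatrix],
    cpg_map: dict[str, str] | None = None,
    max_missing: float = 0.2,
) -> list[OmicsMatrix]:
    """Standard preprocessing chain per modality.

    Methylation is collapsed CpG->gene first (when a map is given); then
    features and samples with > max_missing missing values are dropped,
    remaining gaps are median-imputed, and expression modalities are
    log2(x+1)-transformed.
    """
    out = []
    for m in matrices:
        if m.modality == "methylation" and cpg_map is not None:
            m = aggregate_methylation(m, cpg_map)
        if np.isnan(m.values).any():
            m = filter_missing(m, max_missing)
            m = impute_median(m)
        if m.modality in ("mrna", "mirna"):
            m = log2_transform(m)
        out.append(m)
    return out


def _fit_components(
    bundle: FusionBundle,
    graph: PathwayGraph,
    surv: SurvivalTable,
    train_ids: list[str],
    cfg: PipelineConfig,
) -> tuple[Standardizer, EncoderParams, RiskModel, Embedding, list[float]]:
    """Fit scaler, encoder and Cox model on the training columns only."""
    train_bundle = bundle.columns(train_ids)
    scaler = Standardizer().fit(train_bundle.X)
    std_all = FusionBundle(
        scaler.transform(bundle.X), bundle.feature_meta, bundle.sample_ids
    )
    std_train = std_all.columns(train_ids)

    meta = list(zip(bundle.feature_meta["modality"], bundle.feature_meta["gene_symbol"]))
    A = build_feature_adjacency(graph, meta)
    S = normalize_adjacency(A, bundle.fused_feature_ids)

    theta_q, _, log = train_encoder(std_train, S, cfg.encoder, cfg.augment)
    embedding = extract_embedding(theta_q, std_all, S, cfg.encoder)

    train_emb = Embedding(
        embedding.Z[:, [bundle.sample_ids.index(s) for s in train_ids]], train_ids
    )
    cox = fit_cox_en(
        train_emb,
        surv.subset(train_ids),
        lambda_en=cfg.cox.lambda_en,
        alpha_mix=cfg.cox.alpha_mix,
        cv_folds=cfg.cox.cv_folds,
        seed=cfg.seed + 17,
    )
    return scaler, theta_q, cox, embedding, log


def _stratify_or_fallback(scores: RiskScores) -> RiskGroups:
    """Median split; with a constant predictor (fully shrunk model) any split
    is arbitrary, so fall back to a deterministic balanced split and warn."""
    try:
        return stratify_median(scores)
    except ValueError:
        logger.warning(
            "risk scores are constant; stratification is arbitrary "
            "(balanced split by sample order)"
        )
        n = len(scores.sample_ids)
        labels = ["low"] * ((n + 1) // 2) + ["high"] * (n // 2)
        return RiskGroups(list(scores.sample_ids), labels)


def run_pipeline(
    matrices: list[OmicsMatrix],
    survival: SurvivalTable,
    graph: PathwayGraph,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Full run: align, split, fuse, encode, score, stratify, evaluate, select.

    ``matrices`` may hold any nonempty subset of the three modalities
    (single-modality ablation runs are supported).
    """
    cfg = (cfg or PipelineConfig()).seeded()
    t0 = _time.perf_counter()
    matrices, survival = align_cohort(matrices, survival)
    modalities = [m.modality for m in matrices]
    train_ids, test_ids = holdout_split(survival.sample_ids, cfg.train_fraction, cfg.seed)
    bundle = stitch(matrices)
    logger.info(
        "pipeline: %d features x %d samples (%s), %d train / %d test, seed %d",
        bundle.n_features, bundle.n_samples, "+".join(modalities),
        len(train_ids), len(test_ids), cfg.seed,
    )

    scaler, theta_q, cox, embedding, log = _fit_components(
        bundle, graph, survival, train_ids, cfg
    )

    scores = predict_risk(cox, embedding)
    groups_all = _stratify_or_fallback(scores)

    test_idx = [bundle.sample_ids.index(s) for s in test_ids]
    test_scores = RiskScores(test_ids, scores.r[test_idx])
    test_groups = _stratify_or_fallback(test_scores)
    report = evaluate(test_scores, test_groups, survival.subset(test_ids))
    logger.info(
        "pipeline: held-out C-index %.3f, |log10 p| %.2f (%.1fs)",
        report.c_index, report.abs_log10_p, _time.perf_counter() - t0,
    )

    result = PipelineResult(
        train_ids=train_ids,
        test_ids=test_ids,
        scaler=scaler,
        encoder_params=theta_q,
        cox_model=cox,
        embedding=embedding,
        scores=scores,
        groups_all=groups_all,
        report=report,
        modalities=modalities,
        training_log=log,
    )
    if cfg.select_features:
        imp = fit_importance(bundle, groups_all, cfg.select.importance)
        f_xgb = select_top_k(imp, cfg.select.top_k)
        de = differential_expression(bundle, groups_all)
        f_de = select_de(de, cfg.select.lfc_threshold, cfg.select.alpha)
        result.feature_sets = combine_sets(f_de, f_xgb)
        result.importance_model = imp
        result.de_table = de
        result.feature_table = feature_report(bundle, imp, de, result.feature_sets)
        result.modality_counts = modality_breakdown(result.feature_sets, bundle.feature_meta)
    return result


def cv_evaluate(
    matrices: list[OmicsMatrix],
    survival: SurvivalTable,
    graph: PathwayGraph,
    cfg: PipelineConfig | None = None,
) -> CVReport:
    """k-fold cross-validation of held-out C-index and |log10 p|."""
    cfg = (cfg or PipelineConfig()).seeded()
    matrices, survival = align_cohort(matrices, survival)
    bundle = stitch(matrices)
    folds = cv_folds(survival.sample_ids, cfg.cv_folds, cfg.seed)
    cis, alps = [], []
    for fi, fold in enumerate(folds):
        train_ids = [s for s in survival.sample_ids if s not in set(fold)]
        try:
            scaler, theta_q, cox, embedding, _ = _fit_components(
                bundle, graph, survival, train_ids, cfg
            )
            fold_idx = [bundle.sample_ids.index(s) for s in fold]
            fold_scores = RiskScores(fold, embedding.Z[:, fold_idx].T @ cox.beta)
            fold_groups = _stratify_or_fallback(fold_scores)
            rep = evaluate(fold_scores, fold_groups, survival.subset(fold))
        except ValueError as err:
            logger.warning("cv_evaluate: fold %d invalid (%s); excluded", fi, err)
            continue
        cis.append(rep.c_index)
        alps.append(rep.abs_log10_p)
    if not cis:
        raise RuntimeError("every cross-validation fold was invalid")
    return CVReport(cis, alps)


def write_artifacts(result: PipelineResult, surv: SurvivalTable, outdir: str) -> None:
    """Write the standard artifact set: risks, groups, report, features, KM tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": result.scores.sample_ids,
            "risk": result.scores.r,
            "group": result.groups_all.label,
        }
    ).to_csv(out / "risk_scores.tsv", sep="\t", index=False)
    (out / "eval_report.json").write_text(json.dumps(result.report.to_dict(), indent=2))
    surv_aligned = surv.subset(result.scores.sample_ids)
    for which in ("high", "low"):
        mask = result.groups_all.mask(which)
        ids = [s for s, m in zip(result.scores.sample_ids, mask) if m]
        km_curve(surv_aligned.subset(ids)).to_csv(
            out / f"km_{which}.tsv", sep="\t", index=False
        )
    if result.feature_table is not None:
        result.feature_table.to_csv(out / "feature_report.tsv", sep="\t", index=False)
        (out / "modality_counts.json").write_text(
            json.dumps(result.modality_counts, indent=2)
        )
    meta = {
        "modalities": result.modalities,
        "n_train": len(result.train_ids),
        "n_test": len(result.test_ids),
        "lambda_en": result.cox_model.lambda_en,
        "alpha_mix": result.cox_model.alpha_mix,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
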