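"""Informative-feature selection from predicted risk groups.

Two routes identify candidate biomarkers among the fused multimodal features:
(1) a gradient-boosted tree classifier trained to predict the high/low risk
label, ranked by total-gain importance with the top k = 200 retained (F_XGB);
(2) a differential test between risk groups (Welch's t on log2-scale values
with Benjamini-Hochberg correction), thresholded at |log2 fold change| > 1.6
and adjusted p < 0.05 (F_DE). Their union is the set of global informative
molecules (IFMs) and their intersection the key informative molecules
(key-IFMs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from xgboost import XGBClassifier

from gcsurv.fusion_augment import FusionBundle
from gcsurv.survival_risk import RiskGroups

logger = logging.getLogger(__name__)


@dataclass
class ImportanceConfig:
    """Boosted-tree settings; tree depth is selected from depth_grid by
    internal stratified 3-fold accuracy."""

    n_trees: int = 200
    learning_rate: float = 0.1
    subsample: float = 0.8
    depth_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    cv_folds: int = 3
    seed: int = 0


@dataclass
class ImportanceModel:
    """Per-feature total-gain importances from the fitted classifier."""

    feature_ids: list[str]
    importance: np.ndarray
    best_depth: int
    config: ImportanceConfig

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if np.any(self.importance < 0):
            raise ValueError("importances must be nonnegative")
        if len(self.feature_ids) != self.importance.shape[0]:
            raise ValueError("one importance per feature required")


@dataclass
class FeatureSets:
    """F_DE, F_XGB and their union (IFM) / intersection (key-IFM)."""

    f_de: set[str]
    f_xgb: set[str]
    ifm: set[str] = field(init=False)
    key_ifm: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.f_de = set(self.f_de)
        self.f_xgb = set(self.f_xgb)
        self.ifm = self.f_de | self.f_xgb
        self.key_ifm = self.f_de & self.f_xgb


def _labels_vector(bundle: FusionBundle, groups: RiskGroups) -> np.ndarray:
    if groups.sample_ids != bundle.sample_ids:
        pos = {s: i for i, s in enumerate(groups.sample_ids)}
        idx = [pos[s] for s in bundle.sample_ids]
        labels = [groups.label[i] for i in idx]
    else:
        labels = groups.label
    return np.array([1 if lab == "high" else 0 for lab in labels])


def fit_importance(
    bundle: FusionBundle,
    groups: RiskGroups,
    cfg: ImportanceConfig | None = None,
) -> ImportanceModel:
    """Train the boosted-tree risk-label classifier and return importances.

    The tree depth is chosen from cfg.depth_grid by stratified k-fold
    accuracy; the final model is refitted on all samples at the best depth.
    Importance is total gain; features never split on score exactly 0.
    """
    cfg = cfg or ImportanceConfig()
    y = _labels_vector(bundle, groups)
    if len(np.unique(y)) < 2:
        raise ValueError("both risk classes must be present to fit importances")
    X = bundle.X.T  # samples x features
    m = X.shape[1]

    def make_clf(depth: int) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=cfg.n_trees,
            max_depth=depth,
            learning_rate=cfg.learning_rate,
            subsample=cfg.subsample,
            random_state=cfg.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            importance_type="total_gain",
        )

    best_depth, best_acc = cfg.depth_grid[0], -1.0
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    for depth in cfg.depth_grid:
        accs = []
        for tr, te in splits:
            clf = make_clf(depth)
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_depth = acc, depth

    clf = make_clf(best_depth)
    clf.fit(X, y)
    booster = clf.get_booster()
    gain = booster.get_score(importance_type="total_gain")
    imp = np.zeros(m)
    for name, val in gain.items():
        imp[int(name[1:])] = val  # feature names are f0..f{m-1}
    return ImportanceModel(bundle.fused_feature_ids, imp, best_depth, cfg)


def select_top_k(model: ImportanceModel, k: int = 200) -> list[str]:
    """The min(k, m) features with highest importance; ties break toward the
    lower feature index (stable)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    m = len(model.feature_ids)
    order = np.lexsort((np.arange(m), -model.importance))
    return [model.feature_ids[i] for i in order[: min(k, m)]]


def differential_expression(bundle: FusionBundle, groups: RiskGroups) -> pd.DataFrame:
    """Welch's t-test per fused feature between risk groups, BH-corrected.

    log2_fc is mean(high) - mean(low) on the stored (log2-scale) values.
    Features with zero variance in both groups get p = 1 by convention.
    """
    y = _labels_vector(bundle, groups)
    hi, lo = bundle.X[:, y == 1], bundle.X[:, y == 0]
    if hi.shape[1] < 2 or lo.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    lfc = hi.mean(axis=1) - lo.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("differential_expression: %d zero-variance features set p=1", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature_id": bundle.fused_feature_ids,
            "log2_fc": lfc,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )


def select_de(
    de: pd.DataFrame, lfc_threshold: float = 1.6, alpha: float = 0.05
) -> list[str]:
    """Features with |log2_fc| strictly above the threshold AND adjusted p
    strictly below alpha."""
    keep = (de["log2_fc"].abs() > lfc_threshold) & (de["p_adjusted"] < alpha)
    return de.loc[keep, "feature_id"].tolist()


def combine_sets(f_de, f_xgb) -> FeatureSets:
    """Union (IFM) and intersection (key-IFM) of the two selection routes."""
    sets = FeatureSets(set(f_de), set(f_xgb))
    if not sets.key_ifm:
        logger.warning("combine_sets: DE and boosted-tree selections are disjoint")
    return sets


def modality_breakdown(sets: FeatureSets, feature_meta: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Counts of selected features per modality for each feature set.

    ``feature_meta`` must carry fused feature ids as "<modality>:<source_id>"
    rows (as produced by FusionBundle) or a modality column indexed likewise.
    """
    modality_of = {
        f"{m}:{f}": m
        for m, f in zip(feature_meta["modality"], feature_meta["source_feature_id"])
    }
    out: dict[str, dict[str, int]] = {}
    for name in ("f_de", "f_xgb", "ifm", "key_ifm"):
        counts = {"mrna": 0, "mirna": 0, "methylation": 0}
        for fid in getattr(sets, name):
            counts[modality_of[fid]] += 1
        out[name] = counts
    return out


def feature_report(
    bundle: FusionBundle,
    model: ImportanceModel,
    de: pd.DataFrame,
    sets: FeatureSets,
) -> pd.DataFrame:
    """Full per-feature report joining importances, DE statistics and set flags."""
    df = de.copy()
    df.insert(1, "modality", list(bundle.feature_meta["modality"]))
    df.insert(2, "gene_symbol", list(bundle.feature_meta["gene_symbol"]))
    df["importance"] = model.importance
    for name in ("f_xgb", "f_de", "ifm", "key_ifm"):
        df[f"in_{name}"] = df["feature_id"].isin(getattr(sets, name))
    return df
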