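"""Early fusion (row stitching) of modality matrices and stochastic augmentation.

The fused matrix X row-binds the modality matrices over a shared, ordered
sample set. Contrastive training consumes pairs of independently corrupted
views of each sample; four corruption operators are provided (Gaussian noise,
entrywise dropout, within-column value swaps, whole-feature masking), each
deterministic given its seed and applied in a fixed composition order with
independent substreams so that toggling one operator does not shift another's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gcsurv.omics_io import OmicsMatrix


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic substream derived from a master seed and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class AugmentConfig:
    """Corruption strengths for view generation.

    All strengths are mild by default (standardized-feature scale); set a
    strength to 0 to disable that operator.
    """

    gaussian_sd: float = 0.1
    dropout_rate: float = 0.1
    swap_frac: float = 0.05
    mask_rate: float = 0.05
    views_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        for name in ("dropout_rate", "swap_frac", "mask_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.views_per_sample < 2:
            raise ValueError("views_per_sample must be >= 2")


@dataclass
class FusionBundle:
    """Row-stitched multimodal matrix with per-row metadata.

    ``feature_meta`` is a DataFrame aligned with the rows of ``X`` carrying
    columns ``modality``, ``gene_symbol`` and ``source_feature_id``; fused row
    ids are "<modality>:<feature_id>". ``provenance`` maps every column to the
    original sample it derives from (identity for unaugmented bundles).
    """

    X: np.ndarray
    feature_meta: pd.DataFrame
    sample_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not self.provenance:
            self.provenance = list(self.sample_ids)
        if self.X.shape != (len(self.feature_meta), len(self.sample_ids)):
            raise ValueError("X shape must match feature_meta rows x sample_ids")
        if len(self.provenance) != len(self.sample_ids):
            raise ValueError("provenance must cover every column")
        originals = set(s for s, p in zip(self.sample_ids, self.provenance) if s == p)
        for p in self.provenance:
            if p not in originals:
                raise ValueError(f"provenance {p!r} does not resolve to an original sample")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def fused_feature_ids(self) -> list[str]:
        return [
            f"{m}:{f}"
            for m, f in zip(self.feature_meta["modality"], self.feature_meta["source_feature_id"])
        ]

    def columns(self, sample_ids: list[str]) -> "FusionBundle":
        """Restrict to the given columns (by sample id)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return FusionBundle(
            self.X[:, idx],
            self.feature_meta,
            list(sample_ids),
            [self.provenance[i] for i in idx],
        )


@dataclass
class PairedViews:
    """Two augmented views per sample: 2N columns with an involutive pairing."""

    view_matrix: np.ndarray
    pair_index: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        p = np.asarray(self.pair_index, dtype=int)
        if np.any(p[p] != np.arange(len(p))) or np.any(p == np.arange(len(p))):
            raise ValueError("pair_index must be an involution without fixed points")
        for i, j in enumerate(p):
            if self.provenance[i] != self.provenance[j]:
                raise ValueError("paired views must share provenance")
        self.pair_index = p


def stitch(matrices: list[OmicsMatrix]) -> FusionBundle:
    """Row-bind modality matrices sharing an identical ordered sample set."""
    if not matrices:
        raise ValueError("need at least one matrix to stitch")
    ref = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ref:
            raise ValueError("sample ids (and order) must be identical across modalities")
    X = np.vstack([m.values for m in matrices])
    meta = pd.DataFrame(
        {
            "modality": sum(([m.modality] * m.n_features for m in matrices), []),
            "gene_symbol": sum((list(m.feature_ids) for m in matrices), []),
            "source_feature_id": sum((list(m.feature_ids) for m in matrices), []),
        }
    )
    return FusionBundle(X, meta, list(ref))


class Standardizer:
    """Per-feature z-scoring with parameters learned on the training split."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean_ = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # constant features pass through centered
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fitted first")
        return (X - self.mean_) / self.scale_


def augment_gaussian(X: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add iid zero-mean Gaussian noise with standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return X.copy()
    return X + _rng(seed, 1).normal(0.0, sd, size=X.shape)


def augment_dropout(X: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Zero each entry independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return X.copy()
    mask = _rng(seed, 2).random(X.shape) < rate
    out = X.copy()
    out[mask] = 0.0
    return out


def augment_swap(X: np.ndarray, frac: float, seed: int) -> np.ndarray:
    """Exchange floor(frac*m/2) disjoint feature pairs within each column.

    The multiset of values in every column is preserved.
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must lie in [0, 1)")
    m, n = X.shape
    k = int(frac * m / 2)
    if k == 0:
        return X.copy()
    rng = _rng(seed, 3)
    out = X.copy()
    for j in range(n):
        perm = rng.permutation(m)
        a, b = perm[:k], perm[k : 2 * k]
        out[a, j], out[b, j] = out[b, j].copy(), out[a, j].copy()
    return out


def augment_mask(X: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Zero floor(rate*m) whole feature rows across all columns of the view."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    m = X.shape[0]
    k = int(rate * m)
    if k == 0:
        return X.copy()
    rows = _rng(seed, 4).choice(m, size=k, replace=False)
    out = X.copy()
    out[rows, :] = 0.0
    return out


def augment_view(X: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Apply the full corruption chain: gaussian -> dropout -> swap -> mask."""
    out = augment_gaussian(X, cfg.gaussian_sd, seed)
    out = augment_dropout(out, cfg.dropout_rate, seed)
    out = augment_swap(out, cfg.swap_frac, seed)
    return augment_mask(out, cfg.mask_rate, seed)


def make_paired_views(
    bundle: FusionBundle, cfg: AugmentConfig, batch_sample_ids: list[str]
) -> PairedViews:
    """Build two independently corrupted views of each batch sample.

    Columns 0..N-1 are view 1, N..2N-1 are view 2; column i pairs with i+N.
    All non-partner columns act as negatives in the contrastive loss.
    """
    if len(batch_sample_ids) < 2:
        raise ValueError("contrastive batches need at least 2 samples")
    sub = bundle.columns(batch_sample_ids)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2)
    v1 = augment_view(sub.X, cfg, int(seeds[0]) % (2**31))
    v2 = augment_view(sub.X, cfg, int(seeds[1]) % (2**31))
    n = sub.n_samples
    pair = np.concatenate([np.arange(n) + n, np.arange(n)])
    return PairedViews(
        np.hstack([v1, v2]), pair, [sub.provenance[i % n] for i in range(2 * n)]
    )


def expand_dataset(bundle: FusionBundle, cfg: AugmentConfig, copies: int) -> FusionBundle:
    """Append ``copies`` augmented columns per original sample, with provenance."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies == 0:
        return FusionBundle(
            bundle.X.copy(), bundle.feature_meta, list(bundle.sample_ids), list(bundle.provenance)
        )
    blocks = [bundle.X]
    ids = list(bundle.sample_ids)
    prov = list(bundle.provenance)
    for c in range(copies):
        blocks.append(augment_view(bundle.X, cfg, int(cfg.seed) + 1000 + c))
        ids.extend(f"{s}#aug{c + 1}" for s in bundle.sample_ids)
        prov.extend(bundle.provenance)
    return FusionBundle(np.hstack(blocks), bundle.feature_meta, ids, prov)
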