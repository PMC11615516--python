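"""Reading, validation and preprocessing of per-modality omics matrices.

Each modality is a feature-by-sample numeric matrix. Preprocessing follows the
standard multi-omics recipe: CpG-to-gene averaging for methylation, removal of
features then samples with more than 20% missing values, per-feature median
imputation, and log2(x+1) transform for the expression modalities.
Missing entries are represented as NaN throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("mrna", "mirna", "methylation")


@dataclass
class OmicsMatrix:
    """One modality's feature-by-sample matrix.

    ``values`` has shape ``(len(feature_ids), len(sample_ids))``; missing
    entries are NaN. Expression modalities hold log2-scale values after
    :func:`log2_transform`; methylation holds beta values in [0, 1].
    """

    modality: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.modality,
            list(self.feature_ids),
            list(self.sample_ids),
            self.values.copy(),
        )


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: one record per sample.

    ``time`` is the observed follow-up time (event or censoring time, > 0);
    ``event`` is 1 if the outcome was observed and 0 if censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time and event must be one value per sample")
        _check_unique(self.sample_ids, "sample id")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        """Restrict (and reorder) to the given sample ids."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in survival table: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_matrix(path: str, modality: str) -> OmicsMatrix:
    """Read a delimited feature-by-sample matrix (TSV or CSV).

    First column: feature ids; header row: sample ids. Empty cells become
    missing (NaN); non-numeric cells are a hard error with their location.
    """
    sep = _detect_sep(str(path))
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.full(raw.shape, np.nan)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    return OmicsMatrix(modality, feature_ids, sample_ids, values)


def write_matrix(matrix: OmicsMatrix, path: str) -> None:
    """Write a matrix as TSV; round-trips bit-identically through read_matrix."""
    matrix.to_frame().to_csv(path, sep="\t", na_rep="", float_format=None)


def read_survival(path: str) -> SurvivalTable:
    """Read a survival table with columns sample_id, time, event."""
    sep = _detect_sep(str(path))
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return SurvivalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(float),
        df["event"].to_numpy(int),
    )


def write_survival(surv: SurvivalTable, path: str) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False)


def read_cpg_map(path: str) -> dict[str, str]:
    """Read a CpG-to-gene map (two-column TSV/CSV: cpg_id, gene_symbol).

    Many CpGs map to one gene; a CpG mapping to two different genes is an error.
    """
    sep = _detect_sep(str(path))
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("CpG map needs two columns: cpg_id, gene_symbol")
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in ("cpg_id", "cpg"):
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for cpg, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cpg, gene = str(cpg), str(gene)
        if cpg in mapping and mapping[cpg] != gene:
            raise ValueError(f"CpG {cpg!r} maps to both {mapping[cpg]!r} and {gene!r}")
        mapping[cpg] = gene
    return mapping


def aggregate_methylation(cpg_values: OmicsMatrix, cpg_map: dict[str, str]) -> OmicsMatrix:
    """Collapse CpG-level methylation to gene level by per-gene averaging.

    Each gene's value is the arithmetic mean of its mapped CpG rows, computed
    per sample over observed (non-missing) entries; a (gene, sample) cell with
    no observed CpG stays missing. CpGs absent from the map are dropped.
    """
    mapped = [f for f in cpg_values.feature_ids if f in cpg_map]
    n_dropped = cpg_values.n_features - len(mapped)
    if n_dropped:
        logger.info("aggregate_methylation: dropped %d unmapped CpGs", n_dropped)
    if not mapped:
        raise ValueError("no CpGs map to any gene")
    df = cpg_values.to_frame().loc[mapped]
    genes = pd.Series([cpg_map[f] for f in mapped], index=df.index)
    agg = df.groupby(genes, sort=True).mean()  # skips NaN per cell
    return OmicsMatrix(
        cpg_values.modality,
        [str(g) for g in agg.index],
        list(cpg_values.sample_ids),
        agg.to_numpy(),
    )


def filter_missing(matrix: OmicsMatrix, max_frac: float = 0.2) -> OmicsMatrix:
    """Drop features, then samples, whose missing fraction strictly exceeds max_frac.

    Features are filtered first (retaining more patients), then samples are
    re-assessed over the remaining features. Comparisons are strict (> 20%
    removed, exactly 20% kept).
    """
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must lie in [0, 1]")
    miss = np.isnan(matrix.values)
    keep_f = miss.mean(axis=1) <= max_frac
    miss_f = miss[keep_f]
    keep_s = (
        miss_f.mean(axis=0) <= max_frac
        if keep_f.any()
        else np.zeros(matrix.n_samples, dtype=bool)
    )
    if not keep_f.any() or not keep_s.any():
        raise ValueError("filter_missing removed every feature or sample")
    return OmicsMatrix(
        matrix.modality,
        [f for f, k in zip(matrix.feature_ids, keep_f) if k],
        [s for s, k in zip(matrix.sample_ids, keep_s) if k],
        matrix.values[np.ix_(keep_f, keep_s)],
    )


def impute_median(matrix: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing entry by the median of its feature's observed values."""
    values = matrix.values.copy()
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = matrix.feature_ids[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(
            f"feature {bad!r} has no observed values; apply filter_missing first"
        )
    med = np.nanmedian(values, axis=1)
    rows, cols = np.nonzero(np.isnan(values))
    values[rows, cols] = med[rows]
    return OmicsMatrix(matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), values)


def log2_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Apply x -> log2(x + 1) to an expression matrix (mrna or mirna only)."""
    if matrix.modality == "methylation":
        raise ValueError("log2_transform is not applicable to methylation beta values")
    vals = matrix.values
    if np.nanmin(vals) < 0:
        raise ValueError("log2_transform requires nonnegative values")
    return OmicsMatrix(
        matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), np.log2(vals + 1.0)
    )


def align_cohort(
    matrices: list[OmicsMatrix], survival: SurvivalTable
) -> tuple[list[OmicsMatrix], SurvivalTable]:
    """Restrict all inputs to the shared samples, in lexicographic order."""
    if not matrices:
        raise ValueError("need at least one omics matrix")
    common = set(survival.sample_ids)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared across all matrices and the survival table")
    order = sorted(common)
    out = []
    for m in matrices:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        idx = np.array([pos[s] for s in order], dtype=int)
        out.append(OmicsMatrix(m.modality, list(m.feature_ids), order, m.values[:, idx]))
    return out, survival.subset(order)
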