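"""Layer-aware two-group differential comparison across omics matrices.

Each assay layer (bulk RNA TPM, Olink NPX proteomics, CyTOF and high-
parameter flow percent-of-parent, mIF percent-of-parent) is compared
between two clinical groups with a Student t-test plus a layer-specific
effect-size gate:

    layer   p threshold   effect metric   effect threshold
    RNA     0.05          log2 fold change     1
    NPX     0.05          log2 fold change     0.75
    CYTOF   0.01          mean difference      0 (no gate)
    X50     0.05          mean difference      20 (pp)
    MIF     0.05          mean difference      5 (pp)

Also: quantile normalization, baseline subtraction for longitudinal
layers, mean-of-z signature scoring, and hypergeometric gene-set
over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class Layer(str, Enum):
    RNA_TPM = "RNA_TPM"
    NPX = "NPX"
    PCT_PARENT_CYTOF = "PCT_PARENT_CYTOF"
    PCT_PARENT_X50 = "PCT_PARENT_X50"
    PCT_MIF = "PCT_MIF"


class Scale(str, Enum):
    LINEAR = "LINEAR"
    LOG2 = "LOG2"


class EffectMetric(str, Enum):
    LOG2FC = "LOG2FC"
    MEAN_DIFF = "MEAN_DIFF"


@dataclass
class ComparisonRule:
    p_threshold: float
    effect_metric: EffectMetric
    effect_threshold: float

    def __post_init__(self) -> None:
        self.effect_metric = EffectMetric(self.effect_metric)
        if self.p_threshold <= 0 or self.effect_threshold < 0:
            raise ValueError("thresholds must be positive / nonnegative")


#: Per-layer significance rules (p gate + effect gate).
LAYER_RULES: dict[Layer, ComparisonRule] = {
    Layer.RNA_TPM: ComparisonRule(0.05, EffectMetric.LOG2FC, 1.0),
    Layer.NPX: ComparisonRule(0.05, EffectMetric.LOG2FC, 0.75),
    Layer.PCT_PARENT_CYTOF: ComparisonRule(0.01, EffectMetric.MEAN_DIFF, 0.0),
    Layer.PCT_PARENT_X50: ComparisonRule(0.05, EffectMetric.MEAN_DIFF, 20.0),
    Layer.PCT_MIF: ComparisonRule(0.05, EffectMetric.MEAN_DIFF, 5.0),
}


@dataclass
class FeatureMatrix:
    """Features x samples continuous matrix with layer/scale annotation."""

    values: pd.DataFrame  # index = features, columns = samples
    layer: Layer
    scale: Scale

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.scale = Scale(self.scale)
        if self.values.index.duplicated().any():
            raise ValueError("duplicated feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        v = self.values.to_numpy(dtype=float)
        if self.layer in (Layer.PCT_PARENT_CYTOF, Layer.PCT_PARENT_X50, Layer.PCT_MIF):
            if self.scale is Scale.LINEAR and (np.nanmin(v) < 0 or np.nanmax(v) > 100):
                raise ValueError("percent-of-parent values must lie in [0, 100]")
        if self.layer is Layer.RNA_TPM and self.scale is Scale.LINEAR and np.nanmin(v) < 0:
            raise ValueError("linear TPM values must be nonnegative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSet:
    set_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


def student_t_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Equal-variance two-sided Student t with df = |a| + |b| - 2.

    When the pooled variance is zero the statistic is undefined; the
    feature is not testable (nan, nan) — except in the fully degenerate
    case of two identical constant groups, where t = 0, p = 1 by the
    no-evidence-of-difference convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def log2_transform(matrix: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """log2(value + pseudocount); marks the matrix as LOG2 scale."""
    if matrix.scale is Scale.LOG2:
        raise ValueError("matrix is already on log2 scale")
    vals = np.log2(matrix.values + pseudocount)
    return FeatureMatrix(values=vals, layer=matrix.layer, scale=Scale.LOG2)


def quantile_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Force every sample (column) onto the mean distribution of order
    statistics; ties within a column receive the mean of the reference
    values their ranks span."""
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = df.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)  # mean order statistics
    ranks = df.rank(method="average").to_numpy()  # 1-based, .5 on ties
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    out = (ref[lo] + ref[hi]) / 2.0
    return FeatureMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        layer=matrix.layer,
        scale=matrix.scale,
    )


def baseline_normalize(matrix: FeatureMatrix, meta: pd.DataFrame) -> FeatureMatrix:
    """Subtract each subject's baseline (BL) sample from its later samples.

    BL columns are dropped from the output; subjects lacking a BL sample
    are dropped with a warning. `meta` must have sample_id, subject_id and
    timepoint columns, one BL row per subject.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    bl = meta[meta["timepoint"] == "BL"]
    dup = bl["subject_id"].duplicated()
    if dup.any():
        raise ValueError("more than one baseline sample for a subject")
    bl_by_subject = {row["subject_id"]: sid for sid, row in bl.iterrows()}
    cols, out = [], []
    for sid in matrix.sample_ids:
        if meta.loc[sid, "timepoint"] == "BL":
            continue
        subj = meta.loc[sid, "subject_id"]
        if subj not in bl_by_subject:
            warnings.warn(f"subject {subj} lacks a baseline sample; dropped", stacklevel=2)
            continue
        cols.append(sid)
        out.append(matrix.values[sid] - matrix.values[bl_by_subject[subj]])
    vals = pd.concat(out, axis=1) if out else pd.DataFrame(index=matrix.values.index)
    vals.columns = cols
    # differences are no longer bounded percentages; keep layer, relax via LOG2-safe path
    fm = FeatureMatrix.__new__(FeatureMatrix)
    fm.values = vals
    fm.layer = matrix.layer
    fm.scale = matrix.scale
    return fm


def differential_features(
    matrix: FeatureMatrix,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    rule: ComparisonRule,
    group_col: str = "group_label",
) -> pd.DataFrame:
    """Per-feature two-group comparison under a layer rule.

    contrast = (group_a, group_b); effect = mean(a) - mean(b), which on a
    log2-scale matrix is the log2 fold change. Output is sorted by p and
    carries a `significant` flag (p < p_threshold AND |effect| >
    effect_threshold) plus a `testable` flag for zero-variance features.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    ga, gb = contrast
    a_ids = [s for s in matrix.sample_ids if meta.loc[s, group_col] == ga]
    b_ids = [s for s in matrix.sample_ids if meta.loc[s, group_col] == gb]
    for name, ids in ((ga, a_ids), (gb, b_ids)):
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    if rule.effect_metric is EffectMetric.LOG2FC and matrix.scale is not Scale.LOG2:
        raise ValueError("LOG2FC effect requires a log2-scale matrix")
    A = matrix.values[a_ids].to_numpy(dtype=float)
    B = matrix.values[b_ids].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    effect = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    identical = degenerate & (mean_a == mean_b)
    testable = ~degenerate | identical
    t = np.where(identical, 0.0, np.where(testable, t, np.nan))
    p = np.where(identical, 1.0, np.where(testable, p, np.nan))
    sig = testable & (p < rule.p_threshold) & (np.abs(effect) > rule.effect_threshold)
    out = pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "effect": effect,
            "t": t,
            "p": p,
            "testable": testable,
            "significant": sig,
        }
    ).sort_values("p", kind="mergesort", na_position="last")
    return out.reset_index(drop=True)


def signature_score(matrix: FeatureMatrix, gene_set: GeneSet) -> pd.Series:
    """Mean-of-z signature: z-score each member gene across samples, then
    average member z-scores within each sample."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    present = [g for g in gene_set.members if g in matrix.values.index]
    dropped = gene_set.members - set(present)
    if dropped:
        warnings.warn(
            f"gene set {gene_set.set_id}: {len(dropped)} members absent from matrix",
            stacklevel=2,
        )
    sub = matrix.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sub[sd > 0]
    if usable.empty:
        raise ValueError(f"gene set {gene_set.set_id}: no usable members")
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    score = z.mean(axis=0)
    score.name = gene_set.set_id
    return score


def overrepresentation_test(
    significant: GeneSet, pathway: GeneSet, universe: GeneSet, p_cutoff: float = 0.01
) -> dict:
    """One-sided hypergeometric upper-tail test for pathway enrichment
    among significant features, within the given universe."""
    uni = universe.members
    if not significant.members <= uni:
        raise ValueError("significant set must be a subset of the universe")
    path_in_uni = pathway.members & uni
    if not path_in_uni:
        return {
            "set_id": pathway.set_id,
            "overlap": 0,
            "expected": 0.0,
            "p": np.nan,
            "testable": False,
            "significant": False,
        }
    M, K, N = len(uni), len(path_in_uni), len(significant.members)
    k = len(significant.members & path_in_uni)
    p = float(stats.hypergeom.sf(k - 1, M, K, N))
    return {
        "set_id": pathway.set_id,
        "overlap": k,
        "expected": K * N / M,
        "p": p,
        "testable": True,
        "significant": bool(p < p_cutoff),
    }


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (set id, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets.append(GeneSet(set_id=parts[0], members=frozenset(parts[2:])))
    return sets


def read_matrix(path: str | Path, layer: Layer | str, scale: Scale | str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(values=df, layer=Layer(layer), scale=Scale(scale))
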