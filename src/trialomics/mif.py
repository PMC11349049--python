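"""Multiplex-immunofluorescence cell phenotyping.

Implements the image-analysis scheme used on segmented mIF ROIs:

1. Per image and marker, pool the pixel intensities of all segmented
   cells and split them into three clusters by 1-D k-means; the
   background threshold is the mean of the two largest cluster centers.
2. A cell is positive for a marker when strictly more than half of its
   pixels strictly exceed that threshold.
3. Cells are assigned to hierarchical phenotypes (required-positive and
   required-negative markers under a parent population).
4. Percent-of-parent is computed per ROI and averaged, unweighted,
   across the ROIs of an image.
5. Image-level population percentages are compared between clinical
   groups with a Student t-test and the (p < 0.05, |mean difference| >
   5 percentage points) significance rule.

The 3-means problem is solved exactly (minimum within-cluster sum of
squares) by dynamic programming over the sorted intensities, so the
threshold is deterministic — no Lloyd initialization or seed involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compare import LAYER_RULES, ComparisonRule, EffectMetric, Layer, student_t_two_sample


class DegenerateChannelError(ValueError):
    """Raised when a channel has too few distinct intensities to threshold."""


@dataclass
class MarkerThreshold:
    image_id: str
    marker: str
    centers: tuple[float, float, float]  # ascending
    threshold: float
    separation_ok: bool = True  # QC: top two centers well apart vs within-cluster spread


@dataclass
class PhenotypeDefinition:
    """One node of the gating hierarchy.

    parent == "ROOT" means the population is gated on all cells.
    """

    name: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()
    parent: str = "ROOT"


def _seg_cost(i: int, j: int, csum: np.ndarray, csq: np.ndarray) -> float:
    """Within-segment sum of squared deviations for sorted x[i..j] inclusive."""
    n = j - i + 1
    s = csum[j + 1] - csum[i]
    return (csq[j + 1] - csq[i]) - s * s / n


def kmeans_1d_three(x: Sequence[float]) -> tuple[np.ndarray, float]:
    """Exact 1-D 3-means: returns (ascending centers, total within-SSE).

    Dynamic programming over the sorted values; the optimal clusters are
    contiguous segments of the sorted order, so it suffices to search the
    two boundary indices. The middle layer uses divide-and-conquer over
    the (monotone) optimal split positions, giving O(n log n). Ties in
    SSE are broken toward the smallest boundary indices.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if np.unique(xs).size < 3:
        raise DegenerateChannelError("need at least 3 distinct intensity values")
    csum = np.concatenate(([0.0], np.cumsum(xs)))
    csq = np.concatenate(([0.0], np.cumsum(xs * xs)))

    # D1[i]: cost of one cluster covering xs[0..i]
    idx = np.arange(n)
    s = csum[1:]
    D1 = csq[1:] - s * s / (idx + 1)

    # D2[i]: best cost of two clusters covering xs[0..i]; arg2[i] = start of 2nd
    D2 = np.full(n, np.inf)
    arg2 = np.zeros(n, dtype=int)

    def solve(lo: int, hi: int, optlo: int, opthi: int) -> None:
        if lo > hi:
            return
        mid = (lo + hi) // 2
        best, barg = np.inf, optlo
        jmax = min(mid, opthi)
        for j in range(optlo, jmax + 1):
            v = D1[j - 1] + _seg_cost(j, mid, csum, csq)
            if v < best:
                best, barg = v, j
        D2[mid], arg2[mid] = best, barg
        solve(lo, mid - 1, optlo, barg)
        solve(mid + 1, hi, barg, opthi)

    solve(1, n - 1, 1, n - 1)

    # final layer: choose start j of the third cluster (smallest j on ties)
    best, bj = np.inf, 2
    for j in range(2, n):
        v = D2[j - 1] + _seg_cost(j, n - 1, csum, csq)
        if v < best:
            best, bj = v, j
    b2 = bj  # start index of cluster 3
    b1 = arg2[b2 - 1]  # start index of cluster 2
    centers = np.array(
        [
            xs[:b1].mean(),
            xs[b1:b2].mean(),
            xs[b2:].mean(),
        ]
    )
    return centers, float(best)


def kmeans_threshold(
    pixels: Sequence[float], image_id: str = "", marker: str = ""
) -> MarkerThreshold:
    """Background threshold for one image/marker: mean of the two largest
    of the three exact k-means centers of the pooled pixel intensities."""
    px = np.asarray(pixels, dtype=float)
    try:
        centers, sse = kmeans_1d_three(px)
    except DegenerateChannelError as e:
        raise DegenerateChannelError(
            f"image {image_id!r}, marker {marker!r}: {e}"
        ) from None
    thr = float((centers[1] + centers[2]) / 2.0)
    # QC: a usable positive/background split needs the two top centers to
    # sit further apart than the typical within-cluster spread; a single
    # Gaussian mode yields a gap of ~2.8 within-cluster sd, so 3 sd marks
    # genuinely bimodal channels
    within_sd = float(np.sqrt(sse / px.size))
    sep_ok = bool(centers[2] - centers[1] > 3.0 * within_sd)
    if not sep_ok:
        warnings.warn(
            f"image {image_id!r}, marker {marker!r}: poorly separated intensity "
            "modes; positivity calls are near-chance",
            stacklevel=2,
        )
    return MarkerThreshold(
        image_id=image_id, marker=marker, centers=tuple(centers), threshold=thr,
        separation_ok=sep_ok,
    )


def call_positive(pixel_intensities: Sequence[float], threshold: float) -> bool:
    """Positive iff strictly more than half the pixels strictly exceed
    the threshold."""
    px = np.asarray(pixel_intensities, dtype=float)
    if px.size == 0:
        raise ValueError("cell has no pixels in this channel")
    return bool((px > threshold).sum() * 2 > px.size)


def _ordered_definitions(defs: Sequence[PhenotypeDefinition]) -> list[PhenotypeDefinition]:
    """Topological order of the gating hierarchy; rejects cycles/orphans."""
    by_name = {d.name: d for d in defs}
    ordered: list[PhenotypeDefinition] = []
    state: dict[str, int] = {}

    def visit(name: str) -> None:
        if name == "ROOT" or state.get(name) == 2:
            return
        if state.get(name) == 1:
            raise ValueError(f"cycle in phenotype hierarchy at {name!r}")
        if name not in by_name:
            raise ValueError(f"unknown parent population {name!r}")
        state[name] = 1
        visit(by_name[name].parent)
        state[name] = 2
        ordered.append(by_name[name])

    for d in defs:
        visit(d.name)
    return ordered


def phenotype_cells(
    cell_calls: pd.DataFrame, definitions: Sequence[PhenotypeDefinition]
) -> pd.DataFrame:
    """Per-cell population membership from per-cell marker positivity.

    `cell_calls`: one row per cell, boolean column per marker (index =
    cell id). Returns a boolean DataFrame with one column per population.
    A cell belongs to a population iff it meets the marker requirements
    and belongs to the parent population.
    """
    ordered = _ordered_definitions(definitions)
    member = pd.DataFrame(index=cell_calls.index)
    for d in ordered:
        needed = [*d.positive, *d.negative]
        missing = [m for m in needed if m not in cell_calls.columns]
        if missing:
            raise ValueError(f"population {d.name!r}: missing marker calls {missing}")
        ok = pd.Series(True, index=cell_calls.index)
        for m in d.positive:
            ok &= cell_calls[m]
        for m in d.negative:
            ok &= ~cell_calls[m]
        if d.parent != "ROOT":
            ok &= member[d.parent]
        member[d.name] = ok
    return member


def percent_of_parent(
    memberships: Mapping[str, pd.DataFrame],
    definitions: Sequence[PhenotypeDefinition],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-of-parent per ROI, and per image as the unweighted mean
    over evaluable ROIs.

    `memberships` maps roi_id -> per-cell membership frame for one image.
    Returns (roi_table, image_row): roi_table has one row per
    (roi, population) with counts and percents; image_row one row per
    population with the across-ROI mean (NaN when no ROI was evaluable).
    """
    defs = _ordered_definitions(definitions)
    rows = []
    for roi_id, mem in memberships.items():
        n_cells = len(mem)
        for d in defs:
            child = int(mem[d.name].sum())
            parent = n_cells if d.parent == "ROOT" else int(mem[d.parent].sum())
            pct = 100.0 * child / parent if parent > 0 else np.nan
            rows.append(
                {
                    "roi_id": roi_id,
                    "population": d.name,
                    "count": child,
                    "parent_count": parent,
                    "percent_of_parent": pct,
                    "evaluable": parent > 0,
                }
            )
    roi_table = pd.DataFrame(rows)
    img_rows = []
    for d in defs:
        sub = roi_table[(roi_table["population"] == d.name) & roi_table["evaluable"]]
        if sub.empty:
            warnings.warn(
                f"population {d.name!r}: no evaluable ROI in image", stacklevel=2
            )
            img_rows.append({"population": d.name, "percent_of_parent": np.nan, "n_rois": 0})
        else:
            img_rows.append(
                {
                    "population": d.name,
                    "percent_of_parent": float(sub["percent_of_parent"].mean()),
                    "n_rois": len(sub),
                }
            )
    return roi_table, pd.DataFrame(img_rows)


def run_image(
    cells: pd.DataFrame, definitions: Sequence[PhenotypeDefinition]
) -> tuple[list[MarkerThreshold], pd.DataFrame, pd.DataFrame]:
    """Full pipeline for one image given long-form pixel data.

    `cells` columns: image_id, roi_id, cell_id, marker, intensity (one
    row per pixel). Thresholds pool all pixels of all ROIs of the image.
    Returns (thresholds, roi_table, image_table).
    """
    image_id = str(cells["image_id"].iloc[0])
    markers = sorted(cells["marker"].unique())
    thresholds = {
        m: kmeans_threshold(
            cells.loc[cells["marker"] == m, "intensity"].to_numpy(), image_id, m
        )
        for m in markers
    }
    memberships: dict[str, pd.DataFrame] = {}
    for roi_id, roi_df in cells.groupby("roi_id", sort=True):
        grouped = roi_df.groupby(["cell_id", "marker"], sort=True)["intensity"]
        tbl: dict[str, dict[str, bool]] = {}
        for (cell_id, marker), px in grouped:
            tbl.setdefault(cell_id, {})[marker] = call_positive(
                px.to_numpy(), thresholds[marker].threshold
            )
        cell_calls = pd.DataFrame.from_dict(tbl, orient="index").fillna(False)
        memberships[str(roi_id)] = phenotype_cells(cell_calls, definitions)
    roi_table, image_table = percent_of_parent(memberships, definitions)
    roi_table.insert(0, "image_id", image_id)
    image_table.insert(0, "image_id", image_id)
    return list(thresholds.values()), roi_table, image_table


def compare_mif_populations(
    image_table: pd.DataFrame,
    groups: Mapping[str, str],
    rule: ComparisonRule | None = None,
) -> pd.DataFrame:
    """Between-group comparison of image-level population percentages.

    `image_table`: rows (image_id, population, percent_of_parent);
    `groups`: image_id -> group label (exactly two labels). Applies the
    mIF significance rule (p < 0.05 and |mean difference| > 5 pp) unless
    another rule is supplied.
    """
    rule = rule or LAYER_RULES[Layer.PCT_MIF]
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    ga, gb = labels
    rows = []
    for pop, sub in image_table.groupby("population", sort=True):
        sub = sub.dropna(subset=["percent_of_parent"])
        a = sub.loc[sub["image_id"].map(groups) == ga, "percent_of_parent"].to_numpy()
        b = sub.loc[sub["image_id"].map(groups) == gb, "percent_of_parent"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"population {pop!r}: fewer than 2 images in a group")
        t, p = student_t_two_sample(a, b)
        effect = float(a.mean() - b.mean())
        testable = not np.isnan(p)
        sig = bool(
            testable and p < rule.p_threshold and abs(effect) > rule.effect_threshold
        )
        rows.append(
            {
                "population": pop,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "effect": effect,
                "t": t,
                "p": p,
                "testable": testable,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)


def read_phenotypes_yaml(path) -> list[PhenotypeDefinition]:
    """Read a gating hierarchy from YAML: list of {name, positive,
    negative, parent} mappings."""
    raw = yaml.safe_load(open(path))
    return [
        PhenotypeDefinition(
            name=d["name"],
            positive=tuple(d.get("positive", ())),
            negative=tuple(d.get("negative", ())),
            parent=d.get("parent", "ROOT"),
        )
        for d in raw
    ]
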